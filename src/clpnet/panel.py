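"""Panel data model, CSV ingestion/validation, and scale reliability.

A :class:`SymptomPanel` holds one row per subject with nine ordinal PHQ-9
item scores (0-3) at each of two waves plus optional numeric covariates.
Only listwise-complete subjects are analyzed; by default incomplete rows are
dropped with a per-row report, mirroring a completers-only cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ITEMS = 9
WAVES = ("t1", "t2")

#: Conventional PHQ-9 item content, indexed 1..9.
ITEM_LABELS = (
    "anhedonia",
    "depressed_mood",
    "sleep",
    "lack_of_energy",
    "appetite",
    "guilt",
    "concentration",
    "motor",
    "suicidal_ideation",
)


def default_item_columns() -> dict:
    """Column-name mapping ``{(item, wave): column}`` for the wide CSV layout
    ``phq{1..9}_t1``, ``phq{1..9}_t2``."""
    return {(i, w): f"phq{i}_{w}" for i in range(1, N_ITEMS + 1) for w in WAVES}


class PanelValidationError(ValueError):
    """Raised when item scores violate the 0-3 integer range or completeness."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


class PanelConfigError(ValueError):
    """Raised when required columns are absent or options are inconsistent."""


@dataclass
class SymptomPanel:
    """Two-wave ordinal symptom panel.

    Attributes
    ----------
    subject_id : array of identifiers, one per subject.
    scores_t1, scores_t2 : (n, 9) integer arrays of item scores in {0..3}.
    covariates : DataFrame of per-subject numeric covariates (may be empty).
    item_labels : length-9 tuple of item names.
    """

    subject_id: np.ndarray
    scores_t1: np.ndarray
    scores_t2: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    item_labels: tuple = ITEM_LABELS

    def __post_init__(self):
        self.scores_t1 = np.asarray(self.scores_t1, dtype=int)
        self.scores_t2 = np.asarray(self.scores_t2, dtype=int)
        self.subject_id = np.asarray(self.subject_id)
        n = len(self.subject_id)
        for name, arr in (("scores_t1", self.scores_t1), ("scores_t2", self.scores_t2)):
            if arr.shape != (n, N_ITEMS):
                raise PanelValidationError(f"{name} must be (n, {N_ITEMS}); got {arr.shape}")
            if arr.min(initial=0) < 0 or arr.max(initial=0) > 3:
                raise PanelValidationError(f"{name} contains scores outside {{0,1,2,3}}")
        if len(self.covariates) not in (0, n):
            raise PanelValidationError("covariates must have one row per subject")
        if len(self.covariates):
            vals = self.covariates.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise PanelValidationError("covariates must be complete and finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def scores(self, wave: str) -> np.ndarray:
        if wave not in WAVES:
            raise PanelConfigError(f"wave must be one of {WAVES}, got {wave!r}")
        return self.scores_t1 if wave == "t1" else self.scores_t2

    def totals(self, wave: str) -> np.ndarray:
        """PHQ-9 total score (0-27) per subject at a wave."""
        return self.scores(wave).sum(axis=1)

    def subset(self, mask: np.ndarray) -> "SymptomPanel":
        """Row-subset (boolean mask or index array) preserving covariates."""
        cov = self.covariates.iloc[mask].reset_index(drop=True) if len(self.covariates) else self.covariates
        return SymptomPanel(
            subject_id=self.subject_id[mask],
            scores_t1=self.scores_t1[mask],
            scores_t2=self.scores_t2[mask],
            covariates=cov,
            item_labels=self.item_labels,
        )

    def to_frame(self, item_columns: dict | None = None) -> pd.DataFrame:
        """Wide one-row-per-subject DataFrame (inverse of :func:`load_panel`)."""
        cols = item_columns or default_item_columns()
        out = {"subject_id": self.subject_id}
        for i in range(1, N_ITEMS + 1):
            out[cols[(i, "t1")]] = self.scores_t1[:, i - 1]
            out[cols[(i, "t2")]] = self.scores_t2[:, i - 1]
        df = pd.DataFrame(out)
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def to_csv(self, path, item_columns: dict | None = None) -> None:
        self.to_frame(item_columns).to_csv(path, index=False)


def load_panel(
    path,
    item_columns: dict | None = None,
    covariate_columns: list | None = None,
    id_column: str = "subject_id",
    drop_incomplete: bool = True,
) -> SymptomPanel:
    """Read and validate a wide CSV panel.

    Parameters
    ----------
    item_columns : mapping ``{(item 1..9, 't1'|'t2'): column name}``;
        defaults to ``phq{i}_{wave}``.
    covariate_columns : optional list of covariate column names to retain.
    drop_incomplete : if True (default), rows with missing or out-of-range
        item scores are dropped and reported; if False such rows raise
        :class:`PanelValidationError` with the same per-row report attached.

    Returns the validated panel; the validation report is attached as
    ``panel.validation_report`` (DataFrame: row index, column, problem).
    """
    cols = item_columns or default_item_columns()
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise PanelConfigError(f"missing item columns: {missing}")
    covariate_columns = covariate_columns or []
    missing_cov = [c for c in covariate_columns if c not in df.columns]
    if missing_cov:
        raise PanelConfigError(f"missing covariate columns: {missing_cov}")

    problems = []
    bad_rows = np.zeros(len(df), dtype=bool)
    for col in cols.values():
        vals = pd.to_numeric(df[col], errors="coerce")
        isna = vals.isna()
        nonint = ~isna & (vals != np.floor(vals))
        oor = ~isna & ~nonint & ~vals.isin([0, 1, 2, 3])
        for idx in df.index[isna]:
            problems.append((idx, col, "missing"))
        for idx in df.index[nonint]:
            problems.append((idx, col, f"non-integer score {df.at[idx, col]!r}"))
        for idx in df.index[oor]:
            problems.append((idx, col, f"out-of-range score {df.at[idx, col]!r}"))
        bad_rows |= (isna | nonint | oor).to_numpy()
    for col in covariate_columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        isna = vals.isna() | ~np.isfinite(vals.fillna(0))
        for idx in df.index[isna]:
            problems.append((idx, col, "missing or non-finite covariate"))
        bad_rows |= isna.to_numpy()

    report = pd.DataFrame(problems, columns=["row", "column", "problem"])
    if len(report) and not drop_incomplete:
        raise PanelValidationError(
            f"{len(report)} invalid cells in {int(bad_rows.sum())} rows "
            f"(first: row {report.iloc[0]['row']}, column {report.iloc[0]['column']}, "
            f"{report.iloc[0]['problem']})",
            report=report,
        )

    keep = df[~bad_rows].reset_index(drop=True)
    ids = keep[id_column].to_numpy() if id_column in keep.columns else np.arange(len(keep))
    t1 = np.column_stack([keep[cols[(i, "t1")]].to_numpy(dtype=int) for i in range(1, N_ITEMS + 1)])
    t2 = np.column_stack([keep[cols[(i, "t2")]].to_numpy(dtype=int) for i in range(1, N_ITEMS + 1)])
    cov = keep[covariate_columns].astype(float) if covariate_columns else pd.DataFrame(index=keep.index)
    panel = SymptomPanel(subject_id=ids, scores_t1=t1, scores_t2=t2, covariates=cov)
    panel.validation_report = report
    return panel


def cronbach_alpha(panel: SymptomPanel, wave: str) -> float:
    """Cronbach's alpha for the 9 items at one wave.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum),
    with unbiased (n-1) sample variances.  Raises ``ValueError`` when the
    total-score variance is zero (reliability undefined).
    """
    x = panel.scores(wave).astype(float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("cronbach_alpha needs >=2 subjects and >=2 items")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; reliability undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def write_edgelist(fit, path) -> None:
    """Write a CLPN fit as a full-precision CSV edge list.

    All p*p entries are written (no thresholding), columns
    ``source_label, target_label, weight, is_autoregressive``.
    """
    labels = fit.item_labels
    rows = []
    p = fit.edge_matrix.shape[0]
    for i in range(p):
        for j in range(p):
            rows.append((labels[i], labels[j], repr(float(fit.edge_matrix[i, j])), i == j))
    pd.DataFrame(rows, columns=["source_label", "target_label", "weight", "is_autoregressive"]).to_csv(
        path, index=False
    )


def read_edgelist(path, item_labels: tuple = ITEM_LABELS) -> np.ndarray:
    """Read back an edge-list CSV into a p x p matrix (lossless round trip)."""
    df = pd.read_csv(path, dtype={"weight": str})
    index = {lab: k for k, lab in enumerate(item_labels)}
    p = len(item_labels)
    mat = np.zeros((p, p))
    for _, row in df.iterrows():
        mat[index[row["source_label"]], index[row["target_label"]]] = float(row["weight"])
    return mat
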