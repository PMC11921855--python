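"""Bootstrap accuracy and stability diagnostics for estimated networks.

Three procedures, all seeded through independent per-replicate substreams so
results are reproducible regardless of execution order:

* nonparametric bootstrap of subjects (with replacement, default 1000
  iterations) for 95% percentile confidence intervals around every edge;
* case-drop bootstrap for correlation-stability (CS) coefficients: the
  largest proportion of subjects that can be dropped such that, with 95%
  confidence, the subsample centrality still correlates >= 0.7 with the
  full-sample centrality (CS >= 0.25 acceptable, >= 0.5 preferred);
* difference tests for pairs of edges or pairs of node centralities, judged
  significant when the 95% bootstrap CI of the difference excludes zero.

The penalty is re-selected by cross-validation inside every refit by
default (full-procedure bootstrap).  ``fast=True`` freezes the per-target
penalties at their full-sample values, trading a little fidelity for a
large speedup; tests and exploratory runs use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SymptomPanel, N_ITEMS
from .estimation import CLPNFit, fit_clpn
from .centrality import expected_influence_raw

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.10, 0.7001, 0.05), 2))


@dataclass
class BootstrapEdges:
    """Edge-weight bootstrap: point fit, replicate draws, percentile CIs."""

    fit: CLPNFit
    replicates: np.ndarray  # (n_boot, p, p)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    boot_mean: np.ndarray
    n_boot: int
    seed: int
    degenerate_flags: list = field(default_factory=list)  # (replicate, target) pairs zeroed

    def ci_table(self) -> pd.DataFrame:
        labels = self.fit.item_labels
        p = len(labels)
        rows = []
        for i in range(p):
            for j in range(p):
                rows.append(
                    (labels[i], labels[j], self.fit.edge_matrix[i, j],
                     self.boot_mean[i, j], self.ci_lower[i, j], self.ci_upper[i, j])
                )
        return pd.DataFrame(rows, columns=["source", "target", "estimate",
                                           "boot_mean", "ci_lower", "ci_upper"])


@dataclass
class CSResult:
    index: str  # "in_ei" or "out_ei"
    cs_value: float
    correlation_threshold: float
    confidence: float
    drop_grid: tuple
    quantiles: dict  # drop proportion -> (1-confidence) quantile of correlations
    correlations: dict  # drop proportion -> array of per-subsample correlations


def _refit(panel: SymptomPanel, idx: np.ndarray, seed: int, covariates: bool,
           lambdas: np.ndarray | None, n_folds: int) -> CLPNFit:
    import warnings

    sub = panel.subset(idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_clpn(sub, covariates=covariates, seed=seed, lambdas=lambdas, n_folds=n_folds)


def bootstrap_edge_ci(
    panel: SymptomPanel,
    n_boot: int = 1000,
    seed: int = 0,
    covariates: bool = True,
    fast: bool = False,
    n_folds: int = 10,
    level: float = 0.95,
) -> BootstrapEdges:
    """Nonparametric bootstrap of the full CLPN estimation.

    Subjects are resampled with replacement ``n_boot`` times and the network
    re-estimated on each resample (penalty re-selected unless ``fast``).
    CI bounds are the empirical 2.5/97.5 percentiles per edge.  A resample
    with a zero-variance outcome column keeps the replicate with that
    target's coefficients recorded as 0 and flagged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = fit_clpn(panel, covariates=covariates, seed=seed, n_folds=n_folds)
    frozen = base.lambdas if fast else None
    n = panel.n_subjects
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_boot)
    reps = np.empty((n_boot, N_ITEMS, N_ITEMS))
    flags = []
    for b in range(n_boot):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, n, size=n)
        sub_seed = int(streams[b].generate_state(1)[0] % (2**31))
        fit_b = _refit(panel, idx, sub_seed, covariates, frozen, n_folds)
        reps[b] = fit_b.edge_matrix
        for j in fit_b.degenerate_targets:
            flags.append((b, j))
    alpha = (1 - level) / 2
    lower = np.quantile(reps, alpha, axis=0)
    upper = np.quantile(reps, 1 - alpha, axis=0)
    return BootstrapEdges(
        fit=base,
        replicates=reps,
        ci_lower=lower,
        ci_upper=upper,
        boot_mean=reps.mean(axis=0),
        n_boot=n_boot,
        seed=seed,
        degenerate_flags=flags,
    )


def case_drop_cs(
    panel: SymptomPanel,
    index: str = "out_ei",
    drop_grid: tuple = DEFAULT_DROP_GRID,
    reps_per_level: int = 100,
    seed: int = 0,
    correlation_threshold: float = 0.7,
    confidence: float = 0.95,
    covariates: bool = True,
    fast: bool = False,
    variant: str = "overall",
    n_folds: int = 10,
) -> CSResult:
    """Case-drop bootstrap CS coefficient for one centrality index.

    For each drop proportion q, draws ``reps_per_level`` subsamples without
    replacement of size round(n*(1-q)), refits the network, and correlates
    the subsample centrality with the full-sample centrality.  CS is the
    largest q whose empirical (1-confidence) quantile of correlations stays
    at or above ``correlation_threshold`` (0 if none does).
    """
    if index not in ("in_ei", "out_ei"):
        raise ValueError("index must be 'in_ei' or 'out_ei'")
    if len(drop_grid) == 0:
        raise ValueError("drop grid is empty")
    n = panel.n_subjects
    max_drop = max(drop_grid)
    if round(n * (1 - max_drop)) < 20:
        raise ValueError("too few subjects at the maximum drop proportion")
    full_fit = fit_clpn(panel, covariates=covariates, seed=seed, n_folds=n_folds)
    frozen = full_fit.lambdas if fast else None
    full_in, full_out = expected_influence_raw(full_fit.edge_matrix, variant)
    full_vec = full_in if index == "in_ei" else full_out

    ss = np.random.SeedSequence([seed, 7])
    quantiles = {}
    correlations = {}
    for q, stream in zip(drop_grid, ss.spawn(len(drop_grid))):
        m = int(round(n * (1 - q)))
        cors = np.empty(reps_per_level)
        for r, sub_stream in enumerate(stream.spawn(reps_per_level)):
            rng = np.random.default_rng(sub_stream)
            idx = rng.choice(n, size=m, replace=False)
            sub_seed = int(sub_stream.generate_state(1)[0] % (2**31))
            fit_r = _refit(panel, idx, sub_seed, covariates, frozen, min(n_folds, m))
            sub_in, sub_out = expected_influence_raw(fit_r.edge_matrix, variant)
            vec = sub_in if index == "in_ei" else sub_out
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(full_vec, vec)[0, 1]
            cors[r] = c if np.isfinite(c) else 0.0
        correlations[q] = cors
        quantiles[q] = float(np.quantile(cors, 1 - confidence))
    passing = [q for q in drop_grid if quantiles[q] >= correlation_threshold]
    cs = max(passing) if passing else 0.0
    return CSResult(
        index=index,
        cs_value=cs,
        correlation_threshold=correlation_threshold,
        confidence=confidence,
        drop_grid=tuple(drop_grid),
        quantiles=quantiles,
        correlations=correlations,
    )


def _edge_index(boot: BootstrapEdges, edge) -> tuple:
    labels = list(boot.fit.item_labels)
    i, j = edge
    if isinstance(i, str):
        if i not in labels or j not in labels:
            raise KeyError(f"unknown edge {edge!r}")
        return labels.index(i), labels.index(j)
    p = len(labels)
    if not (0 <= i < p and 0 <= j < p):
        raise KeyError(f"unknown edge {edge!r}")
    return i, j


def edge_difference_test(boot: BootstrapEdges, edge_a, edge_b, level: float = 0.95):
    """Is the CI of (w_a - w_b) across bootstrap replicates away from zero?

    Returns ``(significant, (ci_lower, ci_upper))``.  An edge compared with
    itself gives a [0, 0] interval and is never significant.
    """
    ia, ja = _edge_index(boot, edge_a)
    ib, jb = _edge_index(boot, edge_b)
    diff = boot.replicates[:, ia, ja] - boot.replicates[:, ib, jb]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(diff, [alpha, 1 - alpha])
    sig = bool(lo > 0 or hi < 0)
    return sig, (float(lo), float(hi))


def _node_index(boot: BootstrapEdges, node) -> int:
    labels = list(boot.fit.item_labels)
    if isinstance(node, str):
        if node not in labels:
            raise KeyError(f"unknown node {node!r}")
        return labels.index(node)
    if not 0 <= node < len(labels):
        raise KeyError(f"unknown node {node!r}")
    return int(node)


def _replicate_centralities(boot: BootstrapEdges, index: str, variant: str) -> np.ndarray:
    out = np.empty((boot.n_boot, N_ITEMS))
    for b in range(boot.n_boot):
        in_ei, out_ei = expected_influence_raw(boot.replicates[b], variant)
        out[b] = in_ei if index == "in_ei" else out_ei
    return out


def centrality_difference_test(boot: BootstrapEdges, index: str, node_a, node_b,
                               variant: str = "overall", level: float = 0.95):
    """Bootstrap difference test between two nodes' centralities."""
    if index not in ("in_ei", "out_ei"):
        raise ValueError("index must be 'in_ei' or 'out_ei'")
    ia = _node_index(boot, node_a)
    ib = _node_index(boot, node_b)
    cent = _replicate_centralities(boot, index, variant)
    diff = cent[:, ia] - cent[:, ib]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(diff, [alpha, 1 - alpha])
    sig = bool(lo > 0 or hi < 0)
    return sig, (float(lo), float(hi))


def edge_difference_matrix(boot: BootstrapEdges, level: float = 0.95) -> pd.DataFrame:
    """Symmetric boolean significance matrix over all p*p edges."""
    p = N_ITEMS
    flat = boot.replicates.reshape(boot.n_boot, p * p)
    alpha = (1 - level) / 2
    k = flat.shape[1]
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        diff = flat[:, [a]] - flat
        lo = np.quantile(diff, alpha, axis=0)
        hi = np.quantile(diff, 1 - alpha, axis=0)
        sig[a] = (lo > 0) | (hi < 0)
    sig &= sig.T  # symmetry by construction up to quantile asymmetry; enforce
    np.fill_diagonal(sig, False)
    labels = boot.fit.item_labels
    names = [f"{labels[i]}->{labels[j]}" for i in range(p) for j in range(p)]
    return pd.DataFrame(sig, index=names, columns=names)


def centrality_difference_matrix(boot: BootstrapEdges, index: str,
                                 variant: str = "overall", level: float = 0.95) -> pd.DataFrame:
    """Symmetric boolean significance matrix over all node pairs."""
    cent = _replicate_centralities(boot, index, variant)
    p = cent.shape[1]
    alpha = (1 - level) / 2
    sig = np.zeros((p, p), dtype=bool)
    for a in range(p):
        diff = cent[:, [a]] - cent
        lo = np.quantile(diff, alpha, axis=0)
        hi = np.quantile(diff, 1 - alpha, axis=0)
        sig[a] = (lo > 0) | (hi < 0)
    sig &= sig.T
    np.fill_diagonal(sig, False)
    labels = list(boot.fit.item_labels)
    return pd.DataFrame(sig, index=labels, columns=labels)
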