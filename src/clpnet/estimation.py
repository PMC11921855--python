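"""Node-wise LASSO estimation of the cross-lagged panel network.

One penalized regression per wave-2 symptom: the standardized T2 score of
symptom j is regressed on all nine standardized T1 scores (plus any
standardized covariates).  The objective is

    (1/2n) * sum(residual^2) + lambda * sum(|beta|)

with lambda chosen per target by 10-fold cross-validation over a log-spaced
grid of 100 values from lambda_max (the smallest lambda giving the all-zero
solution) down to 1e-4 * lambda_max.  Ties in CV error are broken toward the
larger lambda (the sparser model).  Edge (i, j) of the network is the
coefficient of T1 symptom i in the equation for T2 symptom j; covariate
coefficients are stored separately and never enter the edge matrix.

Both predictors and outcomes are z-standardized within the analyzed group so
edge weights are comparable across equations and groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .panel import SymptomPanel, N_ITEMS

N_LAMBDAS = 100
LAMBDA_MIN_RATIO = 1e-4


@dataclass
class CLPNFit:
    """Estimated cross-lagged panel network for one group.

    ``edge_matrix[i, j]`` is the standardized coefficient of symptom i at T1
    predicting symptom j at T2; the diagonal holds the autoregressive paths.
    """

    edge_matrix: np.ndarray
    covariate_effects: pd.DataFrame
    lambdas: np.ndarray
    intercepts: np.ndarray
    n_subjects: int
    fold_seed: int
    item_labels: tuple
    degenerate_targets: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "edge_matrix": self.edge_matrix.tolist(),
            "covariate_effects": {c: self.covariate_effects[c].tolist() for c in self.covariate_effects.columns},
            "lambdas": self.lambdas.tolist(),
            "intercepts": self.intercepts.tolist(),
            "n_subjects": self.n_subjects,
            "fold_seed": self.fold_seed,
            "item_labels": list(self.item_labels),
            "degenerate_targets": self.degenerate_targets,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CLPNFit":
        cov = pd.DataFrame(d["covariate_effects"])
        return cls(
            edge_matrix=np.asarray(d["edge_matrix"], dtype=float),
            covariate_effects=cov,
            lambdas=np.asarray(d["lambdas"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            n_subjects=int(d["n_subjects"]),
            fold_seed=int(d["fold_seed"]),
            item_labels=tuple(d["item_labels"]),
            degenerate_targets=list(d.get("degenerate_targets", [])),
        )


def standardize_columns(matrix: np.ndarray):
    """Column-wise z-standardization with unbiased (n-1) scales.

    Returns ``(standardized, means, scales, zero_variance_mask)``; columns
    with zero variance become all-zero and are flagged.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("standardization needs n >= 2")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    zero_var = scales == 0
    safe = np.where(zero_var, 1.0, scales)
    z = (x - means) / safe
    z[:, zero_var] = 0.0
    return z, means, scales, zero_var


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """(1/2n)||y - X beta||^2 + lam * ||beta||_1."""
    n = X.shape[0]
    r = y - X @ beta
    return float(0.5 * (r @ r) / n + lam * np.abs(beta).sum())


def solve_lasso(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8) -> np.ndarray:
    """Minimize (1/2n)RSS + lam*L1 by coordinate descent; exact zeros kept.

    With ``lam == 0`` the ordinary least-squares solution is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_.copy()


def lambda_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Descending log-spaced grid of 100 penalties from lambda_max down."""
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, LAMBDA_MIN_RATIO * lam_max, N_LAMBDAS)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return np.array_split(perm, n_folds)


def select_lambda_cv(X: np.ndarray, y: np.ndarray, n_folds: int = 10, seed: int = 0):
    """Pick the penalty minimizing 10-fold CV squared error.

    Folds come from a single seeded permutation.  Returns
    ``(lambda_selected, cv_curve)`` where ``cv_curve`` is a DataFrame with
    columns ``lam`` (descending) and ``cv_mse``.  Ties break toward the
    larger lambda.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"need n >= n_folds ({n} < {n_folds})")
    lams = lambda_grid(X, y)
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, n_folds, rng)
    sse = np.zeros(N_LAMBDAS)
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xva, yva = X[val_idx], y[val_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Xtr, ytr, alphas=lams, max_iter=10_000, tol=1e-6)
        resid = yva[:, None] - Xva @ coefs  # (n_val, n_lambdas)
        sse += (resid ** 2).sum(axis=0)
    cv_mse = sse / n
    best = int(np.argmin(cv_mse))  # first occurrence = largest lambda on a descending grid
    curve = pd.DataFrame({"lam": lams, "cv_mse": cv_mse})
    return float(lams[best]), curve


def fit_clpn(
    panel: SymptomPanel,
    covariates: bool = True,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_folds: int = 10,
) -> CLPNFit:
    """Estimate the full 9x9 cross-lagged panel network for a panel.

    Parameters
    ----------
    covariates : include the panel's covariate columns as (penalized,
        standardized) predictors; their coefficients are stored in
        ``covariate_effects`` and excluded from the edge matrix.
    seed : master seed; per-target fold shuffles are derived from it.
    lambdas : optional length-9 array of frozen penalties (skips CV); used
        by the resampling fast mode.
    """
    n = panel.n_subjects
    if n < 20:
        warnings.warn(f"n={n} is small for CLPN estimation; results may be unstable")
    t1 = panel.scores_t1.astype(float)
    t2 = panel.scores_t2.astype(float)
    cov_names = list(panel.covariates.columns) if covariates else []
    if cov_names:
        cov_raw = panel.covariates.to_numpy(dtype=float)
        design_raw = np.hstack([t1, cov_raw])
    else:
        design_raw = t1
    Xz, _, _, _ = standardize_columns(design_raw)
    Yz, _, _, y_zero = standardize_columns(t2)

    p = N_ITEMS
    edge = np.zeros((p, p))
    cov_eff = np.zeros((len(cov_names), p))
    lam_sel = np.zeros(p)
    degenerate = []
    for j in range(p):
        if y_zero[j]:
            degenerate.append(int(j))
            warnings.warn(f"degenerate target: zero-variance T2 column {j + 1}")
            continue
        yj = Yz[:, j]
        tj_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31))
        if lambdas is not None:
            lam = float(lambdas[j])
        else:
            lam, _ = select_lambda_cv(Xz, yj, n_folds=n_folds, seed=tj_seed)
        beta = solve_lasso(Xz, yj, lam)
        edge[:, j] = beta[:p]
        if cov_names:
            cov_eff[:, j] = beta[p:]
        lam_sel[j] = lam
    return CLPNFit(
        edge_matrix=edge,
        covariate_effects=pd.DataFrame(cov_eff, index=cov_names, columns=list(panel.item_labels)),
        lambdas=lam_sel,
        intercepts=np.zeros(p),  # intercepts vanish on the standardized scale
        n_subjects=n,
        fold_seed=seed,
        item_labels=tuple(panel.item_labels),
        degenerate_targets=degenerate,
    )


def edge_summary(fit: CLPNFit) -> dict:
    """Count nonzero cross-lags and locate the strongest paths.

    Reports nonzero off-diagonal edges out of the 72 possible directed
    cross-lags for 9 nodes, the largest autoregressive coefficient, and the
    largest-|weight| cross-lagged edge with its signed value.
    """
    m = fit.edge_matrix
    p = m.shape[0]
    off_mask = ~np.eye(p, dtype=bool)
    off = m[off_mask]
    n_nonzero = int(np.count_nonzero(off))
    diag = np.diag(m)
    ar_node = int(np.argmax(diag))
    abs_off = np.abs(m) * off_mask
    src, tgt = np.unravel_index(np.argmax(abs_off), m.shape)
    labels = fit.item_labels
    return {
        "n_nonzero_cross_lagged": n_nonzero,
        "n_possible_cross_lagged": p * (p - 1),
        "max_autoregressive": {"node": labels[ar_node], "weight": float(diag[ar_node])},
        "max_cross_lagged": {
            "source": labels[src],
            "target": labels[tgt],
            "weight": float(m[src, tgt]),
        },
    }
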