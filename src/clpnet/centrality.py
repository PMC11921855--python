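"""Expected-influence centralities and between-network structure correlation.

For a directed temporal network with edge (i, j) = effect of symptom i at
T1 on symptom j at T2:

* out-EI(i) = sum over targets j of edge(i, j) — how much i predicts the
  next wave; high out-EI marks candidate intervention targets.
* in-EI(j)  = sum over sources i of edge(i, j) — how much j is predicted.

Three variants: ``overall`` keeps every path; ``cross_lagged`` drops each
node's autoregressive path; ``cross_construct`` additionally drops paths
between nodes sharing a community label (degenerate — identically zero —
when all nine symptoms form one community, as for a single-scale network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import CLPNFit

VARIANTS = ("overall", "cross_lagged", "cross_construct")


@dataclass
class CentralityTable:
    table: pd.DataFrame  # columns: symptom, in_ei_raw, out_ei_raw, in_ei_z, out_ei_z, variant
    variant: str
    degenerate_z: dict  # which z columns came from a zero-sd vector


@dataclass
class NetworkComparison:
    r: float
    p_value: float
    n_elements: int
    include_diagonal: bool


def z_standardize(values: np.ndarray):
    """(x - mean)/sd with sample (n-1) sd; all zeros + flag when sd == 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z_standardize needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def _variant_mask(p: int, variant: str, community_map: dict | None, labels) -> np.ndarray:
    """Boolean p x p mask of the paths a variant counts."""
    keep = np.ones((p, p), dtype=bool)
    if variant == "overall":
        return keep
    if variant == "cross_lagged":
        np.fill_diagonal(keep, False)
        return keep
    if variant == "cross_construct":
        if community_map is None:
            raise ValueError("cross_construct requires a community_map")
        comm = [community_map[lab] for lab in labels]
        for i in range(p):
            for j in range(p):
                if comm[i] == comm[j]:
                    keep[i, j] = False
        return keep
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def expected_influence_raw(edge_matrix: np.ndarray, variant: str = "overall",
                           community_map: dict | None = None, labels=None) -> tuple:
    """Raw (in_ei, out_ei) vectors for a bare edge matrix."""
    m = np.asarray(edge_matrix, dtype=float)
    p = m.shape[0]
    if labels is None:
        labels = list(range(p))
    keep = _variant_mask(p, variant, community_map, labels)
    kept = np.where(keep, m, 0.0)
    return kept.sum(axis=0), kept.sum(axis=1)  # in-EI per target, out-EI per source


def expected_influence(fit: CLPNFit, variant: str = "overall",
                       community_map: dict | None = None) -> CentralityTable:
    """Per-symptom in-/out-expected influence, raw and z-standardized."""
    in_ei, out_ei = expected_influence_raw(fit.edge_matrix, variant, community_map, fit.item_labels)
    in_z, in_flag = z_standardize(in_ei)
    out_z, out_flag = z_standardize(out_ei)
    table = pd.DataFrame(
        {
            "symptom": list(fit.item_labels),
            "in_ei_raw": in_ei,
            "out_ei_raw": out_ei,
            "in_ei_z": in_z,
            "out_ei_z": out_z,
            "variant": variant,
        }
    )
    return CentralityTable(table=table, variant=variant,
                           degenerate_z={"in_ei": in_flag, "out_ei": out_flag})


def network_correlation(fit_a: CLPNFit, fit_b: CLPNFit,
                        include_diagonal: bool = True) -> NetworkComparison:
    """Pearson correlation of the two vectorized edge matrices.

    The two-sided p-value uses the t transform with n_elements - 2 degrees
    of freedom; it treats edges as independent draws and is therefore
    approximate.
    """
    if fit_a.item_labels != fit_b.item_labels:
        raise ValueError("fits have different symptom sets or ordering")
    a, b = fit_a.edge_matrix, fit_b.edge_matrix
    if include_diagonal:
        va, vb = a.ravel(), b.ravel()
    else:
        mask = ~np.eye(a.shape[0], dtype=bool)
        va, vb = a[mask], b[mask]
    r, p = stats.pearsonr(va, vb)
    return NetworkComparison(r=float(r), p_value=float(p),
                             n_elements=va.size, include_diagonal=include_diagonal)
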