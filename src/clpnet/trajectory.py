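"""Trajectory stratification by PHQ-9 cutoff.

Subjects are dichotomized at each wave with a PHQ-9 total cutoff (default
>= 7, "7 or more" counts as probable depression) and assigned one of four
trajectories by the 2x2 rule: depressed at both waves -> chronic, only at
T2 -> delayed, only at T1 -> recovery, at neither -> resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .panel import SymptomPanel

#: Fixed reporting order everywhere (tables, files).
TRAJECTORY_LABELS = ("chronic", "delayed", "recovery", "resistance")

DEFAULT_CUTOFF = 7


@dataclass
class TrajectoryAssignment:
    subject_id: object
    t1_total: int
    t2_total: int
    depressed_t1: bool
    depressed_t2: bool
    label: str


@dataclass
class CohortSummary:
    """Group counts and percentages (rounded half-up to one decimal)."""

    counts: dict
    percentages: dict
    total_n: int

    @property
    def proportions(self) -> dict:
        return {k: v / self.total_n for k, v in self.counts.items()}


def percentage(count: int, total: int) -> float:
    """100*count/total reported to one decimal, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    exact = Decimal(100 * count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def phq_total(panel: SymptomPanel, subject, wave: str) -> int:
    """Total PHQ-9 score (0-27) of one subject at one wave."""
    idx = np.flatnonzero(panel.subject_id == subject)
    if idx.size == 0:
        raise KeyError(f"unknown subject {subject!r}")
    return int(panel.scores(wave)[idx[0]].sum())


def classify_trajectory(t1_total: int, t2_total: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Four-trajectory label from the two wave totals.

    The cutoff comparison is >= at both waves: a total exactly at the cutoff
    counts as depressed.
    """
    if not 1 <= cutoff <= 27:
        raise ValueError(f"cutoff must be in [1, 27], got {cutoff}")
    for t in (t1_total, t2_total):
        if not 0 <= t <= 27:
            raise ValueError(f"PHQ-9 total must be in [0, 27], got {t}")
    d1, d2 = t1_total >= cutoff, t2_total >= cutoff
    if d1 and d2:
        return "chronic"
    if d2:
        return "delayed"
    if d1:
        return "recovery"
    return "resistance"


def stratify_cohort(panel: SymptomPanel, cutoff: int = DEFAULT_CUTOFF):
    """Assign every subject a trajectory and summarize cohort composition.

    Returns ``(CohortSummary, DataFrame)`` where the frame has one row per
    subject: subject_id, t1_total, t2_total, depressed_t1, depressed_t2,
    label.
    """
    if panel.n_subjects == 0:
        raise ValueError("empty panel")
    t1 = panel.totals("t1")
    t2 = panel.totals("t2")
    labels = np.array([classify_trajectory(int(a), int(b), cutoff) for a, b in zip(t1, t2)])
    assignments = pd.DataFrame(
        {
            "subject_id": panel.subject_id,
            "t1_total": t1,
            "t2_total": t2,
            "depressed_t1": t1 >= cutoff,
            "depressed_t2": t2 >= cutoff,
            "label": labels,
        }
    )
    counts = {lab: int((labels == lab).sum()) for lab in TRAJECTORY_LABELS}
    n = panel.n_subjects
    summary = CohortSummary(
        counts=counts,
        percentages={lab: percentage(c, n) for lab, c in counts.items()},
        total_n=n,
    )
    return summary, assignments


def split_by_trajectory(panel: SymptomPanel, cutoff: int = DEFAULT_CUTOFF) -> dict:
    """Per-label sub-panels, in the fixed label order."""
    _, assignments = stratify_cohort(panel, cutoff)
    labels = assignments["label"].to_numpy()
    return {lab: panel.subset(labels == lab) for lab in TRAJECTORY_LABELS}
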