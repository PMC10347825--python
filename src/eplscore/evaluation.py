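"""Diagnostic performance of a score: contingency tables, per-cutoff
metrics, the full performance table and rank-based AUC.

Positivity convention: a pregnancy is *predicted* to end in early loss
when its total score is at or above the cutoff (``score >= cutoff``),
and the *event* is an observed early pregnancy loss.  The ``>=`` rule is
what makes the extreme rows of a performance table behave as expected
(the lowest cutoff classifies everyone positive: sensitivity 100%,
specificity 0%, PPV equal to prevalence).

Metrics with a zero denominator are *undefined*, not zero; they render
as a dash in text output and ``null`` in JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .scoring import RiskTable, ValidationError, lookup_risk

__all__ = [
    "ContingencyTable",
    "PerformanceRow",
    "contingency_at_cutoff",
    "metrics",
    "performance_table",
    "auc_rank",
    "render_performance_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts at one cutoff: positive = score >= cutoff, event = loss."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def events(self) -> int:
        return self.tp + self.fn

    @property
    def prevalence(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class PerformanceRow:
    """One row of the performance table, percentages at full precision.

    ``estimated_risk`` is the risk-table entry at the cutoff score;
    undefined metrics are ``None``.
    """

    cutoff: int
    estimated_risk: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


def _to_event_array(outcomes: Sequence) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype.kind in ("U", "O", "S"):
        bad = ~np.isin(arr, ["ongoing", "epl"])
        if bad.any():
            raise ValidationError(f"unknown outcome label {arr[bad][0]!r}")
        return arr == "epl"
    return arr.astype(bool)


def contingency_at_cutoff(
    scores: Sequence[float], outcomes: Sequence, cutoff: float
) -> ContingencyTable:
    """Cross-classify predicted (score >= cutoff) against observed loss."""
    s = np.asarray(scores, dtype=float)
    e = _to_event_array(outcomes)
    if len(s) != len(e):
        raise ValidationError(
            f"scores ({len(s)}) and outcomes ({len(e)}) differ in length"
        )
    if len(s) == 0:
        raise ValidationError("empty cohort")
    pos = s >= cutoff
    return ContingencyTable(
        tp=int(np.sum(pos & e)),
        fp=int(np.sum(pos & ~e)),
        fn=int(np.sum(~pos & e)),
        tn=int(np.sum(~pos & ~e)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(table: ContingencyTable) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent.

    Each metric is ``None`` (undefined) when its denominator is zero —
    e.g. PPV when nobody is classified positive.
    """
    if table.total == 0:
        raise ValidationError("empty contingency table")
    return {
        "sensitivity": _ratio(table.tp, table.tp + table.fn),
        "specificity": _ratio(table.tn, table.tn + table.fp),
        "ppv": _ratio(table.tp, table.tp + table.fp),
        "npv": _ratio(table.tn, table.tn + table.fn),
        "accuracy": _ratio(table.tp + table.tn, table.total),
    }


def performance_table(
    scores: Sequence[float],
    outcomes: Sequence,
    risk_table: RiskTable,
) -> list[PerformanceRow]:
    """One row per integer cutoff across the risk table's score range.

    The risk table must span the observed scores, so every achievable
    total has both an estimated risk and cutoff metrics.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) and (s.min() < risk_table.score_min or s.max() > risk_table.score_max):
        raise ValidationError(
            f"observed scores [{s.min():.0f}, {s.max():.0f}] exceed the risk "
            f"table's range [{risk_table.score_min}, {risk_table.score_max}]"
        )
    rows = []
    for cutoff in range(risk_table.score_min, risk_table.score_max + 1):
        m = metrics(contingency_at_cutoff(scores, outcomes, cutoff))
        rows.append(
            PerformanceRow(
                cutoff=cutoff,
                estimated_risk=lookup_risk(cutoff, risk_table),
                **m,
            )
        )
    return rows


def auc_rank(scores: Sequence[float], outcomes: Sequence) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a randomly chosen loss outranks a
    randomly chosen ongoing pregnancy, counting ties as one half; the
    midrank formulation applies the tie correction exactly.
    """
    s = np.asarray(scores, dtype=float)
    e = _to_event_array(outcomes)
    n1 = int(e.sum())
    n0 = len(e) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both outcome classes present")
    ranks = stats.rankdata(s)
    u = ranks[e].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _fmt(x: float | None, width: int = 8) -> str:
    # half-away-from-zero at 2 d.p. for presentation, dash when undefined
    if x is None:
        return "-".rjust(width)
    q = math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)
    return f"{q:.2f}".rjust(width)


def render_performance_table(rows: Sequence[PerformanceRow]) -> str:
    """Plain-text rendering, one row per cutoff, dashes for undefined."""
    header = (
        f"{'Score':>6}{'Risk%':>8}{'Sens%':>8}{'Spec%':>8}"
        f"{'PPV%':>8}{'NPV%':>8}{'Acc%':>8}"
    )
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.cutoff:>6}"
            + _fmt(r.estimated_risk)
            + _fmt(r.sensitivity)
            + _fmt(r.specificity)
            + _fmt(r.ppv)
            + _fmt(r.npv)
            + _fmt(r.accuracy)
        )
    return "\n".join(lines)
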