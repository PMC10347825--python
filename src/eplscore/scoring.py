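"""Integer points-based risk scoring for early pregnancy loss (EPL).

This module implements the Sullivan/Framingham procedure for turning a
fitted logistic regression into a bedside integer score.  Each risk
factor ``i`` has a per-unit log-odds coefficient ``beta_i`` and a set of
clinical categories; category ``j`` carries a representative value
``W_ij`` (a midpoint-like value in the factor's own units).  One
category per factor is the *base* (reference) category with value
``W_iREF``, and the points for any other category are

    points_ij = round( beta_i * (W_ij - W_iREF) / B )

where ``B`` is the points base constant (here five times the
maternal-age coefficient, so that five years of maternal age cost one
point) and rounding is to the nearest integer, half away from zero.
A patient's total score is the sum of their per-factor category points,
and a lookup table maps each achievable total to an estimated risk of
miscarriage in percent.

The published six-factor system (maternal age, endometrial thickness on
transfer day, gestational sac diameter, yolk sac diameter, embryonic
length and embryonic heart rate, measured on days 27-29 after embryo
transfer) ships as a JSON fixture and is returned by
:func:`published_system`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorCategory",
    "RiskFactorSpec",
    "PointSystem",
    "PatientRecord",
    "RiskTable",
    "ScoreBreakdown",
    "ValidationError",
    "SpecificationError",
    "round_half_away",
    "categorize",
    "compute_category_points",
    "build_point_system",
    "score_patient",
    "score_cohort",
    "lookup_risk",
    "published_system",
    "published_category_templates",
    "follow_up_recommendation",
    "system_to_dict",
    "system_from_dict",
]

SCORING_VARIABLES = ("ma", "em", "gsd", "ysd", "el", "ehr")

#: Clinical cutoff recommended for triage: totals at or above this score
#: warrant a repeat scan 7-10 days later.
DEFAULT_CUTOFF = 5


class ValidationError(ValueError):
    """A patient value or record fails validation."""


class SpecificationError(ValueError):
    """A factor or system definition is internally inconsistent."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    The derivation needs this convention: a raw point value of exactly
    1.5 (maternal age >= 40) must become 2, which banker's rounding
    would not give.  The input is pre-rounded to 9 decimals so that
    binary float noise around an exact half does not flip the result.
    """
    x = round(x, 9)
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class FactorCategory:
    """One clinical interval of a risk factor.

    The interval is half-open ``[lower, upper)`` in the factor's own
    units; ``-inf``/``+inf`` bounds are allowed at the extremes.
    ``representative_value`` is the midpoint-like value W_ij the points
    formula uses; the base category's representative value is W_iREF.
    ``points`` is filled in by :func:`build_point_system`.
    """

    label: str
    lower: float
    upper: float
    representative_value: float
    is_base: bool = False
    points: int | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SpecificationError(
                f"category {self.label!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class RiskFactorSpec:
    """A risk factor: coefficient, categories and deviation mode.

    ``deviation_mode`` is ``"signed"`` for ordinary factors and
    ``"absolute"`` for U-shaped ones, where both low and high deviations
    from the reference increase risk (yolk sac diameter in the published
    system: both small and large yolk sacs score +1).
    """

    name: str
    beta: float
    categories: tuple[FactorCategory, ...]
    deviation_mode: str = "signed"

    def __post_init__(self) -> None:
        if self.deviation_mode not in ("signed", "absolute"):
            raise SpecificationError(
                f"factor {self.name!r}: unknown deviation mode "
                f"{self.deviation_mode!r}"
            )
        cats = sorted(self.categories, key=lambda c: c.lower)
        object.__setattr__(self, "categories", tuple(cats))
        if not cats:
            raise SpecificationError(f"factor {self.name!r} has no categories")
        problems = []
        if cats[0].lower != -math.inf:
            problems.append(f"first interval starts at {cats[0].lower}, not -inf")
        if cats[-1].upper != math.inf:
            problems.append(f"last interval ends at {cats[-1].upper}, not +inf")
        for a, b in zip(cats, cats[1:]):
            if a.upper != b.lower:
                kind = "gap" if a.upper < b.lower else "overlap"
                problems.append(
                    f"{kind} between {a.label!r} [{a.lower}, {a.upper}) and "
                    f"{b.label!r} [{b.lower}, {b.upper})"
                )
        if problems:
            raise SpecificationError(
                f"factor {self.name!r}: categories do not partition the line: "
                + "; ".join(problems)
            )
        n_base = sum(c.is_base for c in cats)
        if n_base != 1:
            raise SpecificationError(
                f"factor {self.name!r}: exactly one base category required, "
                f"found {n_base}"
            )

    @property
    def base_category(self) -> FactorCategory:
        return next(c for c in self.categories if c.is_base)

    @property
    def reference_value(self) -> float:
        """W_iREF: the base category's representative value."""
        return self.base_category.representative_value


@dataclass(frozen=True)
class PointSystem:
    """A complete points system: factors with derived integer points.

    ``score_min`` / ``score_max`` are the extremes achievable by any
    combination of categories (the sum of per-factor minima / maxima).
    """

    factors: tuple[RiskFactorSpec, ...]
    B: float
    score_min: int = field(init=False)
    score_max: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise SpecificationError(f"points base constant B must be > 0, got {self.B}")
        for f in self.factors:
            for c in f.categories:
                if c.points is None:
                    raise SpecificationError(
                        f"factor {f.name!r} category {c.label!r} has no points; "
                        "use build_point_system to derive them"
                    )
        lo = sum(min(c.points for c in f.categories) for f in self.factors)
        hi = sum(max(c.points for c in f.categories) for f in self.factors)
        object.__setattr__(self, "score_min", lo)
        object.__setattr__(self, "score_max", hi)

    def factor(self, name: str) -> RiskFactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class PatientRecord:
    """One intrauterine singleton pregnancy.

    The six scoring variables are required and must be finite and
    non-negative.  An embryonic heart rate of 0 bpm encodes absent
    cardiac activity and an embryonic length of 0 mm an absent embryo;
    both are valid clinical presentations, not missing data.
    """

    ma: float  # maternal age, years
    em: float  # endometrial thickness on transfer day, mm
    gsd: float  # gestational sac diameter, mm
    ysd: float  # yolk sac diameter, mm
    el: float  # embryonic length, mm
    ehr: float  # embryonic heart rate, bpm
    bmi: float | None = None  # kg/m^2
    hcg: float | None = None  # day-14 serum beta-hCG, mIU/ml
    duration: float | None = None  # infertility duration, years
    iuh: bool | None = None  # intrauterine hematoma present
    outcome: str | None = None  # "ongoing" or "epl"

    def __post_init__(self) -> None:
        for name in SCORING_VARIABLES:
            v = getattr(self, name)
            if v is None:
                raise ValidationError(f"scoring variable {name!r} is missing")
            if not math.isfinite(v):
                raise ValidationError(f"scoring variable {name!r} is not finite: {v}")
            if v < 0:
                raise ValidationError(f"scoring variable {name!r} is negative: {v}")
        if self.outcome is not None and self.outcome not in ("ongoing", "epl"):
            raise ValidationError(
                f"outcome must be 'ongoing' or 'epl', got {self.outcome!r}"
            )


@dataclass(frozen=True)
class RiskTable:
    """Estimated miscarriage risk (percent) per total score.

    Rows must cover consecutive integer totals and the risk must be
    strictly increasing: a higher score always means a higher estimated
    risk.
    """

    rows: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        totals = [t for t, _ in self.rows]
        risks = [r for _, r in self.rows]
        if totals != list(range(totals[0], totals[0] + len(totals))):
            raise SpecificationError("risk table totals must be consecutive integers")
        if any(b <= a for a, b in zip(risks, risks[1:])):
            raise SpecificationError("risk table must be strictly increasing in score")
        if any(not 0 < r < 100 for r in risks):
            raise SpecificationError("risks must lie strictly between 0 and 100 percent")

    @property
    def score_min(self) -> int:
        return self.rows[0][0]

    @property
    def score_max(self) -> int:
        return self.rows[-1][0]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Total score with the per-factor contributions that compose it."""

    total: int
    points: Mapping[str, int]


def categorize(value: float, factor: RiskFactorSpec) -> int:
    """Return the index of the category whose interval contains ``value``.

    Raises :class:`ValidationError` for non-finite or negative values,
    naming the offending factor.
    """
    if not math.isfinite(value):
        raise ValidationError(f"{factor.name}: value is not finite: {value}")
    if value < 0:
        raise ValidationError(f"{factor.name}: value is negative: {value}")
    for i, cat in enumerate(factor.categories):
        if cat.contains(value):
            return i
    raise SpecificationError(  # unreachable for a validated partition
        f"{factor.name}: no category contains {value}"
    )


def compute_category_points(
    factor: RiskFactorSpec, category: FactorCategory, B: float
) -> int:
    """Points for one category: round(beta * (W_ij - W_iREF) / B).

    In ``absolute`` deviation mode the magnitude of the deviation is
    scored with the magnitude of the coefficient, so categories on both
    sides of the reference earn non-negative points.  The base category
    returns exactly 0.
    """
    if not B > 0:
        raise SpecificationError(f"B must be > 0, got {B}")
    if category.is_base:
        return 0
    dev = category.representative_value - factor.reference_value
    if factor.deviation_mode == "absolute":
        raw = abs(factor.beta) * abs(dev) / B
    else:
        raw = factor.beta * dev / B
    return round_half_away(raw)


def build_point_system(specs: Iterable[RiskFactorSpec], B: float) -> PointSystem:
    """Derive every category's integer points and assemble a system."""
    specs = list(specs)
    if not specs:
        raise SpecificationError("at least one risk factor is required")
    out = []
    for spec in specs:
        cats = tuple(
            replace(c, points=compute_category_points(spec, c, B))
            for c in spec.categories
        )
        out.append(replace(spec, categories=cats))
    return PointSystem(factors=tuple(out), B=B)


def score_patient(record: PatientRecord, system: PointSystem) -> ScoreBreakdown:
    """Score one patient: total points and the per-factor breakdown."""
    points: dict[str, int] = {}
    for factor in system.factors:
        value = getattr(record, factor.name, None)
        if value is None:
            raise ValidationError(f"scoring variable {factor.name!r} is missing")
        idx = categorize(value, factor)
        points[factor.name] = factor.categories[idx].points
    return ScoreBreakdown(total=sum(points.values()), points=points)


def score_cohort(cohort: pd.DataFrame, system: PointSystem) -> pd.Series:
    """Vectorised scoring of a cohort DataFrame.

    Expects one column per factor name; returns an integer Series of
    total scores aligned with the input index.
    """
    total = np.zeros(len(cohort), dtype=int)
    for factor in system.factors:
        if factor.name not in cohort.columns:
            raise ValidationError(f"cohort lacks scoring column {factor.name!r}")
        values = cohort[factor.name].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"{factor.name}: non-finite values in cohort")
        if np.any(values < 0):
            raise ValidationError(f"{factor.name}: negative values in cohort")
        edges = np.array([c.lower for c in factor.categories[1:]])
        pts = np.array([c.points for c in factor.categories])
        total += pts[np.searchsorted(edges, values, side="right")]
    return pd.Series(total, index=cohort.index, name="score")


def lookup_risk(total: int, table: RiskTable) -> float:
    """Estimated miscarriage risk in percent for a total score."""
    if not table.score_min <= total <= table.score_max:
        raise ValidationError(
            f"total score {total} outside the table's range "
            f"[{table.score_min}, {table.score_max}]"
        )
    return table.rows[total - table.score_min][1]


def follow_up_recommendation(total: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Triage advice attached to a total score.

    High-scoring pregnancies are of uncertain viability: a repeat scan
    7-10 days after the first confirms the outcome before any
    intervention.  Low-scoring pregnancies follow the routine schedule
    with the next scan on day 45 after transfer.
    """
    if total >= cutoff:
        return (
            f"Score {total} >= {cutoff}: high estimated risk of early pregnancy "
            "loss. Repeat the ultrasound scan in 7-10 days to confirm embryonic "
            "viability before any intervention."
        )
    return (
        f"Score {total} < {cutoff}: low estimated risk. In the absence of "
        "symptoms, schedule the next routine scan on day 45 after transfer."
    )


# ---------------------------------------------------------------------------
# Serialization


def _bound_to_json(x: float) -> float | None:
    return None if math.isinf(x) else x


def _bound_from_json(x: float | None, sign: int) -> float:
    return sign * math.inf if x is None else float(x)


def system_to_dict(system: PointSystem, risk_table: RiskTable | None = None) -> dict:
    """JSON-serialisable encoding of a system (and optional risk table)."""
    doc: dict = {
        "B": system.B,
        "factors": [
            {
                "name": f.name,
                "beta": f.beta,
                "deviation_mode": f.deviation_mode,
                "categories": [
                    {
                        "label": c.label,
                        "lower": _bound_to_json(c.lower),
                        "upper": _bound_to_json(c.upper),
                        "representative_value": c.representative_value,
                        "is_base": c.is_base,
                        "points": c.points,
                    }
                    for c in f.categories
                ],
            }
            for f in system.factors
        ],
    }
    if risk_table is not None:
        doc["risk_table"] = [
            {"total": t, "estimated_risk": r} for t, r in risk_table.rows
        ]
    return doc


def system_from_dict(doc: Mapping) -> tuple[PointSystem, RiskTable | None]:
    """Rebuild a system from its JSON encoding.

    Points are re-derived from the stored betas, representative values
    and B rather than read back, so a hand-edited file cannot carry an
    inconsistent points column.
    """
    specs = []
    for fdoc in doc["factors"]:
        cats = tuple(
            FactorCategory(
                label=c["label"],
                lower=_bound_from_json(c["lower"], -1),
                upper=_bound_from_json(c["upper"], +1),
                representative_value=c["representative_value"],
                is_base=c["is_base"],
            )
            for c in fdoc["categories"]
        )
        specs.append(
            RiskFactorSpec(
                name=fdoc["name"],
                beta=fdoc["beta"],
                categories=cats,
                deviation_mode=fdoc.get("deviation_mode", "signed"),
            )
        )
    system = build_point_system(specs, doc["B"])
    table = None
    if "risk_table" in doc:
        table = RiskTable(
            rows=tuple((row["total"], row["estimated_risk"]) for row in doc["risk_table"])
        )
    return system, table


_PUBLISHED_CACHE: tuple[PointSystem, RiskTable] | None = None


def _load_published() -> tuple[PointSystem, RiskTable]:
    global _PUBLISHED_CACHE
    if _PUBLISHED_CACHE is None:
        text = resources.files("eplscore.data").joinpath("published_system.json").read_text()
        doc = json.loads(text)
        system, table = system_from_dict(doc)
        assert table is not None
        # cross-check the derived points against the published column
        for fdoc, factor in zip(doc["factors"], system.factors):
            for cdoc, cat in zip(fdoc["categories"], factor.categories):
                if cdoc["points"] is not None and cdoc["points"] != cat.points:
                    raise SpecificationError(
                        f"fixture inconsistency: {factor.name} {cat.label!r} derives "
                        f"{cat.points} points but the fixture records {cdoc['points']}"
                    )
        _PUBLISHED_CACHE = (system, table)
    return _PUBLISHED_CACHE


def published_system() -> tuple[PointSystem, RiskTable]:
    """The published six-factor EPL scoring system and its risk table.

    Points are re-derived from the published coefficients and reference
    values at load time and verified against the published points
    column, so the returned system is guaranteed self-consistent.
    """
    return _load_published()


def published_category_templates() -> tuple[RiskFactorSpec, ...]:
    """The published category scaffolding with coefficients stripped.

    Useful for deriving a new point system from freshly fitted
    coefficients while keeping the published clinical intervals and
    representative values (betas here are placeholders of magnitude 1
    with the published sign).
    """
    system, _ = _load_published()
    return tuple(
        replace(
            f,
            beta=math.copysign(1.0, f.beta),
            categories=tuple(replace(c, points=None) for c in f.categories),
        )
        for f in system.factors
    )
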