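"""Logistic model fitting, stepwise screening and point derivation.

This is the derivation pathway of the scoring system: fit a binary
logistic regression for early pregnancy loss on a training cohort,
screen candidate predictors stepwise on their Wald p-values, and
convert the surviving coefficients into an integer point table with the
Sullivan/Framingham rule implemented in :mod:`eplscore.scoring`.

Maximum-likelihood estimation is delegated to
:class:`statsmodels.api.Logit` (Newton-Raphson, i.e. iteratively
reweighted least squares, with standard errors from the observed
information matrix); this module owns the screening logic, the Wald
summaries and the point derivation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .scoring import (
    PointSystem,
    RiskFactorSpec,
    RiskTable,
    SpecificationError,
    ValidationError,
    build_point_system,
)

__all__ = [
    "FitResult",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "wald_summary",
    "stepwise_select",
    "derive_point_system",
    "estimate_risk_curve",
    "calibrate_risk_intercept",
]


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by a predictor."""


class ConvergenceError(RuntimeError):
    """Maximum likelihood estimation failed to converge."""


@dataclass(frozen=True)
class FitResult:
    """A fitted binary logistic model.

    ``params`` includes the intercept under the key ``"intercept"``;
    odds ratios and 95% confidence intervals are Wald-based
    (``exp(beta +- 1.96 se)``).
    """

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    odds_ratios: Mapping[str, float]
    conf_int: Mapping[str, tuple[float, float]]
    converged: bool
    iterations: int
    llf: float
    nobs: int

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(k for k in self.params if k != "intercept")

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "bse": dict(self.bse),
            "pvalues": dict(self.pvalues),
            "odds_ratios": dict(self.odds_ratios),
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "converged": self.converged,
            "iterations": self.iterations,
            "llf": self.llf,
            "nobs": self.nobs,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FitResult":
        return cls(
            params=dict(doc["params"]),
            bse=dict(doc["bse"]),
            pvalues=dict(doc["pvalues"]),
            odds_ratios=dict(doc["odds_ratios"]),
            conf_int={k: (v[0], v[1]) for k, v in doc["conf_int"].items()},
            converged=bool(doc["converged"]),
            iterations=int(doc["iterations"]),
            llf=float(doc["llf"]),
            nobs=int(doc["nobs"]),
        )


def wald_summary(beta: float, se: float) -> tuple[float, tuple[float, float], float]:
    """Odds ratio, Wald 95% CI and two-sided normal p for one coefficient."""
    if not se > 0:
        raise ValidationError(f"standard error must be > 0, got {se}")
    or_ = math.exp(beta)
    ci = (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return or_, ci, p


def _outcome_vector(cohort: pd.DataFrame, outcome_col: str) -> np.ndarray:
    y = cohort[outcome_col]
    if y.dtype == object or str(y.dtype) == "string":
        return (y == "epl").to_numpy(dtype=float)
    return y.to_numpy(dtype=float)


def _separating_variable(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Name a single covariate that (quasi-)separates the outcome, if any."""
    for col in X.columns:
        x1, x0 = X[col][y == 1], X[col][y == 0]
        if len(x1) and len(x0) and (x1.min() >= x0.max() or x0.min() >= x1.max()):
            return col
    return None


def fit_logistic(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome_col: str = "outcome",
) -> FitResult:
    """Fit a binary logistic regression by maximum likelihood.

    Rows with a missing value in any model column are dropped.  Raises
    :class:`SeparationError` (naming the separating variable when one
    covariate alone explains the separation) or
    :class:`ConvergenceError` with the iteration count on failure.
    """
    variables = list(variables)
    cols = variables + [outcome_col]
    data = cohort[cols].dropna()
    y = _outcome_vector(data, outcome_col)
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    X = data[variables].astype(float)
    constant = [c for c in variables if X[c].nunique() <= 1]
    if constant:
        raise ValidationError(f"constant columns cannot be fitted: {constant}")
    Xc = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, Xc).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        culprit = _separating_variable(X, y)
        detail = f" (separating variable: {culprit})" if culprit else ""
        raise SeparationError(f"perfect separation detected{detail}") from exc
    except np.linalg.LinAlgError as exc:
        culprit = _separating_variable(X, y)
        detail = (
            f" (separating variable: {culprit})"
            if culprit
            else " ((quasi-)separation by a covariate combination, or collinearity)"
        )
        raise SeparationError(
            f"information matrix singular during IRLS{detail}"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"IRLS did not converge in {res.mle_retvals.get('iterations')} iterations"
        )
    names = ["intercept"] + variables
    params = dict(zip(names, np.asarray(res.params, dtype=float)))
    bse = dict(zip(names, np.asarray(res.bse, dtype=float)))
    pvalues, ors, cis = {}, {}, {}
    for name in names:
        or_, ci, p = wald_summary(params[name], bse[name])
        ors[name], cis[name], pvalues[name] = or_, ci, p
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvalues,
        odds_ratios=ors,
        conf_int=cis,
        converged=True,
        iterations=int(res.mle_retvals.get("iterations", 0)),
        llf=float(res.llf),
        nobs=int(res.nobs),
    )


def stepwise_select(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    alpha_stay: float = 0.10,
    direction: str = "backward",
    outcome_col: str = "outcome",
) -> tuple[list[str], FitResult]:
    """Stepwise screening of candidate predictors on Wald p-values.

    ``backward`` starts from the full model and repeatedly drops the
    least significant variable with p >= ``alpha_stay`` until all
    retained variables pass.  ``forward`` adds, at each round, the
    candidate with the smallest p below ``alpha_stay`` in the enlarged
    model.  Ties break on candidate order, so the procedure is
    deterministic given the data.

    An empty final set is reported with a warning and an intercept-only
    ``FitResult`` (fitted event log-odds only).
    """
    candidates = list(candidates)
    if direction not in ("backward", "forward"):
        raise ValidationError(f"unknown stepwise direction {direction!r}")
    if direction == "backward":
        selected = list(candidates)
        while selected:
            res = fit_logistic(cohort, selected, outcome_col)
            worst = max(selected, key=lambda v: res.pvalues[v])
            if res.pvalues[worst] < alpha_stay:
                return selected, res
            selected.remove(worst)
    else:
        selected = []
        while True:
            best, best_p, best_res = None, alpha_stay, None
            for cand in candidates:
                if cand in selected:
                    continue
                res = fit_logistic(cohort, selected + [cand], outcome_col)
                if res.pvalues[cand] < best_p:
                    best, best_p, best_res = cand, res.pvalues[cand], res
            if best is None:
                break
            selected.append(best)
        if selected:
            return selected, fit_logistic(cohort, selected, outcome_col)

    warnings.warn("stepwise screening retained no variables; returning intercept-only fit")
    data = cohort[[outcome_col]].dropna()
    y = _outcome_vector(data, outcome_col)
    p = float(np.mean(y))
    n = len(y)
    if p in (0.0, 1.0):
        raise ValidationError("both outcome classes must be present")
    intercept = float(special.logit(p))
    se = math.sqrt(1 / (n * p * (1 - p)))
    or_, ci, pval = wald_summary(intercept, se)
    return [], FitResult(
        params={"intercept": intercept},
        bse={"intercept": se},
        pvalues={"intercept": pval},
        odds_ratios={"intercept": or_},
        conf_int={"intercept": ci},
        converged=True,
        iterations=0,
        llf=float(n * (p * math.log(p) + (1 - p) * math.log(1 - p))),
        nobs=n,
    )


def derive_point_system(
    fit: FitResult,
    category_templates: Sequence[RiskFactorSpec],
    B_rule: Callable[[FitResult], float] | None = None,
) -> PointSystem:
    """Turn fitted coefficients into an integer point system.

    ``category_templates`` supply the clinical intervals, representative
    values and deviation modes; the fitted coefficient replaces each
    template's beta.  The default ``B_rule`` sets the points base
    constant to five times the maternal-age coefficient, so five years
    of maternal age cost one point.
    """
    templates = {t.name: t for t in category_templates}
    missing = [v for v in fit.variables if v not in templates]
    if missing:
        raise SpecificationError(
            f"no category definitions for fitted variables: {missing}"
        )
    if B_rule is None:
        if "ma" not in fit.params:
            raise SpecificationError(
                "default B rule needs a maternal-age coefficient; supply B_rule"
            )
        B = 5 * fit.params["ma"]
    else:
        B = B_rule(fit)
    if not B > 0:
        raise SpecificationError(f"derived points base constant must be > 0, got {B}")
    specs = [replace(templates[v], beta=fit.params[v]) for v in fit.variables]
    return build_point_system(specs, B)


def estimate_risk_curve(
    intercept: float, B: float, totals: Sequence[int]
) -> RiskTable:
    """Analytic approximation of risk per total score.

    Models the estimated risk as ``expit(intercept + B * total)``: one
    point is worth ``B`` on the log-odds scale by construction of the
    points formula.  This is an analytic approximation — the published
    risk column is a fixture of record, not reproduced by any constant
    slope — and is labelled as such wherever it is reported.
    """
    if not B > 0:
        raise SpecificationError(f"B must be > 0, got {B}")
    totals = list(totals)
    rows = tuple(
        (int(t), float(100 * special.expit(intercept + B * t))) for t in totals
    )
    return RiskTable(rows=rows)


def calibrate_risk_intercept(table: RiskTable, B: float) -> float:
    """Least-squares intercept of the analytic risk curve on a table.

    Minimises ``sum_t (logit(risk_t) - (c + B t))^2`` over ``c``, whose
    solution is the mean logit residual.
    """
    totals = np.array([t for t, _ in table.rows], dtype=float)
    risks = np.array([r for _, r in table.rows], dtype=float) / 100
    return float(np.mean(special.logit(risks) - B * totals))
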