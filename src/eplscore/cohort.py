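"""Synthetic cohorts of first-trimester IVF-ET pregnancies.

The study data behind the published scoring system are not public, so
this module generates cohorts with the same statistical structure: one
row per intrauterine singleton pregnancy, scanned on days 27-29 after
embryo transfer, with a binary outcome (ongoing pregnancy vs. early
pregnancy loss at 12 weeks).

Two generative modes are provided:

``group_conditional``
    The outcome is drawn first (Bernoulli at the cohort prevalence,
    default 1926/13977) and each variable is then drawn from a truncated
    normal whose mean and SD are the published group summaries.  The
    early-loss group's embryonic heart rate is a two-part mixture — a
    point mass at 0 bpm (absent cardiac activity) plus a truncated
    normal for embryos with measurable activity — because no single
    truncated normal can have mean 42.4 bpm with SD 53.5 bpm on the
    non-negative half-line.

``logistic_generative``
    Covariates are drawn from pooled-population distributions and the
    outcome from a Bernoulli whose log-odds are linear in the six
    scoring variables.  This mode has known true coefficients, which
    makes it the right substrate for parameter-recovery experiments on
    the model-fitting stage.

Variables are drawn independently within outcome group by default (no
joint distribution is published); an optional Gaussian copula accepts a
user-supplied correlation matrix for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .scoring import SCORING_VARIABLES, ValidationError

__all__ = [
    "CohortConfig",
    "GenerativeModel",
    "GroupDistribution",
    "ZeroInflatedNormal",
    "TruncatedNormal",
    "DEFAULT_SEED",
    "DEFAULT_PREVALENCE",
    "generate_group_conditional",
    "generate_logistic",
    "generate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "COHORT_COLUMNS",
]

#: Cohort prevalence of early pregnancy loss: 1926 losses among 13,977
#: enrolled singleton pregnancies.
DEFAULT_PREVALENCE = 1926 / 13977

#: Default seed, fixed so that unconfigured runs are reproducible.
DEFAULT_SEED = 20160628

COHORT_COLUMNS = (
    "ma",
    "bmi",
    "duration",
    "hcg",
    "em",
    "gsd",
    "ysd",
    "el",
    "ehr",
    "iuh",
    "outcome",
)

#: Published group summaries (mean, SD) per variable and outcome group.
#: Units: ma years, bmi kg/m^2, duration years, hcg mIU/ml, em/gsd/ysd/el
#: mm, ehr bpm.
GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "ma": {"ongoing": (30.9, 4.5), "epl": (33.3, 5.4)},
    "bmi": {"ongoing": (21.8, 2.4), "epl": (22.1, 2.6)},
    "duration": {"ongoing": (4.0, 3.0), "epl": (4.4, 3.6)},
    "hcg": {"ongoing": (594.4, 301.7), "epl": (430.5, 283.9)},
    "em": {"ongoing": (12.6, 2.0), "epl": (12.3, 1.9)},
    "gsd": {"ongoing": (18.5, 3.6), "epl": (13.2, 4.8)},
    "ysd": {"ongoing": (3.6, 0.4), "epl": (2.6, 1.5)},
    "el": {"ongoing": (3.5, 0.9), "epl": (1.2, 1.6)},
    "ehr": {"ongoing": (114.5, 12.2), "epl": (42.4, 53.5)},
}

#: Intrauterine-hematoma rates per outcome group.
IUH_RATES = {"ongoing": 0.160, "epl": 0.1885}

#: Spread of the positive heart-rate component in the early-loss group's
#: zero-inflated mixture, bpm.  The mixture weight and positive-component
#: mean are then solved so the group mean/SD match the published 42.4 /
#: 53.5 bpm.
EPL_EHR_POSITIVE_SD = 30.0


class TruncatedNormal:
    """Normal(mu, sigma) truncated to [lower, upper], ppf-sampled.

    Sampling goes through the quantile function so that independent and
    copula-correlated draws share one code path and are reproducible
    bit-for-bit under a fixed seed.
    """

    def __init__(self, mean: float, sd: float, lower: float = 0.0, upper: float = math.inf):
        if not sd > 0:
            raise ValidationError(f"sd must be > 0, got {sd}")
        if not lower < upper:
            raise ValidationError(f"truncation bounds unordered: [{lower}, {upper}]")
        a, b = (lower - mean) / sd, (upper - mean) / sd
        self._dist = stats.truncnorm(a, b, loc=mean, scale=sd)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return self._dist.ppf(u)

    def mean(self) -> float:
        return float(self._dist.mean())

    def sd(self) -> float:
        return float(self._dist.std())


class ZeroInflatedNormal:
    """Point mass at zero mixed with a positive truncated normal.

    ``weight`` is the probability of an exact zero; the continuous
    component is Normal(mu, sigma) truncated to (0, inf).  Used for the
    early-loss group's embryonic heart rate, where a zero encodes absent
    cardiac activity.
    """

    def __init__(self, weight: float, mean: float, sd: float):
        if not 0 <= weight < 1:
            raise ValidationError(f"mixture weight must be in [0, 1), got {weight}")
        self.weight = weight
        self._positive = TruncatedNormal(mean, sd, lower=0.0)

    @classmethod
    def from_moments(
        cls, target_mean: float, target_sd: float, positive_sd: float = EPL_EHR_POSITIVE_SD
    ) -> "ZeroInflatedNormal":
        """Solve the mixture weight and positive-component mean so the
        mixture matches the target mean and SD exactly.

        With the positive component's spread fixed, the two moment
        equations determine the two remaining parameters; of the two
        algebraic roots the one with the larger positive mean is taken
        (measurable embryonic heart rates cluster near normal values,
        not near zero).
        """
        target_m2 = target_sd**2 + target_mean**2

        def residuals(p: np.ndarray) -> list[float]:
            w, mu = p
            comp = TruncatedNormal(mu, positive_sd, lower=0.0)
            m1 = comp.mean()
            m2 = comp.sd() ** 2 + m1**2
            return [(1 - w) * m1 - target_mean, (1 - w) * m2 - target_m2]

        # untruncated-moment starting point: the larger root for mu
        ratio = target_m2 / target_mean
        disc = ratio**2 - 4 * positive_sd**2
        if disc <= 0:
            raise ValidationError(
                "no zero-inflated mixture matches the requested moments with "
                f"positive-component sd {positive_sd}"
            )
        mu0 = (ratio + math.sqrt(disc)) / 2
        w0 = 1 - target_mean / mu0
        sol, info, ok, msg = optimize.fsolve(residuals, [w0, mu0], full_output=True)
        if ok != 1 or max(abs(r) for r in info["fvec"]) > 1e-6:
            raise ValidationError(f"mixture moment matching failed: {msg}")
        return cls(weight=float(sol[0]), mean=float(sol[1]), sd=positive_sd)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u)
        out = np.zeros_like(u, dtype=float)
        pos = u >= self.weight
        if self.weight < 1:
            rescaled = (u[pos] - self.weight) / (1 - self.weight)
            out[pos] = self._positive.ppf(rescaled)
        return out


@dataclass
class GenerativeModel:
    """Linear log-odds model for the logistic generative mode.

    Default coefficients are the published per-unit log-odds of the six
    scoring variables; the default intercept is calibrated so the
    first-order event rate at the pooled covariate means equals the
    cohort prevalence.
    """

    intercept: float
    betas: dict[str, float]

    def __post_init__(self) -> None:
        missing = [v for v in SCORING_VARIABLES if v not in self.betas]
        if missing:
            raise ValidationError(
                f"generative model lacks coefficients for scoring variables: {missing}"
            )

    @classmethod
    def published(cls, prevalence: float = DEFAULT_PREVALENCE) -> "GenerativeModel":
        betas = {
            "ma": 0.0920,
            "gsd": -0.1150,
            "el": -0.2450,
            "ehr": -0.0340,
            "ysd": -0.1590,
            "em": -0.074,
        }
        return cls(intercept=_calibrated_intercept(betas, prevalence), betas=betas)


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort draw.

    ``group_params`` maps variable -> outcome group -> (mean, sd);
    ``truncation`` maps variable -> (lower, upper).  Defaults reproduce
    the published group summaries with all measurements truncated at
    zero.  ``correlation`` optionally supplies a Gaussian-copula
    correlation matrix over the continuous variables (order as in
    ``variables``); the default is independence.
    """

    n: int
    prevalence: float = DEFAULT_PREVALENCE
    mode: str = "group_conditional"
    seed: int = DEFAULT_SEED
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {v: dict(g) for v, g in GROUP_SUMMARIES.items()}
    )
    iuh_rates: dict[str, float] = field(default_factory=lambda: dict(IUH_RATES))
    truncation: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {v: (0.0, math.inf) for v in GROUP_SUMMARIES}
    )
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"cohort size must be >= 1, got {self.n}")
        if not 0 <= self.prevalence <= 1:
            raise ValidationError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if self.mode not in ("group_conditional", "logistic_generative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        for v, (lo, hi) in self.truncation.items():
            if not lo < hi:
                raise ValidationError(f"{v}: truncation bounds unordered: [{lo}, {hi}]")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.group_params)


def _calibrated_intercept(betas: Mapping[str, float], prevalence: float) -> float:
    """Intercept making the marginal event rate equal the prevalence.

    Solves ``E[expit(c + sum beta_v X_v)] = prevalence`` over the pooled
    covariate distributions.  The expectation is approximated on a fixed
    internal Monte Carlo sample (n = 200,000, its own constant seed), so
    the calibrated intercept is a deterministic function of the betas
    and the target prevalence, independent of any cohort seed.
    """
    rng = np.random.default_rng(190733)
    n = 200_000
    lin = np.zeros(n)
    for v, beta in betas.items():
        mean, sd = _pooled_params(v, prevalence)
        lin += beta * TruncatedNormal(mean, sd, 0.0).ppf(rng.random(n))

    def rate_gap(c: float) -> float:
        return float(np.mean(special.expit(c + lin))) - prevalence

    return float(optimize.brentq(rate_gap, -30.0, 30.0, xtol=1e-10))


def _pooled_params(variable: str, prevalence: float) -> tuple[float, float]:
    """Prevalence-weighted pooled mean and SD of a variable.

    The pooled variance is the weighted within-group variance plus the
    between-group component.
    """
    m1, s1 = GROUP_SUMMARIES[variable]["epl"]
    m0, s0 = GROUP_SUMMARIES[variable]["ongoing"]
    p = prevalence
    mean = p * m1 + (1 - p) * m0
    var = p * s1**2 + (1 - p) * s0**2 + p * (1 - p) * (m1 - m0) ** 2
    return mean, math.sqrt(var)


def _marginal(config: CohortConfig, variable: str, group: str):
    """The sampling distribution of one variable in one outcome group."""
    mean, sd = config.group_params[variable][group]
    lo, hi = config.truncation.get(variable, (0.0, math.inf))
    if variable == "ehr" and group == "epl":
        return ZeroInflatedNormal.from_moments(mean, sd)
    return TruncatedNormal(mean, sd, lo, hi)


def _uniforms(rng: np.random.Generator, n: int, k: int, correlation: np.ndarray | None) -> np.ndarray:
    """n-by-k uniforms: independent, or Gaussian-copula correlated."""
    if correlation is None:
        return rng.random((n, k))
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (k, k):
        raise ValidationError(f"correlation matrix must be {k}x{k}, got {corr.shape}")
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T
    return stats.norm.cdf(z)


def generate_group_conditional(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort by outcome group.

    The outcome is Bernoulli(prevalence); conditional on the group, each
    variable follows its configured truncated normal (or, for the
    early-loss heart rate, the zero-inflated mixture).  Identical
    configurations and seeds yield bit-identical cohorts.
    """
    if config.mode != "group_conditional":
        raise ValidationError(f"config.mode is {config.mode!r}, not 'group_conditional'")
    rng = np.random.default_rng(config.seed)
    n = config.n
    variables = config.variables
    epl = rng.random(n) < config.prevalence
    u = _uniforms(rng, n, len(variables), config.correlation)
    data: dict[str, np.ndarray] = {}
    for j, v in enumerate(variables):
        col = np.empty(n)
        for group, mask in (("epl", epl), ("ongoing", ~epl)):
            if mask.any():
                col[mask] = _marginal(config, v, group).ppf(u[mask, j])
        data[v] = col
    u_iuh = rng.random(n)
    rate = np.where(epl, config.iuh_rates["epl"], config.iuh_rates["ongoing"])
    data["iuh"] = (u_iuh < rate).astype(int)
    data["outcome"] = np.where(epl, "epl", "ongoing")
    return pd.DataFrame(data, columns=list(COHORT_COLUMNS))


def generate_logistic(config: CohortConfig, model: GenerativeModel | None = None) -> pd.DataFrame:
    """Draw covariates from pooled distributions, outcomes from a
    logistic model.

    The event indicator is Bernoulli(expit(intercept + sum beta_v x_v))
    per record, so the true coefficients are known exactly — the mode
    exists to test whether the fitting stage recovers them.
    """
    if config.mode != "logistic_generative":
        raise ValidationError(f"config.mode is {config.mode!r}, not 'logistic_generative'")
    if model is None:
        model = GenerativeModel.published(config.prevalence)
    rng = np.random.default_rng(config.seed)
    n = config.n
    variables = config.variables
    u = _uniforms(rng, n, len(variables), config.correlation)
    data: dict[str, np.ndarray] = {}
    for j, v in enumerate(variables):
        mean, sd = _pooled_params(v, config.prevalence)
        lo, hi = config.truncation.get(v, (0.0, math.inf))
        data[v] = TruncatedNormal(mean, sd, lo, hi).ppf(u[:, j])
    linpred = model.intercept + sum(
        beta * data[v] for v, beta in model.betas.items()
    )
    prob = special.expit(linpred)
    epl = rng.random(n) < prob
    pooled_iuh = (
        config.prevalence * config.iuh_rates["epl"]
        + (1 - config.prevalence) * config.iuh_rates["ongoing"]
    )
    data["iuh"] = (rng.random(n) < pooled_iuh).astype(int)
    data["outcome"] = np.where(epl, "epl", "ongoing")
    df = pd.DataFrame(data, columns=list(COHORT_COLUMNS))
    df.attrs["event_probability"] = prob
    return df


def generate_cohort(config: CohortConfig, model: GenerativeModel | None = None) -> pd.DataFrame:
    """Dispatch on ``config.mode``."""
    if config.mode == "group_conditional":
        return generate_group_conditional(config)
    return generate_logistic(config, model)


# ---------------------------------------------------------------------------
# CSV round trip

_REQUIRED = ("ma", "em", "gsd", "ysd", "el", "ehr", "outcome")


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as CSV; missing optional covariates stay blank."""
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def cohort_from_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, validating every row.

    Malformed rows raise a :class:`ValidationError` naming the 1-based
    data row and the offending column.  A header-only file yields an
    empty cohort.
    """
    df = pd.read_csv(path, dtype={"outcome": "string", "iuh": "float64"})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file lacks required columns: {missing}")
    for col in ("ma", "em", "gsd", "ysd", "el", "ehr"):
        values = df[col]
        bad = values.isna() | ~np.isfinite(values.astype(float)) | (values < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(
                f"row {row}, column {col!r}: invalid value {values.iloc[row - 1]!r} "
                "(scoring variables must be finite and non-negative)"
            )
    bad_outcome = df["outcome"].notna() & ~df["outcome"].isin(["ongoing", "epl"])
    if bad_outcome.any():
        row = int(np.flatnonzero(bad_outcome.to_numpy())[0]) + 1
        raise ValidationError(
            f"row {row}, column 'outcome': invalid value {df['outcome'].iloc[row - 1]!r}"
        )
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["outcome"] = df["outcome"].astype(object).where(df["outcome"].notna(), None)
    return df[list(COHORT_COLUMNS)]
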