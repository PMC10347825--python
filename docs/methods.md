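# Methods

## The points system

The score is a Sullivan/Framingham-style conversion of a binary
logistic regression into integers. For factor *i* with per-unit
log-odds coefficient βᵢ, category *j* with representative value *W*ᵢⱼ
and reference value *W*ᵢREF (the base category's representative value),

    Points_ij = round( βᵢ (W_ij − W_iREF) / B ),  B = 5 β_MA = 0.46,

so one point is worth B on the log-odds scale and five years of
maternal age cost one point. Rounding is **half away from zero**: the
maternal-age "≥40" category has a raw value of exactly 1.5 and must
round to 2 points, which banker's rounding would not give. Raw values
are pre-rounded to 9 decimals before the half-test so binary float
noise cannot flip an exact half.

Yolk sac diameter uses **absolute-deviation scoring**
(|βᵢ|·|W−W_REF|/B): its risk is U-shaped, with both small and large
yolk sacs abnormal, so deviations on either side of the reference earn
non-negative points. All other factors are scored with the signed
deviation.

### Interval dialect

Printed category labels leave formal gaps at measurement resolution
("30–39" vs "≥40"; "2.1–6.3" vs ">6.3"). Categories are encoded as
half-open intervals [lower, upper) partitioning the real line, with
cuts at MA 30/40 years, GSD 9.0/13.0 mm, EL 2.0 mm, EHR 100/130 bpm,
YSD 3.00/5.00 mm, EM 10.0/15.0 mm. Where a label makes the *upper*
bound inclusive ("13.0–27.0" with ">27.0" above; "2.1–6.3" with ">6.3"
above), the cut is placed half a measurement resolution (0.05 mm) above
the printed bound — 27.05 and 6.35 mm — so a value recorded as 27.0 or
6.3 falls in the middle category and 27.1 or 6.4 above it. Explicit
"≥" labels own their boundary (130 bpm scores as "≥130").

Absent cardiac activity is encoded as EHR = 0 bpm (category "<100",
+5 points) and an absent embryo as EL = 0 mm ("<2.0", +2): the
early-loss group's published heart-rate summary (42.4 ± 53.5 bpm) is
only possible if zeros were measured values, not missing data.

### Risk table

The published risk-per-total table (totals −8…14) is encoded as a
canonical fixture; it is **not** reproducible as expit(c + B·t) with
any constant c (the implied intercept drifts by ~0.8 across the range),
and the source of those risks is unstated, so no analytic re-derivation
is attempted. `estimate_risk_curve` provides an explicitly labelled
analytic approximation expit(c + B·t), with c obtained by least squares
on the logit scale against a reference table (c ≈ −3.0 on the published
table); it is used only where a derived system's score range has no
published risks, never as ground truth. On loading, the fixture's
points are re-derived from the stored β, W and B values and verified
against the stored points column, so the shipped system is
self-consistent by construction.

## Synthetic cohorts

The study cohort (13,977 intrauterine singleton pregnancies, 1926
early losses, prevalence 0.1378) is not public; the generator emulates
its structure in two modes.

**Group-conditional.** Outcome ~ Bernoulli(prevalence); conditional on
the group each variable is a normal with the published group mean/SD,
truncated at zero (no negative measurements). Sampling goes through the
quantile function of the truncated marginal so independent and
copula-correlated draws share one code path and fixed seeds give
bit-identical cohorts. The early-loss heart rate is a **two-part
mixture**: a point mass at 0 bpm plus a truncated normal for embryos
with measurable activity — no single truncated normal on [0, ∞) can
have mean 42.4 with SD 53.5. The positive component's SD is fixed at
30 bpm (a plausible spread from bradycardic to normal rates in failing
pregnancies); the mixture weight and positive mean are then solved from
the two moment equations at configuration time (solution: 58% zeros,
positive component ≈ N(101.0, 30) truncated at 0). Intrauterine
hematoma is Bernoulli per group (16.0% ongoing, 18.85% loss).

**Logistic-generative.** Covariates are drawn from pooled-population
truncated normals (prevalence-weighted mean; variance = within +
between group), and the outcome from Bernoulli(expit(c + Σβx)) with the
published six coefficients as defaults. The default intercept is
calibrated so the marginal event rate equals the cohort prevalence, by
root-finding on a fixed-seed internal Monte Carlo sample of the linear
predictor (n = 200,000); a first-order intercept at the covariate means
would give ~0.20 instead of 0.1378 because of the nonlinearity of the
logistic mean. This mode has known true coefficients and exists for
parameter-recovery testing of the fitting stage.

**What the generator does not model.** Variables are independent
within outcome group (no covariance structure is published); an
optional Gaussian copula accepts a user correlation matrix but defaults
to independence. There is no gestational-age progression, no twins, no
loss to follow-up. Consequences: the synthetic cohorts *overstate*
multivariate separation — the published system's AUC on a
group-conditional cohort is ≈ 0.94 versus the study's real-data 0.884 —
so passing tests demonstrate correctness of the machinery, not
real-world discrimination. The group-conditional mode also does not
follow the fitted logistic model, so coefficient recovery is only
meaningful in the logistic-generative mode.

## Model fitting and screening

Maximum likelihood is computed by `statsmodels.Logit` (Newton–Raphson,
i.e. IRLS; SEs from the observed information matrix; tolerance 1e-10,
max 100 iterations). Perfect or quasi-separation is reported as a
dedicated error naming the separating covariate when a single one
explains it; a singular information matrix is mapped to the same error
class. Odds ratios and CIs are Wald-based, exp(β ± 1.96·se), with
two-sided normal p-values — matching the style of the published
per-variable statistics.

Stepwise screening defaults to **backward elimination with
alpha_stay = 0.10** on Wald p-values: the final published model retains
YSD at p = 0.060, which a 0.05 rule would have dropped, so 0.10 is the
smallest conventional threshold consistent with the published
selection. Direction and threshold are configurable (a forward variant
is provided); ties break on candidate order, making selection
deterministic given the data. Null candidates survive backward
elimination at roughly the alpha_stay rate per variable — an inherent
property of p-value screening, so "exact recovery of the true subset"
is not a meaningful target; the tests check that true effects are
always retained and that null retention stays within its binomial band.

Point derivation from a fit replaces each clinical category template's
β with the fitted coefficient and sets B by rule (default 5·β_MA).
Because points are integers, small estimation error is absorbed by
rounding: at n = 50,000 the derived table matches 18–19 of the 19
published point values in every tested replicate. Under the default B
rule the maternal-age points are *invariant* to estimation error (the
β_MA in numerator and denominator cancels: raw values ±8.5/5 and
7.5/5).

## Evaluation

A prediction is positive when total ≥ cutoff; this convention (not
">") reproduces the published extreme rows (sensitivity 100% /
specificity 0% at the minimum cutoff). Sensitivity, specificity, PPV,
NPV and accuracy are computed at full precision and rounded only for
presentation (2 d.p., half away from zero); a metric whose denominator
is empty is *undefined* — rendered as a dash, `null` in JSON — never
coerced to zero. AUC uses the Mann–Whitney midrank statistic
(ties count one half), cross-checked in tests against an O(n²)
pairwise oracle and scikit-learn's implementation. No AUC confidence
intervals are produced (the published CI method is unstated).

Known discrepancy: the published verification NPV (93.62%) is
inconsistent with the published verification counts
(5686/(5686+339) = 94.37%); the count-derived value is reported.

## Pipeline

The pipeline mirrors the study design: simulate → temporal train/verify
split (first 7261/13977 of records labelled year 2016, the rest 2017) →
stepwise fit on the training split → point derivation → performance
tables on both splits, with a category-by-category comparison of the
derived and published point tables. All artifacts are JSON carrying
seed, configuration hash and package version; no timestamps, so a rerun
with the same configuration is byte-identical. Default problem sizes
(13,977-record cohorts; 50 replicates of n = 50,000 in the recovery
experiment; 10–40 replicates in screening simulations) were chosen to
keep every Monte Carlo check several standard errors away from its
threshold while running in seconds to a couple of minutes.

## Numerical and degenerate-input choices

- Validation errors name the offending field, row or factor; cohort CSV
  parsing reports the 1-based data row and column of the first invalid
  cell.
- A cohort with a single outcome class, a constant covariate, an empty
  category partition (gap/overlap), a non-monotone risk table, or an
  out-of-range score lookup each raise typed errors rather than
  producing silent output.
- `prevalence = 0` (or a −∞ intercept) is a valid degenerate
  configuration producing an all-ongoing cohort; it is the downstream
  fit that refuses single-class data.
- Stepwise screening that eliminates every candidate warns and returns
  an intercept-only fit (event log-odds and its exact binomial SE).
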