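# Methods

## Problem and scope

A 24 h urine collection is the reference method for measuring daily sodium
and potassium excretion, but it is burdensome and error-prone; estimating
equations predict the 24 h totals from one casual spot specimen plus
demographics.  This package implements one such equation family developed
in stroke patients (sex-specific linear models for 24UNaV and 24UKV),
three published comparators (Kawasaki, INTERSALT, Tanaka), the specimen
quality-control rules used before modelling, the model-development step
(random 70/30 split, per-sex stepwise regression), and the agreement
statistics used to validate any of these formulas.  Because no
individual-level data are distributed, a synthetic-cohort generator stands
in for the data and is itself a first-class, tested component.

## Formula evaluation

All spot concentrations are mmol/L.  The new formulas use the Na/Cr and
K/Cr ratios with **both concentrations in mmol/L** — the published
coefficient table gives no units, but at the cohort means the ratio is
≈ 14.8 mmol/mmol, which makes the printed ratio coefficients contribute on
the scale of the outcome; an mg/L denominator would shrink the term by two
orders of magnitude.  Kawasaki and Tanaka divide by spot creatinine in
mg/L (molar mass 113.12 g/mol) before multiplying by the predicted 24 h
creatinine excretion (PrUCr24h, mg/day); INTERSALT keeps creatinine in
mmol/L.  Sodium amounts convert to grams of salt at 0.05844 g NaCl per
mmol Na.

Linear formulas can go negative for extreme covariates.  Outputs are
returned as-is with a warning flag, never clipped, and downstream metrics
consume them unchanged; clipping would silently distort the agreement
statistics.  Kawasaki is applied to casual daytime spot urine even though
it was derived for second-morning voids — that is how the formula is used
in the validation setting this package reproduces.  BMI is taken from the
record when present, otherwise derived from height and weight; a
discrepancy above 0.5 kg/m² between the two is treated as an input error.

## Specimen quality control

Five rules, applied in order: missed volume over 20 % of the total
(total = collected + missed, since the self-report describes urine that
never reached the containers; strict inequality), collected volume below
0.5 L, 24 h creatinine outside [4, 25] mmol/day (women) or [6, 30]
(men) with boundary values kept, then two-sided 3-SD screens on 24 h
volume and on spot creatinine.  The SD screens use mean and SD computed
once over the survivors of the first three rules — a single pass, no
iteration; the source protocol does not state the ordering, and this
choice is deterministic and easy to audit.  Records can accrue several
reason codes; the report always partitions the input exactly.

## Model development

The split draws a uniform random partition with training size
`round(n·fraction)` (banker's rounding); the historical 689/281 allocation
of 970 records is 71.0 %, not exactly 70 %, and is treated as an artifact
of the original software rather than a contract.  Stepwise selection uses
partial-F p values — equivalent to the squared coefficient *t* for a
single term — with entry 0.05 and stay 0.10 (the classic SPSS defaults),
iterating forward and backward passes until the term set stabilises, then
refits the retained terms by OLS (statsmodels).  Selection is optional in
`fit_paper_models`: the published term sets are fixed (sodium: age, BMI,
spot Na, Na/Cr; potassium: age, BMI, spot K, ln K/Cr, ln Na/Cr), so the
default is a plain OLS fit of exactly those terms, with stepwise available
as an option that reports — rather than errors on — any published term it
removes.  Candidates that would leave the standardized design with a
condition number above 1e10, or that are (near-)constant, are refused with
a warning.

## Agreement statistics

* **Mean bias** — mean(estimated − measured) with a t-based 95 % CI and a
  two-sided paired *t* test.  Zero-variance differences collapse the CI to
  a point; the p value is then 1 (exact agreement) or 0.
* **Pearson r and formula comparison** — correlations of two formulas with
  the same measured series are dependent and overlapping; the difference
  is tested with the Hittner–May–Silver modification of Dunn–Clark's z
  (the default of the cocor toolbox), using the back-transformed average
  correlation.  The covariance term can exceed its admissible range when a
  correlation sits at ±1; it is capped so the boundary case yields an
  extreme z instead of a crash.  A 10 000-resample bootstrap of the
  correlation difference serves as the oracle in the test suite.
* **ICC(A,1)** — two-way model, single measures, absolute agreement,
  computed from the two-way ANOVA mean squares with k = 2 raters
  (measured, estimated); the CI is the McGraw–Wong F-based procedure.
  Unlike Pearson's r, it penalises systematic offsets — adding a constant
  to the estimates leaves r untouched and strictly lowers the ICC.  The
  implementation is checked against an independent brute-force ANOVA and
  against pingouin's ICC(A,1) row.
* **P30 and cutoff proportions** — share of pairs with
  |est − meas| / meas ≤ 0.30 (boundary inclusive; "within" is read as
  inclusive throughout), plus general relative/absolute cutoff curves.
  Default companions: ±10 % relative, and ±17.1 mmol/day (Na) /
  ±12.8 mmol/day (K) absolute.
* **Bland–Altman** — bias ± 1.96·SD limits (the conventional plot
  multiplier, not a t quantile), differences oriented estimated − measured,
  with (mean, difference) pairs exported for plotting.

Significance is two-sided at 0.05 with no multiplicity adjustment,
matching standard practice in these validation tables.  Records whose
measured value is not strictly positive are dropped per analyte (relative
differences are undefined for them) and every row reports its effective n.

The Fisher-z sample-size calculation
(`n = ((z_{1−α/2}+z_{power})/atanh r)² + 3`, inflated by the expected
exclusion rate) gives 110 pairs for r = 0.32, α = 0.05, power = 0.90 and
10 % exclusions.  A figure of 435 pairs has circulated for these same
inputs from proprietary software whose configuration is unknown; the
standard formula implemented here does not reproduce it.

## Synthetic cohorts

The generator emulates the published cohort summary: 54.7 % male; age
64.53 ± 7.87 y on [40, 90]; BMI 24.85 ± 3.44 kg/m² on [15, 45]; spot Na
131.85 ± 62.88 mmol/L (> 5); spot K 55.79 ± 36.09 mmol/L (> 2); spot Cr
log-normal moment-matched to 8.93 ± 5.60 mmol/L (the positivity constraint
with that coefficient of variation implies right skew); 24 h volume
1.60 ± 0.60 L.  Truncated-normal marginals are moment-matched: the
underlying (μ, σ) are solved so the *truncated* distribution hits the
target mean and SD — with a binding bound (spot K) the naive
parameterisation would shift the realized mean by almost 10 %.  The
published summary lists the volume SD as 6.00 for the entire cohort
against 0.62/0.56 in its subgroups; this is taken as a misprint for 0.60.

Measured outcomes are the new formulas' linear predictors plus Gaussian
noise.  The residual SD is either given directly or calibrated as
`σ = sd(linear predictor)·sqrt(1/R² − 1)` so that refitting attains target
multiple correlations R = 0.42 (male Na), 0.33 (female Na), 0.71 (K).
Outcomes are *not* floored by default: any binding floor biases the
refitted coefficients and correlations (a floor at 10 mmol/day costs the
potassium model roughly 0.10 in R and shrinks the male spot-Na coefficient
from 0.229 to ≈ 0.19), so positivity is traded away in favour of an exact
linear data-generating process; an optional rejection floor exists for
users who need strictly positive outcomes and accept the distortion.
Consequently a few per cent of synthetic potassium outcomes are
non-positive, and validation drops them per analyte — which also induces a
small negative bias in synthetic bias estimates (the filtered lower tail).

Choices that are deliberately *not* fidelity targets: heights
(Normal(165, 8) cm men, Normal(155, 7) cm women) exist only to exercise
the anthropometric creatinine sub-models; weight is derived from BMI and
height; 24 h creatinine is truncated normal inside the QC plausibility
bands (9.3 ± 2.2 men, 6.6 ± 1.6 women, population-weighted mean ≈ 8.0);
clean day volumes are floored at the 0.5 L QC minimum so threshold rules
fire only on injected contamination; covariates are drawn independently
(no covariance structure is published).  Because of that independence the
synthetic agreement tables do not — and should not — match any published
validation table; what passing tests demonstrate is the correctness of the
pipeline, the metrics and the recovery of generating parameters, not
real-data performance.  Contamination injects QC violations (at most one
rule per record) at configurable rates, far enough outside the clean
distributions that every injected violation is caught.

## Numerical and reproducibility notes

* One integer seed drives everything — cohort draw, noise, split — through
  `numpy.random.default_rng`; pipeline reruns at a fixed seed are
  byte-identical, and every run log records the seed and a config hash
  that identifies the analysis (not its output path).
* Problem sizes used by the checks: parameter recovery averages 200
  replicates of n = 500 single-sex cohorts (mean coefficients accepted
  within 3 Monte-Carlo SEs); generator self-consistency fits n = 20 000
  cohorts over 3 seeds and accepts mean R within ±0.02 of target; the ICC
  oracle comparison runs 50 random instances at 1e−9 absolute tolerance.
* On clean synthetic cohorts the two 3-SD rules still clip ≈ 2 % of
  records — the log-normal spot-creatinine tail genuinely exceeds
  mean + 3 SD that often.  This is a property of the marginal, not a bug;
  the closure test asserts the threshold rules exclude nobody and the SD
  clip stays under 3 %.

## Known limitations

Single-day cross-section only: no day-to-day intra-individual variation,
no intervention arms, no covariate correlation structure.  The stepwise
procedure is the classical p-value-driven one (kept for fidelity to the
development recipe), with all its known inferential caveats; the reported
coefficient p values are not selection-adjusted.  INTERSALT has no
potassium equation, and no further published formulas (Mage, Toft, …) are
included.
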