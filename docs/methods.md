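# Methods

## Models

All models are linear-logistic in the two POSSUM score sums and, for
recalibrated models, an urgency indicator:

    ln[R/(1−R)] = β₀ + β_PS·PS + β_OS·OS + β_NE·NE,   NE = 1[non-elective]

Scores are validated against the loosest arithmetic bounds implied by the
grading scheme (12 factors and 6 factors, each graded 1/2/4/8): 12 ≤ PS ≤ 96
and 6 ≤ OS ≤ 48.  The original grading charts impose tighter caps on some
factors, but the toolkit consumes PS and OS as already-summed integers and
cannot reconstruct them, so only the arithmetic bounds are enforced.  Out of
range scores raise a validation error naming the offending field; passing
`strict=False` downgrades this to a warning for research inputs scored under
non-standard conventions.

The urgency coefficient of the packaged S-POSSUM constant is **+1.057 with
NE = 1 for non-elective surgery**.  Published coefficient tables for this
model family sometimes show the urgency row with the opposite sign, which is
consistent with the category having been reverse-coded (elective = 1) in the
fitting software; since emergency surgery carries several-fold higher
mortality, the risk-increasing orientation is the only one compatible with
the data the model describes.  `derive_recalibrated_model(reverse_urgency=True)`
reproduces the reverse coding; either way the fitted risk surface is
identical and the returned `RiskModel` is always normalised to NE = 1 for
non-elective.

Risks are never rounded internally; two-decimal, half-up rounding happens
only in the table renderers.

## Eligibility

Episodes flagged as having incomplete data or as not directly admitted to
the unit are excluded before any analysis.  An episode failing both checks
is counted once, under insufficient data, so the per-reason counts always
sum to the number excluded.

## Discrimination

The AUC is computed as the Mann–Whitney concordance over all
death/survivor pairs with ties scoring ½, implemented through midranks
(O(n log n)); this equals the trapezoidal area under the threshold-sweep
ROC curve exactly, and the test suite asserts that identity plus
equivalence with a brute-force all-pairs oracle to 1e-10.  The standard
error uses the Hanley–McNeil formula under the binegative-exponential
assumption — a pragmatic default recorded in the output metadata, since
the reported ± SE of published AUCs rarely states its method.  Qualitative
bands: AUC ≥ 0.9 excellent, 0.8–0.9 good to excellent, 0.7–0.8 acceptable,
below 0.7 poor, exactly 0.5 no discrimination.

## Calibration

**Banding.**  Equal-width bands are half-open `[i/k, (i+1)/k)` with the
final band closed at 1 (the printed "0–10 … 90–100" labels do not state
edge handling; half-open is the unambiguous convention).  Equal-expected
bands sort episodes by ascending risk and cut where cumulative expected
deaths first reach `j·(total E)/k`; a tie group sharing one risk value is
never split — when a cut would land inside it the whole group completes
the earlier band.  Empty bands are kept as zero rows for report fidelity
but excluded from the Hosmer–Lemeshow sum and its degrees of freedom.  An
occupied band with E ≤ 0 or E ≥ N (all-certain predictions) would make the
chi-square term undefined; such bands are merged into their predecessor
with a warning.  Fewer than 5 expected deaths per equal-expected band
triggers a warning, not an error.

**Hosmer–Lemeshow.**  Each band contributes the two-cell term
`(O−E)²/E + ((N−O)−(N−E))²/(N−E)`, algebraically `(O−E)²/(E(1−E/N))`.  The
default reference distribution is chi-square with **g − 2** degrees of
freedom (g = occupied bands), the convention of the original test for a
model fitted on the same data and the one used in published validation
tables (10 bands → df 8).  For a model specified *externally* — validated
on a cohort it was not fitted to — the correct null reference is
chi-square with **g** degrees of freedom: the band terms are then g
independent (approximately) standard-normal-squared deviations with no
fitted parameters absorbing two of them.  Simulation confirms this: under
a correctly specified external model, testing at df = g − 2 rejects a
nominal 5% test about 11% of the time, while df = g gives ≈5%.  `hl_test`
therefore defaults to g − 2 for comparability with printed tables and
accepts an explicit `df` argument; the type-I-calibration tests use
df = g.  Within-band risk heterogeneity makes the statistic slightly
conservative (the binomial variance Σp(1−p) is below E(1−E/N)); at the
granularity of ten deciles this effect is small.

**O:E ratios.**  The observed count is treated as Poisson and the expected
total as fixed, as for a standardised mortality ratio; the interval is the
exact (Garwood) Poisson interval for O, divided by E, with lower bound 0
at O = 0.  The method is recorded in report metadata because published
per-band O:E intervals in this literature are often irreproducible from
the printed counts (some are far narrower than any standard Poisson or
binomial interval allows); this package documents and coverage-tests its
own interval instead of imitating unstated methods.  Exact coverage of the
Garwood interval at E ≈ 50–450 is 95.2–95.7%.  When events are common
(per-episode risks well above a few percent), binomial outcome totals are
underdispersed relative to Poisson and the interval over-covers (≈98–99%
observed at mean risk 0.22); at the rare-event scale the package's default
cohort occupies (mean risk ≈3.5%), the Poisson approximation is accurate.

## Recalibration

`fit_logistic` maximises the binomial log-likelihood by Newton–Raphson
with step-halving (the step is halved until the log-likelihood does not
decrease, making the iteration monotone), converging when the
log-likelihood change or gradient max-norm falls below 1e-8, within 50
iterations.  Standard errors come from the inverse observed information at
the optimum; Wald z-tests give p-values and symmetric-in-log odds-ratio
confidence intervals (`exp(B ± z·SE)`).  Any coefficient exceeding 30 in
absolute value during iteration raises a separation error — bounded
reporting instead of silent divergence.  Newton–Raphson rather than IRLS
was chosen for reproducibility and direct oracle comparison; the two are
algebraically equivalent per iteration here, and the suite checks
agreement with an established GLM implementation to 1e-6 in coefficients
and standard errors.  The score equations at the optimum imply
Σŷ = Σy, so a refit is always calibrated-in-the-large on its own training
cohort (overall O:E exactly 1), and its in-sample Hosmer–Lemeshow test
should be near-null — both are asserted in the suite.  The refit uses
exactly the three predictors PS, OS and NE; specialty, though available in
the cohort schema, is deliberately not entered, matching the published
recalibration procedure this mirrors.

## Synthetic cohorts

The generator emulates the observable margins of a single-centre level 1
critical care ward cohort of 2552 post-operative episodes:

| quantity | default | basis |
|---|---|---|
| n (eligible) | 2552 | cohort size |
| raw n, incomplete, indirect | 3741, 690, 499 | pre-filter counts (flags drawn disjointly so the exclusion report is exact) |
| P(non-elective) | 0.245 | urgency mix |
| overall mortality | ≈3.45% | 88/2552 |
| elective / emergency mortality | ≈1.7% / ≈8.7% | urgency-stratified rates |
| mean POSSUM / P-POSSUM risk | ≈0.1375 / 0.0636 | expected-death totals 350.94 and 162.35 over 2552 |

PS and OS are drawn independently (a Gaussian-copula rank-correlation knob
is provided, default 0, since real scores likely correlate) from
discretised log-normals truncated to the valid ranges — PS: σ = 0.276,
median 20.4 (mean ≈21.4, SD ≈5.8); OS: σ = 0.658, median 7.85 (mean ≈12.0,
SD ≈6.5).  No score histogram is available for this population, so these
shapes were calibrated once against the two mean-predicted-risk margins
above and then frozen; right-skewed discrete distributions of this kind
are what surgical score data look like in practice.  Because absolute AUC
depends on the unknown score spread, simulated AUCs (~0.83 for the truth
model) are not a reproduction of any reported AUC; only qualitative
orderings (e.g. the true model out-discriminating an OS-only ranking) are
asserted.

Outcomes are Bernoulli with
`logit(p) = ln(λ) + slope · (truth-model logit)`.  The distortion acts on
the logit scale because a uniform odds multiplier λ is exactly the
miscalibration pattern observed when a model overpredicts at every decile;
`λ = slope = 1` makes the truth model perfectly calibrated.  The default
truth model carries POSSUM's PS/OS weights plus an urgency coefficient
β_NE = 2.1635: with score distributions shared across urgency groups, a
truth model without an urgency term cannot separate elective from
emergency mortality, so the separation enters through the truth model
rather than the score draw.  λ = 0.0581 against this augmented truth
yields the same overall shrinkage as λ ≈ 0.25 against plain POSSUM
(overall O:E vs POSSUM ≈ 0.25, vs P-POSSUM ≈ 0.54).

**What passing tests do and do not show.**  The simulator reproduces the
margins above, not patient-level structure: scores are (by default)
independent of each other and of urgency, specialty is decorative, and no
temporal drift, repeat admissions or within-patient correlation exist.
Pipeline tests on these cohorts therefore validate the *statistical
machinery* — banding, chi-square accounting, interval coverage, MLE
correctness, O:E recovery under known distortion — and not the clinical
fidelity of any particular published estimate.

## Problem sizes and numerical choices

Simulation-based checks use n = 2000 × 1000 replicates for type-I
calibration of the Hosmer–Lemeshow test, n = 50 000 for coefficient
recovery (each coefficient within 3 estimated SEs of truth), n = 10 000
for per-band coverage of a well-calibrated model, and 1000 Poisson draws
at E ≈ 88 for O:E interval coverage — sizes at which binomial/Poisson
sampling error is small relative to the tolerances asserted, chosen so the
full suite runs in well under a minute of simulation time.  Ties in risk
are handled explicitly everywhere they matter: midranks in the AUC,
whole-tie-group assignment in equal-expected banding.  Table renderers
round half-up to two decimals (coefficients to three); all stored values
are unrounded, and reports are reproducible number-for-number from the
stored values.

## Known limitations

- The grading of raw physiology and operative findings into factor scores
  is out of scope; PS and OS enter as integers.
- Morbidity prediction, length-of-stay and time-to-event outcomes are not
  modelled.
- DeLong AUC comparisons, ROC confidence bands, Spiegelhalter's z and the
  Brier score are not implemented (recalibration covers slope/intercept
  style miscalibration implicitly).
- Published per-band O:E confidence intervals of unstated provenance are
  not imitated (see above); only the point estimates are reproduced.
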