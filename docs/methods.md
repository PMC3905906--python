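# Methods

## The misclassification model

An individual's true leukocyte telomere length (LTL) declines from
baseline B to B − μ over a follow-up of T years, where μ = a·T and a is
the attrition rate (bp/yr, or T/S units/yr for relative qPCR measures).
Each measurement adds independent normal error with SD σ, assumed
identical across individuals and time points. The measured change (mean
of r_f follow-up replicates minus mean of r_b baseline replicates) is then

  ΔM ~ Normal(−μ, σ_d),  σ_d = σ·√(1/r_b + 1/r_f),

so the probability of an apparent gain — a true loser measured as longer
at follow-up — is P(ΔM > 0) = Φ(−μ/σ_d). The equal-replicate cases are
σ_d = σ√2 (single measurements) and σ_d = σ (duplicates); the general
√(2/r) form is the exact variance of a difference of two r-replicate
means, and reduces to both.

Assumptions worth keeping in view:

* **Normality of error.** Both tails of the normal extend to infinity, so
  some apparent gainers exist for *any* μ and σ; heavier-tailed real
  error would only increase them.
* **Errors independent between time points.** Running a participant's
  baseline and follow-up sample in the same batch or gel induces positive
  error correlation, which shrinks σ_d below the model's value; the model
  is conservative in that direction.
* **Error SD identical across individuals**, and no drift in assay
  calibration over the follow-up.
* Baseline level cancels out of the change, so the baseline TL
  distribution is irrelevant to the gainer probability under the fixed-
  and random-rate models alike.

## From CV to σ

Laboratories report a unitless coefficient of variation, σ/mean. Two
conversion conventions are used, both exposed as parameters:

* **Theoretical curves**: σ = CV × 7000 bp. 7 kb is a typical mean LTL in
  young adults; the curves are design guidance, not per-study statements.
* **Per-study predictions**: σ = CV × (LTL_baseline + LTL_followup)/2.
  The midpoint is the natural within-study estimate of the mean at which
  the CV was determined; `predict_study` also accepts `baseline` or a
  fixed number. μ uses the reported per-year change times T rather than
  the difference of the rounded level columns, because published tables
  round the two inconsistently.

T/S-ratio (qPCR) studies are handled identically in T/S units; no
conversion between T/S and bp is attempted without the source study's own
calibration.

## Random-effects extension

Let individual rates vary: a_i ~ Normal(μ_rate, σ_b). The measured change
is Normal(−μ_rate·T, √(σ_b²T² + σ_d²)), so

  P(gain) = Φ(−μ_rate·T / √(σ_b²T² + σ_d²)).

This is the minimal model adding between-individual rate variation to the
fixed-rate model; it reduces to it exactly at σ_b = 0, strictly exceeds
it for σ_b > 0 (some apparent gainers are then genuine biological
gainers), and tends to Φ(−μ_rate/σ_b) as T → ∞, when measurement error
has washed out. Negative drawn rates are permitted by default — they are
the biological gainers the extension exists to represent — with a
truncation flag for sensitivity analysis. Whether baseline level should
also be randomized is moot here: it cancels out of the change. σ_b is
estimated from individual-level changes by method of moments,
σ̂_b = √(max(0, s²_changes − σ_d²))/T with the n−1 sample variance,
clamped at zero when error explains all observed spread.

## Synthetic cohorts

`simulate_cohort` draws true baselines ~ Normal(baseline_mean,
baseline_sd), true rates ~ Normal(rate_mean, rate_sd), computes true
follow-up levels, and adds independent Normal(0, σ) error to every
replicate, using `numpy.random.default_rng(seed)`; identical (params,
seed) reproduce a cohort bit-for-bit. The simulator deliberately shares
the analytic model's abstractions — no age-dependence of attrition, no
between-time-point error correlation, no floor at zero TL (negative
values are allowed and logged) and no leukocyte-subset dynamics — so that
agreement between simulator and closed form validates the *derivation*,
not the realism of the assumptions. Passing tests therefore say nothing
about non-normal error or batch effects in real assays.

## Classification rules

Without a band, a gainer is a measured change strictly > 0 (ties have
probability zero; they fall to losers, fixed for determinism). Some
studies instead report a "maintainer" band: |change| < b% of *measured*
baseline — the only baseline those studies could compute — with boundary
ties assigned outward. Harmonisation across studies counts half of the
maintainers as gainers (a 46% maintainer fraction adds 23 points, 32%
adds 16). Confidence intervals for observed gainer proportions are exact
Clopper–Pearson (inverted binomial tails, via scipy's `binomtest`):
observed counts are small and published intervals are visibly asymmetric,
so asymptotic intervals are inappropriate. The CI method behind the
originally published intervals is unstated, so equality with them is not
asserted.

## Numerical choices

* Normal CDF/quantile via `scipy.stats.norm` (`sf`/`isf`); no series of
  our own.
* Reported percentages round half-away-from-zero (22.85 → 22.9), matching
  how the source tables print; Python's banker's rounding would differ on
  ties.
* `required_followup` inverts the curve in closed form,
  T = z_{1−target}·σ_d/a, exact to the precision of the normal quantile;
  targets ≥ 50% are rejected (unreachable under true attrition) as is a
  zero attrition rate.
* Degenerate σ_d = 0 raises rather than silently returning 0.
* One catalog row (a six-month study with a 0.001 T/S/yr change at CV 6%)
  computes to 49.6% where its source printed 50.0% — the change is
  indistinguishable from zero at the reported precision; the value is
  reported as computed, not coerced.

## Problem sizes

Monte-Carlo validations use 10⁶ individuals per parameter set (binomial
SE ≤ 0.05 percentage points at p ≈ 0.25), five to ten study
parameterisations, and 200 cohorts of n = 1000 for the σ_b recovery
check; these sizes put sampling noise well below every tolerance tested
while keeping the full suite to a few seconds on one core.

## Known limitations

* Inter- vs intra-assay CV is taken at face value from each study; the
  model does not arbitrate ambiguous reporting.
* DNA integrity/purity effects and batch design are outside the model.
* The catalog's observed gainer percentages inherit each study's own
  definitions (one study reports "stable or increased" jointly, another
  only >15% lengthening); the flags and notes columns carry these
  caveats, and no numeric claim is made about them.
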