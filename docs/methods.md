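# Methods

## Model

The Compound Rayleigh (CR) family, F(x; α, β) = 1 − (1 + x²/β)^(−α) for
x ≥ 0, is a two-parameter Burr-type lifetime distribution: X² follows a
Lomax (Pareto II) law with shape α and scale β.  Two structural facts
drive the whole package:

1. **Exponential reduction.**  V = ln(1 + X²/β) ~ Exponential(rate α).
   Under type-II censoring (the r smallest of n observed), the v's of a
   CR sample are the first r order statistics of n exponentials, so the
   shape MLE for known β is closed-form: α̂(β) = r / (Σ vᵢ + (n−r) v_r).
2. **Scale equivariance.**  x → cx with β → c²β leaves every vᵢ — hence
   α̂, the uniformized values û(i) and all three statistics — unchanged.
   One consequence (verified by simulation in the tests): for the
   β-known case the null distribution of each modified statistic does
   not depend on the generating α, so one table per (n, r) suffices.

All cdf/pdf/quantile evaluations run through `log1p`/`expm1`; this keeps
boundary fits with α in the thousands finite and monotone.

## Censored likelihood and estimation

The working log-likelihood is

    L(α, β) = r ln α − r ln β + Σ ln x(i) − (α+1) Σ vᵢ − (n−r) α v_r.

Two parameter-free constants of the exact censored log-density are
dropped: the combinatorial factor ln[n!/(n−r)!] and r ln 2 (absorbed
into a proportionality when the density product is formed).  The test
suite pins the exact offset against an independent product-form oracle;
reported log-likelihoods are comparable only within fixed (n, r).

The joint MLE uses **profile likelihood**, not a 2-D Newton iteration:
α is concentrated out in closed form, leaving the one-dimensional
profile Lp(β) = r ln α̂(β) − r ln β + Σ ln x(i) − r − Σ vᵢ, maximized by
a bounded search over ln β on [10⁻⁶, 10⁶] · median(x²) (xatol 10⁻¹⁰),
followed by a short Newton polish on the β-score.  Convergence is
declared when both dimensionless score components |s_α| and |β·s_β| fall
below 10⁻⁸ · r.  Profiling was chosen because a 1-D bounded search is
globally robust and needs no starting values, and the closed-form inner
step makes it as cheap as a Newton step.  Estimation requires at least
two distinct observed values; ties are otherwise permitted; input order
is irrelevant (samples sort on construction).

**Boundary fits.**  Small samples often have no interior maximum: the
profile increases monotonically toward the Rayleigh limit (α, β → ∞
with α/β fixed; empirically ~44% of CR samples at n = 5).  This is a
feature of the likelihood, not a numerical failure.  Such fits are
flagged (`boundary=True`, `converged=False`) but retained: the fitted
cdf converges to the limiting Rayleigh fit as the box grows, so the
statistics are insensitive to the exact bound.  The Monte Carlo engines
therefore redraw a replicate only on non-finite output (with an abort if
more than 1% of replicates need redrawing); discarding boundary fits
would visibly distort small-n null distributions.

## Critical values and conventions

The null simulation follows the estimate-then-test pipeline exactly:
draw a complete CR(n) sample by inverse transform, keep the first r
order statistics, re-estimate (α alone for the β-known case, both
parameters otherwise), evaluate the statistics at the estimates.
Default 5000 replicates; replicate sub-seeds are spawned
deterministically from the run seed, so identical configurations give
byte-identical CSV output.

Empirical quantiles use the ⌈p·B⌉-th ranked draw, ascending, without
interpolation — a reproducible, interpolation-free rule.  The default
convention is **upper**: the level-γ critical value is the (1−γ)
empirical quantile, and the test rejects for large statistics, the
standard direction for EDF tests.  A **lower** convention
(γ-quantile) is also implemented purely as an emulation mode for
comparing against published tables that tabulate the opposite tail; it
plays no role in the testing pipeline.  Generating parameters default to
α = 1, β = 0.5 (β = 0.5 being the conventional known-β table value; the
β-known null is α-invariant, and the both-unknown default is recorded in
the table metadata and configurable).

The central correctness property — replacing any comparison against
previously published table cells — is **size calibration**: fresh null
data tested against an independently generated γ = 0.05 upper critical
value rejects at 0.05 ± 0.015 (2000 + 2000 replicates) for every
statistic, both parameter cases, complete n ∈ {5, 20} and the censored
20(12) design.  This is asserted in the acceptance tests.

## Power study

Power cells re-run the same pipeline with samples drawn from an
alternative family — defaults: exponential with mean 1.5, gamma with
shape 1.5 and scale 2, and chi-square with 4 degrees of freedom — and
count rejections against a matching freshly generated table (same case,
reps and convention), keeping the experiment internally consistent.
The standard grid is n ∈ {5, 15, 30} complete and n(r) ∈
{5(3), 15(9), 30(22)} censored at level 0.05.  Asserted properties:
size equals level when the alternative is the CR family itself, and
power is nondecreasing from n = 5 to n = 30 for every
alternative/statistic (within twice the combined binomial standard
error).  Both parameter cases are supported; the case travels with the
table metadata.

## Bootstrap test

`gof_test` approximates the null of the *modified* statistics by a
parametric bootstrap that re-estimates the parameters in every replicate
(plug-in resampling from a fixed fitted model would target the wrong
null).  p-values use (1 + #{T* ≥ T_obs})/(B + 1), which avoids zero
p-values, and the critical value at the requested level is the
upper-tail quantile of the same draws, so the two decision modes agree
up to the 1/(B+1) grid.

## Synthetic data

All simulation input is generated by inverse transform from seeded
`numpy` generators (`PCG64` via `default_rng`), with per-replicate
`SeedSequence` spawning.  The generator emulates i.i.d. lifetimes under
type-II censoring — the design the theory addresses.  It does **not**
emulate covariates, random (type-I) censoring, ties from rounding, or
measurement error; passing tests therefore demonstrate correctness of
the estimators and Monte Carlo machinery under the stated design, not
robustness of the CR model on messy field data.

## Bundled data and reference-value discrepancies

Three small classic series are bundled for worked examples and
integration tests (March precipitation, n = 30; Sydney average daily
wind speeds, n = 30; chemotherapy survival times, n = 46).  The
precipitation series circulates with 29 legible values and a published
mean of 1.675 at n = 30; the 30th value is reconstructed from the sum
constraint (30·1.675 − 47.28 = 2.97) and flagged in the provenance
metadata.  With it, the published median 1.47 and extremes 0.32/4.75
are reproduced exactly, as is the wind-speed t-row (t = 13.349,
df = 29, mean 4.17, 95% CI 3.5311–4.8089).  The published variance
1.00123 and the moment-based skewness/kurtosis are *not* asserted: the
reconstruction-implied values differ in the third decimal and the
original definitional conventions are unknown.

Two reference checks fail honestly and deliberately remain failing:

- **Precipitation CR fit.**  Reference fitted values α̂ = 1.8, β̂ = 0.63
  with statistics 0.18/0.13/0.16 have circulated for this series.  The
  actual likelihood surface contradicts them: the profile MLE is
  α̂ = 5.036, β̂ = 15.287 (independently confirmed by fitting a Lomax
  law to x² with `scipy.stats.lomax.fit`), the log-likelihood at
  (1.8, 0.63) is ≈ 30 units worse, and no (α, β) pair on a broad grid
  reproduces the reference statistic triple.  The acceptance tests
  assert the reference values and fail; the package reports what the
  data and model actually give.
- **Chemotherapy CvM decision.**  The long-run bootstrap p-value of the
  CvM statistic on the chemotherapy data is 0.0500 to three decimals —
  exactly on the 5% boundary — so the accept/reject decision at finite
  bootstrap size is a coin flip.  KS (p ≈ 0.068) and AD (p ≈ 0.058) do
  not reject.  The acceptance test uses the suite-wide seed and records
  the marginal CvM rejection rather than selecting a seed that accepts.

## Problem sizes

Default scientific runs use 5000 table replicates and 10000 power
replicates.  The test suite uses 2000 + 2000 replicates for calibration
checks, 5000 for the α-invariance comparison, 2000 for power cells and
bootstrap decisions, and 200 replicates of n = 500 for parameter
recovery — sizes at which the asserted tolerances are comfortably
resolved by the binomial noise analysis given above.

## Known limitations

- Standard errors / information-based confidence intervals for (α̂, β̂)
  are out of scope; the package estimates points and tests fit.
- Only type-II right censoring is supported (no type-I or progressive
  schemes).
- The exponentiated-Rayleigh and Rayleigh comparative fits use the
  documented parameterizations above the `compare_fits` docstring; they
  exist for model ranking, not inference, and their fitted values carry
  no reference-value guarantees.
- The one-sample t-test on the wind-speed data is reproduced as a
  descriptive utility; a location test against zero is not evidence for
  or against the CR family and is not part of the goodness-of-fit
  machinery.
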