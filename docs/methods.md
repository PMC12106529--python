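# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `mesothresh`, and the points where the
package's computations are known to differ from the published figures
it re-derives.

## Cohort data model

All analyses operate on cohort *summaries* — one row per cohort — not
person-level data.  The built-in table holds six non-textile chrysotile
cohorts (mining and general industry).  Two redundancies in such tables
matter:

* `CE` vs `E × D`: consistent within 2 % for every built-in row.
* `excess_rate` vs `M / TM`: *not* always consistent.  Connecticut
  records 2 cases among 274 expected deaths (raw rate 0.73 %) against a
  published excess of 0.072 %, and Québec's raw 0.558 % is printed as
  0.54 %.  The package stores the published excess column verbatim,
  because the published model fits are only reproducible from that
  column; `validate_consistency` surfaces the disagreements as warnings
  rather than silently recomputing.  The Connecticut gap looks like a
  factor-of-ten transcription slip in the source table, but that is a
  conjecture and nothing downstream assumes it.

## Conceptual three-factor model

`P(X) = (λX−1)(1−βX)αX` is a qualitative construction: it is never
fitted, and P is deliberately not clipped to [0, 1] — negative values
mean "below baseline".  Sign boundaries `(1/λ, 1/β)` and stationary
points (roots of `3βλX² − 2(λ+β)X + 1`) are returned in closed form
rather than numerically.  With the illustrative constants λ = 0.0072,
β = 0.00125, α = 0.000187, the negative region ends at 138.9 f/cc-years
and the curve peaks at 559.8 f/cc-years.  (The narrative description of
the peak as "about 600" is consistent with reading a plotted curve; the
analytic maximum is what the package reports.)

## Monte Carlo threshold classification

Study conditions: 10,000 iterations; per cohort and iteration,
`M ~ Poisson(excess_rate · TM)` and `CE ~ Uniform(0.7·CE, 1.3·CE)`,
with TM held at its point value; OLS of `100·M/TM` on `CE`; threshold
classification `A ≤ 0 and B > 0`; threshold statistics conditional on
the classified draws.  Decisions worth recording:

* **Poisson mean.** `excess_rate · TM` is the default rather than the
  raw case count, for internal consistency with the published excess
  column (the two disagree for Connecticut, and the choice changes the
  threshold fraction from ~78 % to ~16 %).  Both are available
  (`poisson_mean="excess" | "cases"`).
* **All-zero draws** fit `A = B = 0` and count as non-threshold
  (`B > 0` is strict).
* The 95 % CI of the mean threshold uses a normal approximation over
  the classified draws; percentiles are empirical.
* `mean_slope` averages all draws; the threshold-conditional mean slope
  is also reported, since conditioning on `A ≤ 0, B > 0` biases the
  slope upward.

**Known discrepancy.** The published summaries for this simulation
(72 % threshold fraction; mean threshold 25.6 f/cc-years, CI
24.2–27.1; percentiles 3.3 / 52.9; slope 0.0016) are not reproducible
from the stated data model.  This implementation obtains 77.8 %, mean
34.7, percentiles ≈ 5.9 / 60.5, and mean slope 0.00145 (all draws) /
0.00155 (threshold draws).  Alternative defensible conventions were
examined — Poisson means from raw counts, exposure jitter only, count
noise only, dropping single cohorts, TM-weighted regression — and none
reproduces the published pair (72 %, 25.6) jointly; the original
simulation (run in a spreadsheet add-in) is under-specified in its
source.  The corresponding acceptance tests are left failing rather
than tuned.

## Lifetime-risk model

The closed form is the exact integral of the cubed-lagged-time
incidence kernel; the ¼ coefficient is forced by the antiderivative and
is verified against numerical quadrature to 10⁻⁹ relative error in the
tests.  Negative increments are clamped to zero in prediction and
simulation.  At the published parameters (K_M = 0.0042×10⁻⁸, V = 85.9,
Th = 2.8, p = 1.5, L = 10) the Québec prediction is 0.00553 against an
observed 0.0054, and the predicted-vs-observed Pearson R across the six
cohorts is 0.9935.

Fitting profiles K_M analytically (risk is linear in K_M; the profile
estimate is clamped at zero) and scans V ∈ [70, 100] step 0.1 and
Th ∈ [0, min Eᵖ) step 0.01.  The upper Th bound reflects
identifiability: a threshold above every cohort's dose term predicts
zero everywhere.  SSE ties resolve to the first grid point scanned.
The SSE optimum on the built-in table (V ≈ 92.4, Th ≈ 0.02, R ≈ 0.993)
is slightly flatter than the published point — the objective surface is
nearly flat in (V, Th) at six data points, so the published parameters
should be read as one good point on a ridge, not a sharp optimum.

The 20-year-lag / p = 1.8 variant is implemented, but its published
coefficient set predicts risks orders of magnitude above the observed
column when inserted into the closed form (a likely misprint in the
source); only its unit conversion `2.0^(1/1.8) ≈ 1.5 f/cc` is treated
as reproducible.

Unit conversions: intensity threshold `Th^(1/p)` f/cc; cumulative
threshold = intensity × maximum working duration (default 45 years),
giving `2.8^(1/1.5) ≈ 2 f/cc` → 90 f/cc-years.

## Filter model

OLS of S on `(1, u, u²)`, `u = ln(CE+1)`, solved by normal equations.
The default response is the *unrounded* `1 − excess_rate` rather than
the 3-decimal printed survival column: it reproduces the published
coefficients (c = 0.972, a = 0.014, R = 0.91, R² = 0.83) distinctly
better.  The reported threshold uses the conventional formula
`exp(1 − a/(2b))`; the exact second-derivative root of the fitted curve
is `exp(1 − a/(2b)) − 1` (< 1 % different at the relevant scale) and is
exposed separately through `survival_second_derivative`.

**Known discrepancy.** The unrounded fit gives b = −0.0016968
(published −0.00168) and a threshold of 166.3 f/cc-years (published
162).  The published 162 cannot be recovered from the published
coefficients either (they give 175.3); the original unrounded
coefficients evidently differed in the fourth digit.  The acceptance
tests assert the published values and fail on these two quantities.

The single-anchor simulation draws c ~ U(0.9, 1) and a ~ U(−0.87, 1.3)
(the intercept range reflecting a plausible baseline survival band, the
slope range taken from the original filter-model applications), pins
b through the anchor identity `0.97 = c + 2.77a + 7.67b` (anchor
constants as published, = ln 16 and ln² 16), and summarizes
`exp(1 − a/(2b))` over draws.  Because the threshold explodes as
b → 0, draws with |b| < 10⁻¹² or threshold > 100 f/cc-years (the cap)
are discarded and counted.  At 10,000 draws this gives mean ≈ 11.0,
sd ≈ 3.0 against published 10.88 / 2.8; the mean agrees within the ±5 %
seed-to-seed stability of the simulation, the sd is ~7 % high —
plausibly a different (unstated) tail-handling rule in the original.

## Synthetic cohorts

The generators invert the two fitted data models: linear-threshold
excess (`r = max(0, B*(CE − T*))/100`, Poisson counts, optional ±30 %
uniform error applied to the *reported* exposure only — the Poisson
mean always uses the latent dose, mimicking exposure-assessment error)
and the lifetime-risk closed form.  Defaults mirror the study
conditions: six cohorts, slope 0.0016 %/f/cc-yr, threshold 25
f/cc-years, ±30 % exposure error.  What they deliberately do not
emulate: cohort heterogeneity in background rates, correlated exposure
errors, under-ascertainment of cases, or competing risks — so passing
recovery tests demonstrates estimator correctness under the assumed
data model, not robustness to real-world violations of it.

## Mineral extrapolation

Potency ratios ship as configuration data ({crocidolite: 364, amosite:
86, LAA: 21} relative to non-textile chrysotile) because the literature
offers two inconsistent routes — relative ratios vs absolute potencies
(e.g. crocidolite 0.52 % vs chrysotile 0.0011 % gives a ratio of ~473,
not 364) — and a user may prefer either.  `threshold_from_potency`
implements the absolute-potency route; the algebraic identity between
the two routes is property-tested.  Method-level chrysotile estimates
are combined by arithmetic mean; tremolite is reported as the LAA range
rather than a single value.

## Problem sizes and reproducibility

Default problem sizes (10,000 Monte Carlo iterations, 10,000 anchor
draws, 301 × ~336 grid points for the lifetime-risk fit) run in about a
second in total; tests use smaller sizes where a property does not need
the full run.  Every stochastic operation takes an explicit integer
seed into `numpy.random.default_rng`; identical seeds give bitwise
identical results, and `run_all` reports are byte-identical given the
same configuration.
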