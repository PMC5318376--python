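# Methods

This note documents the models and estimators implemented in `dendromort`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Growth

Ring widths (mm, measured to 0.01 mm in the Tucson convention) are converted
to basal area increment by accumulating radii from the pith offset:
R₀ = pith offset, Rₜ = Rₜ₋₁ + wₜ, BAIₜ = π(Rₜ² − Rₜ₋₁²) in cm². The
telescoping identity ΣBAI = π(R_last² − R₀²) holds to rounding error by
construction and is property-tested. When a core misses the pith, the
number of missing rings is the externally estimated distance to pith
divided by the mean width of the innermost k rings (default k = 5),
rounded half-to-even; the geometric distance estimate itself (arc fitting)
is an input, not something the pipeline computes.

Windowed metrics are computed on raw BAI — no detrending or chronology
standardisation, since level and trend are themselves the quantities of
interest:

* median (BAI is right-skewed, so the median is the location summary);
* CV = 100·SD/mean with the sample SD (n − 1; windows are short);
* trend = OLS slope of BAI on calendar year (cm² yr⁻¹);
* A1 = Pearson correlation of the (BAIₜ, BAIₜ₋₁) pairs inside the window.
  The pairwise definition (rather than the full-series autocovariance with
  a global mean) is the least surprising on 10–35-year windows; a
  zero-variance window reports A1 = 0 with a degeneracy flag.

Default windows are 1980–2014 (long), 2000–2014 (mid) and 2005–2014
(short); all windows are inclusive on both ends. Trees whose series end
inside a window (dead trees missing the final ring) use the available
years and carry a `partial` flag; fewer than 3 usable years is an error
and such trees are excluded from group summaries. The death year of a tree
is the year of its last formed ring.

Cross-dating quality control is a light surrogate: each series is
correlated against the mean of all others over common years (≥ 15 years
overlap required; default flag threshold r < 0.32). It catches gross
misdating — a series shifted by one year ranks lowest — but does not
replace segment-wise cross-dating validation.

## Competition and wood anatomy

Competition intensity is the distance-weighted basal area sum
CI = Σ BAⱼ/dᵢⱼ over the three nearest neighbours (cm² m⁻¹). Fewer
neighbours than requested yields a flagged result; zero distances are
invalid.

Vessels are classified earlywood (EW) when the lumen diameter strictly
exceeds 50 µm, else latewood (LW); the threshold is configurable and a
lumen exactly at the threshold is LW. The zone sampling windows are
tangential bands of 2 mm (EW) and 0.3 mm (LW); sampled zone area is the
window width times the zone's radial extent, which must be supplied per
ring (it cannot be recovered from vessel data alone). Per ring:
density = count/area (mm⁻²), percent lumen area = 100·Σlumen/area
(bounded at 100 with a warning — kernel of truth: a measured lumen cannot
exceed its zone), and the hydraulic diameter D_h = Σd⁵/Σd⁴ over all
vessels of the ring, which weights conduits by their Hagen–Poiseuille
conductivity; D_h ≥ the arithmetic mean for any non-uniform set (power-mean
inequality, property-tested). Per-tree summaries are unweighted means over
rings 1980–2013 (dead trees often lack the final ring, so the anatomy
window stops in 2013).

## Non-parametric tests

All tests are two-sided at α = 0.05, and no multiple-testing correction is
applied anywhere (per-year tests are reported with that caveat in their
metadata). Mann–Whitney U uses the exact null when n₁ + n₂ ≤ 20 without
ties, otherwise the midrank/tie-corrected normal approximation; Wilcoxon
signed-rank drops zero differences (counting them), uses the exact null for
n ≤ 25 without tied magnitudes, else the continuity-corrected
approximation. Exact p-values are verified against exhaustive enumeration
oracles for every configuration with total n ≤ 10.

The per-year living/dead comparison applies the paired Wilcoxon test to
living−dead BAI differences across couples, year by year (≥ 6 couples with
data required, else the year is unassessable), and flags years where
p < 0.05 *and* the median difference favours the living trees; contiguous
flagged years are reported as periods. Because the flag is directional,
the nominal null flag rate is ≈ 2.5%, which the generator's null
configuration reproduces.

Drought–growth response is the Pearson correlation of raw BAI with one
annual drought-index value per year (by convention a fixed month/time-scale
column, e.g. May of a 10-month SPEI) over two equally long, non-overlapping
periods: pre-dieback 1950–1981 and dieback 1982–2013. Trees covering less
than 80% of a period are flagged out. The two-sided critical r for the full
period length is computed from the t transform and reported alongside the
results, never hard-coded. Correlating raw (untrended) BAI means shared
trends can inflate r; this mirrors the analysis the pipeline reproduces and
is deliberately not "fixed".

## Logistic mortality models

Survival (alive = 1, dead = 0) is modelled by fixed-effects binomial GLMs,
logit p = α₀ + Σβₖxₖ, fitted by maximum likelihood (the reported mortality
probability is 1 − p̂). The candidate pool defaults to height, dbh, age, CI
and one BAI metric of each kind (median and CV on the short window, trend
on the mid window, A1 on the short window); every non-empty subset up to 4
terms is fitted exhaustively. Ranking uses AIC = −2logL + 2k (k counts the
intercept), ΔAIC to the best model, and Akaike weights over the evaluated
set (they sum to 1 by construction). Discrimination is the rank-based AUC —
the probability that a random survivor outranks a random dead tree, ties at
half credit, identical to the Mann–Whitney statistic scaled to [0, 1] — and
fit quality is McFadden's pseudo-R² = 1 − logL/logL₀ against the
intercept-only model with its closed-form likelihood. AUC is in-sample (no
cross-validation), matching the reporting convention of the analysis this
package reproduces. Non-convergent fits are excluded from the ranking;
perfect in-sample discrimination (AUC = 1) is flagged as separation, since
a monotone fitted score that splits the classes implies (quasi-)complete
separation and untrustworthy coefficients. Collinear predictor pairs can
optionally be barred from co-occurring (|r| threshold, off by default —
height and dbh covary and barring them is an analysis decision, not a
default).

## Drift–diffusion–jump metrics

Each log(BAI+1) series (default window 1970–2014, when BAI has stabilised
with age; ≥ 25 points required) is treated as a realisation of
dx = f(x)dt + g(x)dW + J dN at an annual step. Conditional moments of the
increments against the state, M₁, M₂ and the central moments M₂c, M₄c, M₆c,
are estimated by Nadaraya–Watson regression with a Gaussian kernel on a
100-point grid spanning the observed states; the bandwidth defaults to
0.3 × SD of the states (configurable — small enough to resolve the
plateau-vs-collapse state contrast of dieback series, large enough to keep
dozens of effective increments per grid point at n ≈ 44).

From the moments: drift = M₁, total variance = M₂, conditional variance =
M₂ − M₁² (the grid identity is exact by construction; negative estimates
are clipped to 0 and counted). Jumps are separated from diffusion by an
exact two-point moment match: conditional on the state, the increment
variance is modelled as two-valued — σ² with probability 1 − λ and
σ² + σ_J² with probability λ — whose first three moments
(E V = M₂c, E V² = M₄c/3, E V³ = M₆c/15) identify (σ², σ_J², λ) in closed
form through the spread and skewness of V. The familiar small-timestep
ratios (σ_J² from M₆/5M₄, λ from M₄/3σ_J⁴) are *not* used: at Δt = 1 year
they assign all variance to jumps even for exactly Gaussian increments
(their fourth-moment "jump" term, 3σ⁴Δt², is not negligible), collapsing
the estimated diffusion to zero on jump-free data. The jump terms are
activated only when a one-sided kurtosis test on the increments rejects
Gaussian tails at α = 0.01 (conservative, because short ecological series
produce noisy higher moments); otherwise λ = 0 and diffusion² = M₂c.
Validation against the simulation oracle (a random walk with known σ, jump
rate and jump size): on a jump-free walk of 2000 steps the mean diffusion²
lands within 15% of σ² with λ = 0; with jumps (rate 0.1, magnitude 5σ,
5000 steps) the recovered intensity is within 50% of truth and the
conditional variance exceeds the jump-free case.

Per-time-point trajectories evaluate the grid estimates at each observed
state, so the output time axis is the input years minus the final year.
Two aggregation modes exist: per-tree results summarised as ensemble bands
(each tree's trajectory standardized to [0, 1], then the median and the
10–90% and 40–60% quantile bands across ≥ 3 trees per year), and a pooled
cohort estimate in which all (state, increment) pairs of a cohort enter one
kernel regression — much lower estimator variance, evaluated along the
cohort's median state trajectory.

### Transition detection

The transition report gives (i) the year of maximum conditional variance,
(ii) the year of steepest decline of the (optionally smoothed) diffusion
trajectory, and (iii) a suggested start year for the growth-trend window of
the mortality models. The suggested start is the changepoint of a
flat-then-declining least-squares fit to the cohort state trajectory — the
growth level whose collapse drives the diffusion drop. Because living and
dead trees share the year-to-year climate signal, a wet/dry run can imitate
an onset; when a reference cohort (the living trees of the paired design)
is supplied, its trajectory is regressed out before the changepoint search,
which in simulation sharpens onset recovery from roughly half of replicates
within ±5 years to about 85%. Flat or monotonically rising diffusion yields
a no-transition report. The least-squares knot of a ramp fit slightly leads
a hard step; the steepest-decline year is the sharp-change locator.

## The synthetic-data generator

`simulate_site` emulates the paired study design so each downstream stage
can be validated against known ground truth. Per site it draws n couples
(default 24) of living/dead trees less than 20 m apart, with log BAI

log BAI_it = log L_i + log(1 − e^(−r·age_it)) + β_s·S_t + ε_it + δ_s·(t − t₀)₊

where L_i is a per-tree level (lognormal, median 2.6 cm², log-SD 0.4,
scaled by dbh), the age ramp has rate r = 0.04 yr⁻¹ (growth stabilised well
before 1970 at ages ≈ 145), S_t is a shared standardized AR(1) drought
index (φ = 0.3; positive = wet), ε is AR(1) noise (φ = 0.35, SD 0.25) and
the post-divergence term (t₀ = 2000) applies log 0.98 per year to dying
trees and log 1.013 to survivors. These defaults place group medians near
2–3 cm², CV near 35–45%, A1 near 0.3, BAI–index correlations near 0.5
(living; dead trees respond with β = 0.12 vs 0.20, making them less
drought-sensitive), and 2000–2014 trends near +0.04/−0.04 cm² yr⁻¹ —
the descriptive statistics of the emulated design. Heights are drawn
14.1 ± 4.4 m (living) vs 9.5 ± 2.4 m (dead), dbh 32.6 ± 4.4 vs
28.2 ± 4.9 cm, correlated with height within status (0.65 living, 0.35
dead). Death years are sampled with 70% mass on the final year and the
rest spread over 2007–2013; dead series truncate at the death year.
Neighbour tables are drawn identically for both statuses, so no
competition effect exists by construction.

Ring widths are back-computed from BAI and the target under-bark radius
(dbh/2 × 0.88), with the residual inner radius recorded as the pith
offset — so the BAI transform inverts the generator exactly (tested to
1e-8 relative). If a tree's simulated growth would imply a negative inner
radius, its level noise is redrawn (up to 8 attempts) before the stem is
allowed to come out thicker than drawn. Vessel tables cover the first 5
couples: per ring, Poisson counts at 8 (EW) and 170 (LW) vessels mm⁻²,
lumen diameters 265 ± 40 µm (EW) and 30 ± 8 µm (LW, +1.4 µm for dead
trees), truncated so classification at 50 µm is exact and total lumen
stays below the sampled zone area; rings narrower than 0.2 mm are skipped
as unmeasurable. One integer seed drives named substreams (drought,
attributes, growth, deaths, neighbours, vessels).

What the generator does **not** emulate: spatial autocorrelation of
mortality, release effects transmitted through the neighbour structure,
mechanistic hydraulics or carbon balance, age-dependent mortality, missing
rings or dating error, and measurement noise in heights/dbh. Passing tests
therefore demonstrate that the estimators recover the structure they
assume — not that real dieback data satisfy those assumptions. The
simulated mean ring width (~0.3 mm) is narrower than typical field values
because the negative-exponential age curve has no juvenile growth peak;
the unreached early growth is absorbed into the pith offset, which keeps
all BAI-level quantities calibrated while ring-width-level summaries
remain generator-specific.

## Validation problem sizes

The test suite validates at the following scales, chosen to give stable
Monte-Carlo estimates: null-model AUC over 50 replicates of 2000 trees;
dieback discrimination over 100 replicates of 24 couples; BAI conservation
over 1000 random series; exact-test enumeration for all sample-size
configurations with total n ≤ 10; DDJ recovery on walks of 2000 (jump-free)
and 5000 (with jumps) steps; transition detection over 100 replicate
cohorts; type-I error of the paired per-year test over 25 null-site
replicates; and 10,000-draw-scale rejection-rate checks for the
rank tests (2000 replicates in-suite).

## Known limitations

* The DDJ estimator needs dozens of points per series; at the 44 annual
  increments of a 1970–2014 window, per-tree estimates are qualitative and
  the pooled-cohort mode should be preferred for detection.
* Jump detection is gated globally per series, not per state; state-local
  jump regimes in long series would be diluted.
* The suggested trend-window start assumes one sustained decline; multiple
  partial collapses return the best single changepoint.
* In-sample AUC is optimistic (the null simulation averages ≈ 0.512 at
  n = 2000 with two fitted predictors, and more so at n = 48); comparisons
  between models of different complexity should lean on AIC/weights.
* The per-year paired test inherits the power of n ≈ 24 couples; with the
  generator's dbh-linked growth levels, a baseline living/dead level
  difference exists and pre-divergence years can be flagged — a property of
  the emulated design (dead trees already grew slightly less), not a bug.
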