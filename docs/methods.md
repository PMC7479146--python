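# Methods

## The lifespan model

Tree lifespan is operationalised as the conditional 95th-percentile age
given early growth: `log A_q = a + b·RW̄`, with `RW̄` the mean ring width
over the first 10 rings (mm yr⁻¹) and `b` (per mm yr⁻¹, or per relative
unit after species normalisation) the exponential decay constant of
lifespan with early growth. A high quantile is the right target because
ordinary regression of age on growth confounds the lifespan ceiling with
early- and intermediate-stage mortality; the 95th quantile of a large,
rigorously screened sample tracks the ceiling itself. Living-tree ages
proxy natural lifespans under this reading.

The fit minimises the pinball (check) loss at quantile q over
(RW̄, log A). We solve the standard linear-programming formulation
(HiGHS, sparse constraints) and then *polish* the solution: the optimum
of a two-parameter quantile regression is attained at a vertex, i.e. a
line through two data points, so the near-zero-residual support points
are enumerated and the exact interpolating line with the lowest loss is
returned, ties broken by smallest |b|. This makes small-sample fits
bit-reproducible and lets the solver agree exactly with an exhaustive
pairwise-line search. Significance of `b` is a seeded case bootstrap
(default 1000 resamples; two-sided p with the (k+1)/(n+1) correction)
because the slope's sampling distribution under quantile loss is not
usefully Gaussian at the sample sizes involved.

Percentiles throughout (binned empirical quantiles, resampling
thresholds) use the linear-interpolation (type-7) definition, since
"95th percentile" is otherwise ambiguous for integer ages.

Cross-species aggregation first rescales each tree by its species maxima
(RW̄/max RW̄, A/max A), then averages per-species decay constants with
cube-root-of-n weights — heavy enough to damp the 10³-fold sample-size
range between species, light enough that well-sampled species do not
drown out the rest.

## Screening rules and their boundary semantics

Sites need ≥ 20 trees and an age coefficient of variation
CV = sd/mean × 100 ≥ 10 % (sample sd, n−1): even-aged stands cannot
constrain a lifespan ceiling. Species flags: ≥ 30 trees for
species-level lifespan estimates; strictly more than 150 trees from ≥ 3
sites for within-species decay fits; archive sources additionally need
≥ 3 sites and ≥ 100 series. "Before 1900" (dead classification),
"lower than 10 %", and "more than 150" are strict; the minima are
inclusive. Duplicate cores (IDs equal up to the final character, after
stripping a trailing separator) are combined by per-age mean aligned at
the pith, merged age = longest member; the combination rule is
configurable to "first" since the source convention is not fixed.
Diameter is 2 × cumulative ring width — one core approximates a radius;
no bark or pith-offset correction is applied (problematic trees are
expected to be excluded upstream, and an exclusion hook exists for
that).

## Mortality from stand structure

Under stationarity the diameter distribution obeys, per 2-cm class,
`0 = I(D) − L(D) − deaths(D)`, so the annual rate is
`μ(D) = (I − L)/N` with I the ingrowth, L the growth-out, and N the mean
abundance. The same accounting over yearly age classes gives μ(A) (a
life-table hazard). Two parametric families are supported, with the
published black-spruce constants as defaults:

| family | form | defaults | threshold |
|---|---|---|---|
| diameter | 0 for D ≤ D₀, else b + k(D−D₀)⁴ | b = 0.025 yr⁻¹, k = 3×10⁻¹¹ yr⁻¹ mm⁻⁴ | D₀ = 91 mm (minimum coring diameter) |
| age | 0 for A ≤ A₀, else a + b·A | a = 0.021 yr⁻¹, b = 1.5×10⁻⁶ yr⁻² | A₀ = 74 yr (mean age at 91 mm) |

Hazards are annual death probabilities (Bernoulli per tree-year), capped
at 1; zero at and below the threshold because cored trees all survived
to the coring diameter, so the comparable simulated population must too.
Refitting is N-weighted linear least squares with the threshold fixed by
the sampling design — both families are then linear in their free
parameters. The quartic makes k ill-conditioned: it is identified almost
entirely by the sparse largest-diameter classes, so round-trip tests
require k only within a factor of two while b recovers to ±0.005 yr⁻¹.

## The cohort simulator

A 600-year sequence of annually seeded cohorts (1250 members at full
scale; 125 is the desk-scale default used by the shipped tests and the
acceptance script — same dynamics, ~10× less work). Each member is a
ring-width trajectory drawn with replacement from the trajectory set
(600 × cohort exceeds any realistic set size). Per year and tree: grow
the next ring, multiply by exp(λ(age)·δT(t)) when the stimulus is
active, update diameter (2 × cumulative realized widths — the boost
feeds the diameter the size-dependent hazard sees, which is the whole
trade-off mechanism), then draw the mortality lottery. The lottery runs
after the year's growth; a tree whose trajectory is exhausted (500 yr)
is removed without counting as a death.

The stimulus is δT(t) = 0.0221 °C yr⁻¹ × (t − 300) for the first 50
years, constant after — the observed Quebec warming rate over a 50-year
ramp — modulated by the age sensitivity

```
λ(A) = 1.32e-5·A² − 2.91e-3·A + 0.229   (A < 135 yr)
λ(A) = 0.07                              (A ≥ 135 yr)
```

(°C⁻¹), estimated by space-for-time substitution: per 10-year age band,
the log of a tree's mean ring width in the band is regressed on site
mean annual temperature; a quadratic in age is fitted to the band slopes
below the 135-yr knee and the plateau is the mean beyond it.
`estimate_lambda` reproduces this procedure on any series/site table;
the published constants ship as `PUBLISHED_LAMBDA`. A ring formed in a
tree's first year carries the age-0 sensitivity. The "fast-species"
scenario multiplies the whole trajectory set by 2 before the run (a
property of the set, not of the stimulus).

**Paired streams.** Baseline and treatment runs with the same seed must
differ only through the mechanism under study. Each year the simulator
draws the cohort's trajectory indices and then one uniform for *every
tree ever seeded*, alive or not, so the stream position is identical
across scenarios and the percent-change series are free of seed noise.
A consequence: the pre-stimulus death-rate *change* series is
identically zero, so the "2× pre-stimulus sd" lag detector would fire
immediately. When that sd is exactly zero the detector falls back to the
baseline run's own demographic noise — the sd of its smoothed death
rate over the 100 equilibrated pre-stimulus years, expressed in percent
of its mean.

**Trajectory extension.** Real cores are shorter than 500 yr; they are
extended with the per-age mean of the 10 oldest donors from the same
early-growth class (six equal-width classes over the pool's RW̄ range),
donors dropping out age-by-age, the last available mean held when all
are exhausted, and an empty class falling back to the global pool with a
warning. Synthetic trajectories are generated full-length directly (the
generator knows the true growth curve), so the simulation experiments do
not stack the extension approximation on top of the generator; extension
has its own tests.

Output series (mean living-tree ring width, stem death rate %,
75th-percentile age of trees dying each year, total basal area
Σ π(D/2)² of survivors) are stored raw; scenario summaries use a 10-yr
centred moving average, the window being configurable since the
appropriate smoothing is a presentation choice.

## The synthetic generator

The generator emulates a boreal conifer population in which maximum size
is a trait independent of growth speed:
`D(A) = Dmax·(1 − exp(−r·A))`, ring width = successive diameter
differences / 2, times stationary lognormal AR(1) noise (multiplicative,
keeping widths positive; tree growth is strongly autocorrelated).
Observation ages are uniform on [10, age at 0.99·Dmax] (capped at 600),
giving the uneven age structures the screening demands. Defaults are
anchored to printed black-spruce facts rather than fitted to anything:
Dmax ~ N(300 mm, 23 mm) truncated positive, so the 99th-percentile
attained size is ~353 mm; median r = −ln(1 − 91/300)/74 ≈ 0.0049 yr⁻¹,
so the average tree reaches the 91-mm coring threshold at age 74;
lognormal sdlog 0.55, so early growth spans ~0.2–3.2 mm yr⁻¹; AR(1)
coefficient 0.5 with noise sd 0.2; site MAT uniform over an 8 °C
gradient with a 10 %/°C multiplicative effect on r.

Two structural notes. First, realized early growth ≈ Dmax·r/2, which
mechanically couples it to Dmax with ρ ≈ σ_logDmax/σ_logRW̄ ≈ 0.14 even
though the *traits* r and Dmax are drawn independently — tests assert
trait independence and a weak (|ρ| < 0.15) realized correlation.
Second, the known-trade-off sampler used for parameter recovery draws
RW̄ ~ U(0.2, 3.2) and log A = a + b·RW̄ + log(U) − log(q) with
U ~ U(0,1): log is monotone, the q-quantile of log U is log q, so the
conditional q-quantile of log A sits exactly on the generating line.
That residual is *dense* near its upper quantile, so slope recovery is
far more precise than for field age data (mean absolute relative error
~2 % at n = 300, versus ~12 % reported for real data); recovery tests
bound the error rather than match that figure.

The stationary-stand generator seeds a constant number of recruits per
year, grows them deterministically along their curves, applies the
Bernoulli hazard, and after a one-lifespan burn-in tallies N, I, L per
2-cm class; total-count drift above 1 % per decade (estimated from two
30-yr windows) is rejected as non-stationary.

What passing tests show — and don't. The synthetic population has the
assumed structure by construction, so green tests demonstrate that the
estimators recover known truth under that structure, not that field data
satisfy it: real cores add pith offsets, missing rings, crossdating
error, climate signals, competition, and non-stationary recruitment,
none of which are emulated.

## Stratified and site-level analyses

Temperature classes are half-open 2 °C intervals anchored at the data
minimum; growth bands are equal-count quartiles (the trade-off is fitted
within temperature classes; the lifespan–temperature quantile slope is
fitted within growth bands — if the trade-off is direct, the first stays
negative and the second collapses to zero, which the generator-truth
test confirms). Sites too small for a maximum-age estimate are pooled
greedily: the smallest under-sized pool merges with its nearest
neighbour (haversine distance between count-weighted centroids) until
every pool has ≥ 30 trees. The pooling radius is unbounded by design;
with very sparse data everything may end in one pool, which is reported
rather than hidden. Fits with bootstrap p > 0.05 are flagged
non-significant rather than dropped.

The big-tree-bias experiment rebuilds an artificial population matching
a field diameter-frequency table: per 2-cm class, the observed count is
drawn with replacement from the trajectories that transit the class,
recording early growth and the age at entering the class. Scenarios fit
the trade-off on all classes, on classes at or above the 91-mm coring
threshold, and on the largest 10 % of draws. The threshold-weakening
direction reproduces under a field-realistic *declining* stem-size
distribution; feeding the trajectory set's own max-size histogram
instead (roughly bell-shaped) does not represent a field stand and can
reverse the sign.

## Known limitations

* **Population-mean growth gain.** The end-of-ramp mean-growth increase
  of a mixed-age stand is a ring-width-weighted average of
  exp(λ(A)·δT); its upper bound, attained only by an all-juvenile
  stand, is exp(λ(0)·1.105) − 1 ≈ 28.8 %. With the saturating
  growth-curve family anchored to the black-spruce facts above, the
  width–age profile is nearly flat over ages 0–100, the effective
  sensitivity is ~0.13 °C⁻¹, and the simulated gain is ~15 % (peak
  basal-area gain ~10 %). Reported figures near 29 % correspond to the
  juvenile upper bound, not to a population mean under this family;
  matching them would require a growth family whose ring-width mass is
  concentrated below age ~10.
* The simulator has no competition, self-thinning, recruitment response,
  or climate-dependent mortality: the hazard curves are fixed.
* The generator's single species, static site temperature, and
  noise-law choices are calibration conveniences, not claims about real
  ring data.
* The quartic hazard's curvature is only weakly identified from desk-
  scale stands (factor-of-two tolerance).
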