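# ringlife

Growth–lifespan trade-offs from tree rings, and what they imply for the
forest carbon sink.

Across and within tree species, individuals that grow fast when young tend
to die younger: maximum attainable size is a species trait roughly
independent of growth speed, so fast starters reach the high-mortality
large-diameter range sooner. If warming or CO₂ fertilisation stimulates
growth, standing biomass rises at first — but the same trade-off brings
tree deaths forward, so the gain is transient. `ringlife` packages the
full analysis chain needed to quantify this from increment-core data:

* **I/O and screening** (`ringlife.ring_io`) — Tucson (ITRDB) RWL and
  long-form CSV readers/writers, duplicate-core merging, per-tree
  summaries, dead/living classification, and the site (n ≥ 20,
  CV_Age ≥ 10 %) and species eligibility filters.
* **Trade-off estimation** (`ringlife.tradeoff`) — the lifespan model

  ```
  log A₀.₉₅ = a + b · RW̄        (lifespan ≈ exp(a + b · RW̄))
  ```

  fitted by 95th-quantile regression of log age on mean early ring width
  RW̄ (first 10 rings, mm yr⁻¹). The decay constant *b* measures the
  trade-off. Solved as a linear program (pinball loss) with exact
  vertex polishing; significance by seeded case bootstrap. Also: species
  normalisation and cube-root-weighted mean decay, major-axis regression
  for site-level climate relationships, stratified fits (2 °C temperature
  classes / growth bands / crown cover / soil), maximum-age and
  slope-error resampling diagnostics, the big-tree sampling-bias
  reconstruction, and the age-band temperature sensitivity λ(A).
* **Mortality inference** (`ringlife.mortality`) — annual hazards from
  steady-state stand structure, μ(D) = (I − L)/N per 2-cm class, with the
  parametric families μ(D) = b + k(D − D₀)⁴ above the 91-mm coring
  threshold and μ(A) = a + b·A above 74 yr (published black-spruce
  constants shipped as defaults).
* **Cohort simulation** (`ringlife.stand_simulator`) — a 600-year
  annually seeded stochastic cohort model with donor-based trajectory
  extension, pluggable mortality, and a warming-driven growth stimulus
  RW·exp(λ(A)·δT(t)) whose boosted widths feed back into the diameter the
  size-dependent hazard sees.
* **Synthetic data** (`ringlife.synthetic_data`) — a black-spruce-like
  generator (saturating diameter curves toward an independent Dmax,
  lognormal growth speeds, AR(1) multiplicative noise, a site temperature
  gradient) so every stage is testable without any download.

Estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; the module-level functions are thin wrappers.

## Worked example

```python
import numpy as np
from ringlife import (SynthConfig, generate_population, fit_quantile_exponential,
                      DIAMETER_MORTALITY_DEFAULTS, SimConfig, StimulusConfig,
                      run_simulation, compare_scenarios)
from ringlife.ring_io import summarize_trees

# a synthetic black-spruce-like population of 2000 cored trees
series, sites = generate_population(SynthConfig(n_trees=2000, seed=1))
summaries, _ = summarize_trees(series)

fit = fit_quantile_exponential(summaries, q=0.95, n_boot=200, random_state=0)
print(f"decay constant b = {fit.decay:.3f} per mm/yr (p = {fit.p_value:.3f}, n = {fit.n})")
print(f"lifespan at RWbar = 0.5 mm/yr: {fit.lifespan(0.5):.0f} yr")
print(f"lifespan at RWbar = 2.0 mm/yr: {fit.lifespan(2.0):.0f} yr")
```

```
decay constant b = -0.169 per mm/yr (p = 0.010, n = 2000)
lifespan at RWbar = 0.5 mm/yr: 577 yr
lifespan at RWbar = 2.0 mm/yr: 448 yr
```

The negative, significant decay constant is the trade-off: a tree growing
2.0 mm yr⁻¹ in youth has a ~22 % shorter expected maximum lifespan than
one growing 0.5 mm yr⁻¹. Feeding full-length trajectories into the cohort
simulator and comparing a 50-year warming-driven growth stimulus
(0.0221 °C yr⁻¹ from year 300) against its paired baseline:

```python
traj, _ = generate_population(SynthConfig(seed=3), full_length=True)
cfg = SimConfig(cohort_size=125, mortality=DIAMETER_MORTALITY_DEFAULTS, seed=11)
base = run_simulation(traj, cfg)
boosted = run_simulation(traj, cfg, StimulusConfig())
_, summary = compare_scenarios(base, boosted, StimulusConfig())
```

```
growth_gain_end_of_ramp_pct: 14.94
peak_basal_area_gain_pct: 10.33
max_p75_death_age_reduction_yr: 20.38
final_basal_area_change_pct: 1.67
death_rate_rise_lag_yr: 43.00
peak_death_rate_change_pct: 21.96
```

Growth stimulation raises mean ring width ~15 % and standing basal area
~10 % — but the death rate rises ~22 % after a multi-decade lag, large
trees die up to ~20 years younger, and by year 600 the biomass gain has
collapsed back to within 2 % of baseline. Re-running with the
age-dependent hazard (`AGE_MORTALITY_DEFAULTS`, no size feedback) keeps
the biomass gain indefinitely: the trade-off is what neutralises the
carbon sink.

## Command line

```
ringlife synth    --out out/synth --seed 1          # synthetic RWL/CSV + sites
ringlife ingest   --csv out/synth/population.csv --out out/ingest
ringlife tradeoff --summaries out/ingest/summaries.csv --out out/fits
ringlife mortality --out out/mortality
ringlife simulate --scenario stim --cohort 125 --out out/sim
ringlife all      --out out --seed 1                # the whole pipeline
```

Every stage writes a `manifest.json` with SHA-256 checksums; a single
`--seed` expands deterministically into per-stage substreams.

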