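"""Synthetic tree-ring populations with the structure the analysis assumes.

The generator emulates a boreal conifer (black-spruce-like) population in
which maximum attainable diameter is a trait independent of growth speed:
each tree follows a saturating diameter curve

    D(A) = Dmax * (1 - exp(-r * A)),

with per-tree Dmax drawn from a truncated normal (~300 mm) and per-tree
growth speed r lognormal, multiplied by an exponential site-temperature
effect. Ring width at age A is (D(A) - D(A-1)) / 2 times multiplicative
lognormal AR(1) noise (tree growth is strongly autocorrelated in time, and
multiplicative noise keeps widths positive). Observation ages are drawn
uniformly between 10 and the age at 99% of Dmax, producing the uneven age
structures the screening filters require. Under this construction fast
starters reach the size plateau — and, under size-dependent mortality,
death — much earlier than slow starters, while early growth and Dmax stay
uncorrelated: the mechanism behind the growth-lifespan trade-off.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mortality import MortalityModel, SizeDistribution
from .types import RingSeries, SiteRecord

logger = logging.getLogger(__name__)

#: Hard cap on trajectory length (years); 4.6/r can be enormous for tiny r.
MAX_TRAJECTORY_AGE = 600


@dataclass
class SynthConfig:
    """Parameters of the synthetic population.

    Defaults emulate black spruce: species maximum diameter ~300 mm, with
    sd 23 mm so the 99th-percentile attained size is ~353 mm; the median
    growth speed r = -ln(1 - 91/300)/74 ~ 0.0049 yr^-1 puts the average
    tree at 91 mm diameter at age 74, and the lognormal spread 0.55 makes
    early ring widths span roughly 0.2-3.2 mm yr^-1 across trees; moderate
    first-order autocorrelation in the multiplicative growth noise; site
    mean annual temperatures over an 8 degC boreal gradient with a ~10%
    per degC growth response.
    """

    n_trees: int = 2000
    n_sites: int = 40
    max_diameter_mean: float = 300.0     # mm
    max_diameter_sd: float = 23.0        # mm
    growth_rate_meanlog: float = math.log(0.0049)   # log(yr^-1)
    growth_rate_sdlog: float = 0.55
    ar1_coef: float = 0.5
    noise_sd: float = 0.2
    temp_range: tuple[float, float] = (-4.0, 4.0)  # degC
    temp_growth_slope: float = 0.1       # per degC multiplier on r
    species: str = "PIMA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.max_diameter_mean <= 0:
            raise ValueError("max_diameter_mean must be > 0")
        if self.max_diameter_sd < 0:
            raise ValueError("max_diameter_sd must be >= 0")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.growth_rate_sdlog < 0:
            raise ValueError("growth_rate_sdlog must be >= 0")
        if self.temp_range[1] < self.temp_range[0]:
            raise ValueError("temp_range must be an increasing interval")


def _truncated_normal_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) redrawn until > 0."""
    out = rng.normal(mean, sd, n)
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def _ar1_lognormal_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Multiplicative noise exp(eps) with stationary AR(1) eps."""
    if sd == 0.0:
        return np.ones(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + shocks[t - 1]
    return np.exp(eps)


def _base_widths(dmax: float, r: float, n_years: int) -> np.ndarray:
    """Noise-free ring widths from the saturating diameter curve, mm."""
    ages = np.arange(n_years + 1)
    diam = dmax * (1.0 - np.exp(-r * ages))
    return np.diff(diam) / 2.0


def trajectory_length(r: float, frac: float = 0.99) -> int:
    """Age at which the diameter curve reaches ``frac`` of Dmax, capped."""
    return int(min(math.ceil(-math.log(1.0 - frac) / r), MAX_TRAJECTORY_AGE))


def generate_population(
    config: SynthConfig,
    full_length: bool = False,
    return_truth: bool = False,
):
    """Draw a synthetic tree-ring population and its site table.

    Each tree's observation age is uniform on [10, age at 0.99*Dmax] so age
    structures are uneven; ``full_length=True`` instead returns every
    trajectory to its full (capped) length, which is what the cohort
    simulator consumes. ``return_truth=True`` appends a per-tree table of
    the generating traits (Dmax, r, site MAT) for diagnostics and
    parameter-recovery tests. Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t_lo, t_hi = config.temp_range
    sites = []
    for i in range(config.n_sites):
        sites.append(
            SiteRecord(
                site_id=f"S{i:03d}",
                lat=float(rng.uniform(48.0, 58.0)),
                lon=float(rng.uniform(-79.0, -58.0)),
                mat=float(rng.uniform(t_lo, t_hi)),
                map_mm=float(rng.uniform(500.0, 1100.0)),
                crown_cover_class=int(rng.integers(1, 5)),
                soil_class=str(rng.choice(["organic", "till", "sand", "clay"])),
            )
        )
    mats = np.array([s.mat for s in sites])
    mean_mat = 0.5 * (t_lo + t_hi)

    site_idx = rng.integers(0, config.n_sites, config.n_trees)
    dmax = _truncated_normal_positive(rng, config.max_diameter_mean, config.max_diameter_sd, config.n_trees)
    r = rng.lognormal(config.growth_rate_meanlog, config.growth_rate_sdlog, config.n_trees)
    r = r * np.exp(config.temp_growth_slope * (mats[site_idx] - mean_mat))

    out = []
    for i in range(config.n_trees):
        horizon = trajectory_length(r[i])
        if full_length:
            obs_age = max(horizon, 10)
        else:
            obs_age = int(rng.integers(10, max(horizon, 10) + 1))
        base = _base_widths(dmax[i], r[i], obs_age)
        widths = base * _ar1_lognormal_noise(rng, obs_age, config.ar1_coef, config.noise_sd)
        out.append(
            RingSeries(
                tree_id=f"T{i:05d}",
                widths=widths,
                site_id=sites[site_idx[i]].site_id,
                species=config.species,
                status="alive",
            )
        )
    if return_truth:
        truth = pd.DataFrame(
            {
                "tree_id": [s.tree_id for s in out],
                "dmax": dmax,
                "r": r,
                "mat": mats[site_idx],
            }
        )
        return out, sites, truth
    return out, sites


@dataclass
class KnownTradeoffConfig:
    """Generating truth for parameter-recovery tests of the trade-off fit.

    Draws (early growth, age) pairs whose conditional ``quantile``-th
    quantile of log age is exactly ``a_true + b_true * RWbar``.
    """

    a_true: float = math.log(400.0)
    b_true: float = -0.5
    quantile: float = 0.95
    n: int = 1000
    rw_range: tuple[float, float] = (0.2, 3.2)   # mm yr^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if not math.isfinite(self.b_true):
            raise ValueError("b_true must be finite")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_known_tradeoff_sample(config: KnownTradeoffConfig) -> pd.DataFrame:
    """Sample from a known quantile curve.

    Construction: RWbar ~ Uniform(rw_range); log A = a + b*RWbar + E with
    E = log(U) - log(q), U ~ Uniform(0, 1). Since log is monotone, the
    q-quantile of log U is log q, so the q-quantile of E is 0 and the
    conditional q-quantile of log A is exactly a + b*RWbar for every RWbar.
    Returns a summary table usable by the trade-off fitters.
    """
    if config.n < 20:
        warnings.warn("fewer than 20 trees: quantile fits will be unstable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    rw = rng.uniform(config.rw_range[0], config.rw_range[1], config.n)
    e = np.log(rng.uniform(0.0, 1.0, config.n)) - math.log(config.quantile)
    age = np.exp(config.a_true + config.b_true * rw + e)
    return pd.DataFrame(
        {
            "tree_id": [f"K{i:05d}" for i in range(config.n)],
            "site_id": "SYN",
            "species": "SYN",
            "early_growth": rw,
            "age": age,
            "max_diameter": np.nan,
            "status": "alive",
        }
    )


def generate_stand_distribution(
    mortality: Optional[MortalityModel],
    config: SynthConfig,
    recruits_per_year: int = 100,
    bin_width: float = 20.0,
    burn_in: Optional[int] = None,
    tally_years: int = 300,
    max_age: int = 500,
    check_stationarity: bool = True,
) -> SizeDistribution:
    """Simulate a stand to stationarity and tally its size structure.

    Every year ``recruits_per_year`` trees are seeded with (r, Dmax) drawn
    as in :func:`generate_population` (noise-free growth), each tree grows
    along its diameter curve, and dies by a Bernoulli draw against the
    hazard (``mortality=None`` means no stochastic death; trees then only
    leave at ``max_age``). After a burn-in of ``burn_in`` years (default
    ``max_age``, one full lifespan) the per-2-cm-class mean abundance N and
    the yearly ingrowth I and outgrowth L are tallied over ``tally_years``.
    Drift of the total population exceeding 1% per decade at the end of the
    run is rejected as non-stationary.
    """
    rng = np.random.default_rng(config.seed)
    burn = max_age if burn_in is None else burn_in
    horizon = burn + tally_years
    t_lo, t_hi = config.temp_range
    mean_mat = 0.5 * (t_lo + t_hi)

    cap = config.max_diameter_mean + 8 * config.max_diameter_sd
    edges = np.arange(0.0, cap + bin_width, bin_width)
    m = edges.size - 1
    n_acc = np.zeros(m)
    i_acc = np.zeros(m)
    l_acc = np.zeros(m)
    pop_track = []

    total = recruits_per_year * horizon
    dmax = _truncated_normal_positive(rng, config.max_diameter_mean, config.max_diameter_sd, total)
    site_mat = rng.uniform(t_lo, t_hi, total)
    r = rng.lognormal(config.growth_rate_meanlog, config.growth_rate_sdlog, total)
    r = r * np.exp(config.temp_growth_slope * (site_mat - mean_mat))

    age = np.zeros(total, dtype=int)
    alive = np.zeros(total, dtype=bool)
    n_seeded = 0
    for t in range(horizon):
        new = slice(n_seeded, n_seeded + recruits_per_year)
        alive[new] = True
        age[new] = 0
        n_seeded += recruits_per_year
        sl = slice(0, n_seeded)
        live = np.flatnonzero(alive[sl])
        a0 = age[live].astype(float)
        d_prev = dmax[live] * (1.0 - np.exp(-r[live] * a0))
        d_new = dmax[live] * (1.0 - np.exp(-r[live] * (a0 + 1.0)))
        age[live] += 1
        b_prev = np.clip(np.digitize(d_prev, edges) - 1, 0, m - 1)
        b_new = np.clip(np.digitize(d_new, edges) - 1, 0, m - 1)
        in_tally = t >= burn
        if in_tally:
            recruits = a0 == 0.0
            np.add.at(i_acc, b_new[recruits], 1)  # recruitment enters its first class
            moved = b_new != b_prev
            # a tree can cross several class boundaries in one year
            for bp, bn in zip(b_prev[moved], b_new[moved]):
                l_acc[bp : bn] += 1  # leaves every class from bp up to bn-1
                i_acc[bp + 1 : bn + 1] += 1
            np.add.at(n_acc, b_new, 1)
        if mortality is not None:
            u = rng.random(live.size)
            dead = u < mortality.hazard(d_new)
            alive[live[dead]] = False
        too_old = age[live] >= max_age
        alive[live[too_old]] = False
        if in_tally:
            pop_track.append(int(alive[sl].sum()))

    if check_stationarity and len(pop_track) >= 60:
        last = float(np.mean(pop_track[-30:]))
        prev = float(np.mean(pop_track[-60:-30]))
        decades = 3.0  # the two 30-yr window centres are 30 yr apart
        if prev > 0 and abs(last - prev) / prev / decades > 0.01:
            raise RuntimeError(
                "stand not stationary: total count drifting "
                f"{100 * (last - prev) / prev / decades:.2f}% per decade at the end of the run"
            )
    return SizeDistribution(
        bin_edges=edges,
        N=n_acc / tally_years,
        I=i_acc / tally_years,
        L=l_acc / tally_years,
    )
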