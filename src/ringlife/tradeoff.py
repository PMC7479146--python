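"""Growth-lifespan trade-off estimation and its robustness diagnostics.

The central statistic is the exponential lifespan model

    log(A at the q-th quantile) = a + b * RWbar,

fitted by quantile regression (pinball loss) of log age on mean early ring
width; the decay constant ``b`` (per mm yr^-1, or per relative growth unit
after species normalization) measures the strength of the trade-off. The
module also provides major-axis regression for cross-species and site-level
environmental relationships, stratified fits that separate the direct
growth effect from temperature covariance, the sample-size and maximum-age
resampling diagnostics, the big-tree sampling-bias reconstruction, and the
age-band temperature-sensitivity fit feeding the growth-stimulus model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import SiteRecord, sites_to_frame

logger = logging.getLogger(__name__)


def pinball_loss(residuals: np.ndarray, q: float) -> float:
    """Total check loss sum_i rho_q(r_i), rho_q(r) = r*(q - 1[r<0])."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.maximum(q * r, (q - 1.0) * r)))


def _solve_quantile_line(x: np.ndarray, y: np.ndarray, q: float) -> tuple[float, float]:
    """Quantile regression of y on x via the standard LP formulation.

    min q*1'u + (1-q)*1'v  s.t.  a + b*x_i + u_i - v_i = y_i,  u,v >= 0.

    The optimum is attained at a vertex, i.e. a line through two data
    points; the LP solution is polished onto the exact best such line
    (ties broken by lowest loss, then smallest |b|) so that small-sample
    fits are reproducible to machine precision.
    """
    n = x.size
    c = np.concatenate([[0.0, 0.0], np.full(n, q), np.full(n, 1.0 - q)])
    eye = sparse.eye(n, format="csc")
    A_eq = sparse.hstack(
        [sparse.csc_matrix(np.ones((n, 1))), sparse.csc_matrix(x[:, None]), eye, -eye],
        format="csc",
    )
    bounds = [(None, None), (None, None)] + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a, b = float(res.x[0]), float(res.x[1])

    # Polish: the optimal line interpolates >= 2 points; re-derive it exactly
    # from the near-zero-residual support points.
    resid = y - (a + b * x)
    scale = max(1.0, float(np.max(np.abs(y))))
    support = np.flatnonzero(np.abs(resid) <= 1e-7 * scale)
    best = (pinball_loss(resid, q), abs(b), b, a)
    if support.size >= 2:
        for ii in range(support.size - 1):
            for jj in range(ii + 1, support.size):
                i, j = support[ii], support[jj]
                if x[i] == x[j]:
                    continue
                b2 = (y[j] - y[i]) / (x[j] - x[i])
                a2 = y[i] - b2 * x[i]
                loss2 = pinball_loss(y - (a2 + b2 * x), q)
                cand = (loss2, abs(b2), b2, a2)
                if cand[:2] < best[:2]:
                    best = cand
    return best[3], best[2]


class QuantileExponentialRegressor(RegressorMixin, BaseEstimator):
    """Exponential lifespan-quantile model ``A_q(x) = exp(a + b*x)``.

    Fits log(y) = a + b*x at quantile ``q`` by minimizing the pinball loss
    (linear-programming solver), where x is mean early ring width and y is
    age in years. The slope ``b`` is the exponential decay constant of
    lifespan with early growth. Significance of ``b`` against 0 is assessed
    by a seeded case (pairs) bootstrap.

    Parameters
    ----------
    q : float, default 0.95
        Quantile of log age to model.
    n_boot : int, default 1000
        Bootstrap replicates for the two-sided p-value of the slope;
        0 disables the bootstrap (``pvalue_`` is then NaN).
    random_state : int or None
        Seed for the bootstrap resampling.

    Attributes
    ----------
    intercept_ : float
        ``a``, in log-years.
    slope_ : float
        ``b``, the decay constant.
    n_ : int
        Number of trees used.
    pvalue_ : float
        Two-sided bootstrap p-value for ``b != 0``.
    """

    def __init__(self, q: float = 0.95, n_boot: int = 1000, random_state: Optional[int] = None):
        self.q = q
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        if np.any(y <= 0):
            raise ValueError("ages must be strictly positive")
        if np.ptp(x) == 0.0:
            raise ValueError("no growth variance: all early growth values are equal")
        logy = np.log(y)
        a, b = _solve_quantile_line(x, logy, self.q)
        self.intercept_, self.slope_ = a, b
        self.n_ = int(x.size)
        self.pvalue_ = np.nan
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            slopes = []
            for _ in range(self.n_boot):
                idx = rng.integers(0, x.size, x.size)
                xb, yb = x[idx], logy[idx]
                if np.ptp(xb) == 0.0:
                    continue
                try:
                    slopes.append(_solve_quantile_line(xb, yb, self.q)[1])
                except RuntimeError:
                    continue
            slopes = np.asarray(slopes)
            if slopes.size:
                n_hi = int(np.sum(slopes >= 0.0))
                n_lo = int(np.sum(slopes <= 0.0))
                p = 2.0 * (min(n_hi, n_lo) + 1) / (slopes.size + 1)
                self.pvalue_ = float(min(1.0, p))
        return self

    def predict(self, X):
        """Predicted lifespan (years) at the modelled quantile."""
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.intercept_ + self.slope_ * x)


class MajorAxisRegressor(RegressorMixin, BaseEstimator):
    """Major-axis (model II) regression for variables with shared error.

    The fitted line follows the principal eigenvector of the 2x2 sample
    covariance matrix and passes through the means — appropriate when
    neither variable is a controlled predictor (e.g. site mean growth vs
    site maximum lifespan).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 3:
            raise ValueError("need at least 3 paired observations")
        vx = float(np.var(x, ddof=1))
        vy = float(np.var(y, ddof=1))
        if vx == 0.0 or vy == 0.0:
            raise ValueError("major axis undefined: zero variance in x or y")
        cxy = float(np.cov(x, y, ddof=1)[0, 1])
        if cxy == 0.0:
            slope = 0.0 if vx >= vy else np.inf
        else:
            slope = (vy - vx + np.hypot(vy - vx, 2.0 * cxy)) / (2.0 * cxy)
        self.slope_ = float(slope)
        self.intercept_ = float(np.mean(y) - self.slope_ * np.mean(x))
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float).reshape(-1)


@dataclass
class TradeoffFit:
    """One quantile-exponential trade-off fit."""

    intercept: float          # a, log-years
    decay: float              # b, per (mm yr^-1) or per relative unit
    q: float
    n: int
    p_value: float = np.nan
    relative: bool = False
    label: str = ""

    def lifespan(self, early_growth) -> np.ndarray:
        return np.exp(self.intercept + self.decay * np.asarray(early_growth, dtype=float))


@dataclass
class MajorAxisFit:
    slope: float
    intercept: float
    n: int
    label: str = ""


@dataclass
class LambdaFit:
    """Age-modulated temperature sensitivity of ring width.

    ``lambda(A)`` (per degC) is quadratic in age below the knee and constant
    (plateau) beyond it; ``scale`` is the growth-scale constant of the
    exponential temperature-response model.
    """

    band_edges: np.ndarray
    band_lambdas: np.ndarray
    c2: float
    c1: float
    c0: float
    plateau: float
    knee: float = 135.0
    scale: float = np.nan

    def __call__(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        quad = self.c2 * a**2 + self.c1 * a + self.c0
        return np.where(a < self.knee, quad, self.plateau)


#: Published age-sensitivity constants for black spruce (Quebec gradient).
PUBLISHED_LAMBDA = LambdaFit(
    band_edges=np.arange(0, 160, 10.0),
    band_lambdas=np.array([]),
    c2=0.0000132,
    c1=-0.00291,
    c0=0.229,
    plateau=0.07,
    knee=135.0,
)


# ---------------------------------------------------------------------------
# Spec-surface functions
# ---------------------------------------------------------------------------

def fit_quantile_exponential(
    summaries: pd.DataFrame,
    q: float = 0.95,
    n_boot: int = 1000,
    random_state: Optional[int] = None,
    min_n: int = 20,
    relative: bool = False,
    label: str = "",
) -> TradeoffFit:
    """Fit the lifespan-quantile model to a summary table.

    ``summaries`` must carry ``early_growth`` and ``age`` columns. At least
    ``min_n`` distinct trees are required for a stable quantile fit.
    """
    x = summaries["early_growth"].to_numpy(dtype=float)
    y = summaries["age"].to_numpy(dtype=float)
    if len(summaries) < min_n:
        raise ValueError(f"need at least {min_n} trees, got {len(summaries)}")
    est = QuantileExponentialRegressor(q=q, n_boot=n_boot, random_state=random_state).fit(x, y)
    return TradeoffFit(
        intercept=est.intercept_,
        decay=est.slope_,
        q=q,
        n=est.n_,
        p_value=est.pvalue_,
        relative=relative,
        label=label,
    )


def normalize_relative(summaries: pd.DataFrame) -> pd.DataFrame:
    """Rescale each tree's growth and age by its species maxima.

    Puts species on a common (0, 1] scale so decay constants are comparable
    across species. Species represented by a single tree are dropped (their
    maxima are the tree itself, pinning it at (1, 1)).
    """
    if summaries.empty:
        raise ValueError("empty summary table")
    counts = summaries.groupby("species")["tree_id"].transform("size")
    out = summaries[counts > 1].copy()
    if out.empty:
        raise ValueError("no species with more than one tree")
    out["early_growth"] = out["early_growth"] / out.groupby("species")["early_growth"].transform("max")
    out["age"] = out["age"] / out.groupby("species")["age"].transform("max")
    return out.reset_index(drop=True)


def weighted_mean_decay(fits: Sequence[TradeoffFit]) -> tuple[float, int]:
    """Cube-root-of-n weighted mean decay constant across species.

    The cube-root weighting damps the enormous sample-size differences
    between species while still favouring well-constrained fits. Also
    returns the count of species with a negative decay constant.
    """
    if not fits:
        raise ValueError("no fits supplied")
    w = np.array([f.n ** (1.0 / 3.0) for f in fits])
    b = np.array([f.decay for f in fits])
    return float(np.sum(w * b) / np.sum(w)), int(np.sum(b < 0))


def binned_quantile_check(
    summaries: pd.DataFrame,
    n_bins: int,
    fit: Optional[TradeoffFit] = None,
    q: float = 0.95,
    min_per_bin: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Empirical per-bin age quantiles vs the fitted exponential curve.

    Bins early growth into ``n_bins`` equal-width classes, computes the
    empirical q-th percentile of age per bin (linear-interpolation, type-7
    definition) and the fitted curve at the bin centre. Returns the bin
    table and the maximum relative deviation over well-filled bins.
    """
    if fit is None:
        fit = fit_quantile_exponential(summaries, q=q, n_boot=0)
    x = summaries["early_growth"].to_numpy(dtype=float)
    y = summaries["age"].to_numpy(dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        n = int(sel.sum())
        center = 0.5 * (edges[k] + edges[k + 1])
        emp = float(np.percentile(y[sel], 100.0 * fit.q)) if n else np.nan
        pred = float(fit.lifespan(center))
        sparse = n < min_per_bin
        dev = abs(emp - pred) / pred if n else np.nan
        rows.append((center, n, emp, pred, dev, sparse))
    table = pd.DataFrame(
        rows, columns=["bin_center", "n", "empirical_quantile_age", "fitted_age", "rel_deviation", "sparse"]
    )
    ok = table[~table["sparse"] & table["rel_deviation"].notna()]
    max_dev = float(ok["rel_deviation"].max()) if len(ok) else float("nan")
    return table, max_dev


def fit_major_axis(x, y, label: str = "") -> MajorAxisFit:
    est = MajorAxisRegressor().fit(x, y)
    return MajorAxisFit(slope=est.slope_, intercept=est.intercept_, n=est.n_, label=label)


def stratified_tradeoff(
    summaries: pd.DataFrame,
    sites: Sequence[SiteRecord] | pd.DataFrame,
    strat: str,
    q: float = 0.95,
    min_n: int = 30,
    n_growth_bands: int = 4,
    temp_class_width: float = 2.0,
    n_boot: int = 200,
    random_state: Optional[int] = None,
) -> list[TradeoffFit]:
    """Trade-off fits within environmental strata.

    ``strat="temperature"`` bins trees into half-open mean-annual-
    temperature classes of ``temp_class_width`` degC anchored at the data
    minimum and fits growth -> lifespan within each: a persistent negative
    decay here shows the trade-off is not a temperature artefact.
    ``strat="growth_band"`` bins trees into equal-count early-growth bands
    and fits lifespan vs temperature within each: a slope near zero here
    shows temperature has no residual effect at fixed growth.
    ``"crown_cover_class"`` and ``"soil_class"`` stratify on the site
    covariate directly. Strata with fewer than ``min_n`` trees are skipped.
    Fits with p > 0.05 should be treated as non-significant.
    """
    site_df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    df = summaries.merge(site_df[["site_id", "mat_c", "crown_cover_class", "soil_class"]], on="site_id")
    fits: list[TradeoffFit] = []

    def _fit(sub: pd.DataFrame, xcol: str, label: str) -> None:
        if len(sub) < min_n or sub[xcol].nunique() < 2:
            logger.info("stratum %s skipped (n=%d)", label, len(sub))
            return
        x = sub[xcol].to_numpy(dtype=float)
        y = sub["age"].to_numpy(dtype=float)
        est = QuantileExponentialRegressor(q=q, n_boot=n_boot, random_state=random_state).fit(x, y)
        fits.append(
            TradeoffFit(est.intercept_, est.slope_, q, est.n_, est.pvalue_, label=label)
        )

    if strat == "temperature":
        t0 = df["mat_c"].min()
        cls = np.floor((df["mat_c"] - t0) / temp_class_width).astype(int)
        for k in sorted(cls.unique()):
            lo = t0 + k * temp_class_width
            _fit(df[cls == k], "early_growth", f"T[{lo:g},{lo + temp_class_width:g})")
    elif strat == "growth_band":
        qs = np.quantile(df["early_growth"], np.linspace(0, 1, n_growth_bands + 1))
        band = np.clip(np.searchsorted(qs, df["early_growth"], side="right") - 1, 0, n_growth_bands - 1)
        for k in range(n_growth_bands):
            _fit(df[band == k], "mat_c", f"RW_band{k + 1}")
    elif strat in ("crown_cover_class", "soil_class"):
        for val, sub in df.groupby(strat):
            _fit(sub, "early_growth", f"{strat}={val}")
    else:
        raise ValueError(f"unknown stratification {strat!r}")
    return fits


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(h))


def site_level_aggregate(
    summaries: pd.DataFrame,
    sites: Sequence[SiteRecord] | pd.DataFrame,
    min_per_site: int = 30,
) -> pd.DataFrame:
    """Pool nearby sites until each pool holds ``min_per_site`` trees.

    Individual collection locations are often too small to estimate a site
    maximum age; pools are formed greedily by repeatedly merging the
    smallest under-sized pool with its nearest neighbour (haversine
    distance between tree-count-weighted centroids). Returns one row per
    pool with mean early growth, maximum age, and count-weighted MAT.
    """
    site_df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    df = summaries.merge(site_df[["site_id", "lat", "lon", "mat_c"]], on="site_id")
    pools: dict[int, dict] = {}
    for i, (site, grp) in enumerate(df.groupby("site_id", sort=True)):
        pools[i] = {
            "members": [site],
            "n": len(grp),
            "lat": float(grp["lat"].iloc[0]),
            "lon": float(grp["lon"].iloc[0]),
        }
    while len(pools) > 1:
        under = [k for k, p in pools.items() if p["n"] < min_per_site]
        if not under:
            break
        k = min(under, key=lambda kk: pools[kk]["n"])
        others = [kk for kk in pools if kk != k]
        d = _haversine_km(
            pools[k]["lat"],
            pools[k]["lon"],
            np.array([pools[o]["lat"] for o in others]),
            np.array([pools[o]["lon"] for o in others]),
        )
        j = others[int(np.argmin(d))]
        a, b = pools[k], pools[j]
        ntot = a["n"] + b["n"]
        pools[j] = {
            "members": a["members"] + b["members"],
            "n": ntot,
            "lat": (a["lat"] * a["n"] + b["lat"] * b["n"]) / ntot,
            "lon": (a["lon"] * a["n"] + b["lon"] * b["n"]) / ntot,
        }
        del pools[k]
    rows = []
    for pid, p in enumerate(pools.values()):
        sub = df[df["site_id"].isin(p["members"])]
        rows.append(
            (
                f"pool{pid:03d}",
                ";".join(sorted(p["members"])),
                p["n"],
                float(sub["early_growth"].mean()),
                int(sub["age"].max()),
                float(np.average(sub["mat_c"])),
                p["lat"],
                p["lon"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=["pool_id", "site_ids", "n", "mean_early_growth", "max_age", "mat_c", "lat", "lon"],
    )


def resample_max_age(
    ages: np.ndarray,
    sizes: Sequence[int] = tuple(range(25, 601, 25)),
    reps: int = 500,
    thresholds: Sequence[float] = (95.0, 99.0),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """How often the maximum of a random subsample exceeds a population percentile.

    For each sample size, draws ``reps`` subsamples without replacement and
    reports the fraction whose maximum age is strictly larger than each
    population percentile (linear-interpolation percentile definition).
    Gauges how many trees must be cored before the sample maximum
    approaches the true site maximum age.
    """
    ages = np.asarray(ages, dtype=float)
    if max(sizes) > ages.size:
        raise ValueError(f"sample size {max(sizes)} exceeds population size {ages.size}")
    rng = np.random.default_rng(seed)
    pct = {t: float(np.percentile(ages, t)) for t in thresholds}
    rows = []
    for n in sizes:
        exceed = {t: 0 for t in thresholds}
        for _ in range(reps):
            m = float(np.max(rng.choice(ages, size=n, replace=False)))
            for t in thresholds:
                exceed[t] += m > pct[t]
        rows.append([n] + [exceed[t] / reps for t in thresholds])
    return pd.DataFrame(rows, columns=["sample_size"] + [f"frac_above_p{t:g}" for t in thresholds])


def sample_size_error_curve(
    summaries: pd.DataFrame,
    sizes: Sequence[int],
    reps: int = 100,
    q: float = 0.95,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Error in the decay constant as a function of sample size.

    Refits the trade-off on random subsamples (without replacement) and
    reports the mean absolute and mean signed relative error of ``b``
    against the full-data fit, plus the count of degenerate refits.
    """
    full = fit_quantile_exponential(summaries, q=q, n_boot=0)
    if full.decay == 0:
        raise ValueError("full-data decay constant is zero; relative error undefined")
    rng = np.random.default_rng(seed)
    n_total = len(summaries)
    rows = []
    for size in sizes:
        if size > n_total:
            raise ValueError(f"sample size {size} exceeds population {n_total}")
        errs, fails = [], 0
        for _ in range(reps):
            sub = summaries.iloc[rng.choice(n_total, size=size, replace=False)]
            try:
                f = fit_quantile_exponential(sub, q=q, n_boot=0, min_n=2)
            except (ValueError, RuntimeError):
                fails += 1
                continue
            errs.append((f.decay - full.decay) / full.decay)
        errs = np.asarray(errs)
        rows.append(
            (size, float(np.mean(np.abs(errs))), float(np.mean(errs)), len(errs), fails)
        )
    return pd.DataFrame(
        rows, columns=["sample_size", "mean_abs_rel_error", "mean_rel_error", "n_fits", "n_failed"]
    )


def big_tree_bias_experiment(
    trajectories: Sequence,
    field_size_frequency: pd.DataFrame,
    min_diameter: float = 91.0,
    scenarios: Sequence[str] = ("all", "threshold", "top10pct"),
    bin_width: float = 20.0,
    q: float = 0.95,
    seed: Optional[int] = None,
) -> dict[str, dict]:
    """Quantify the bias from coring only large trees.

    Reconstructs an artificial population whose size structure matches a
    field diameter-frequency table: for each 2-cm size class the observed
    number of trees is drawn (with replacement) from the ring-series whose
    diameter trajectory transits that class, recording each draw's early
    growth and the age at which it reached the class. The trade-off is then
    fitted to three views of this population — ``all`` classes, only
    classes at or above the field coring ``threshold`` (``min_diameter``),
    and the ``top10pct`` largest draws — and each scenario's decay constant
    is reported with its ratio to the unbiased (``all``) fit.

    ``field_size_frequency`` needs columns ``bin_low_mm`` and ``count``.
    """
    rng = np.random.default_rng(seed)
    rw = np.array([float(t.widths[:10].mean()) for t in trajectories])
    diam = [t.cumulative_diameter for t in trajectories]
    draws_x, draws_y, draws_d = [], [], []
    empty = []
    for lo, count in zip(
        field_size_frequency["bin_low_mm"].to_numpy(dtype=float),
        field_size_frequency["count"].to_numpy(dtype=int),
    ):
        lo = float(lo)
        count = int(count)
        if count <= 0:
            continue
        ages_at = np.array(
            [int(np.argmax(d >= lo)) + 1 if d[-1] >= lo else 0 for d in diam]
        )
        eligible = np.flatnonzero(ages_at > 0) if lo > 0 else np.arange(len(diam))
        if lo <= 0:
            ages_at = np.maximum(ages_at, 1)
        if eligible.size == 0:
            empty.append(lo)
            continue
        pick = rng.choice(eligible, size=count, replace=True)
        draws_x.append(rw[pick])
        draws_y.append(ages_at[pick])
        draws_d.append(np.full(count, lo))
    if empty:
        logger.warning("no trajectories reach size classes at %s mm", empty)
    x = np.concatenate(draws_x)
    y = np.concatenate(draws_y).astype(float)
    d = np.concatenate(draws_d)

    def _fit(mask: np.ndarray, label: str) -> TradeoffFit:
        est = QuantileExponentialRegressor(q=q, n_boot=0).fit(x[mask], y[mask])
        return TradeoffFit(est.intercept_, est.slope_, q, est.n_, label=label)

    out: dict[str, dict] = {}
    all_fit = _fit(np.ones_like(x, dtype=bool), "all")
    for sc in scenarios:
        if sc == "all":
            fit = all_fit
        elif sc == "threshold":
            fit = _fit(d >= min_diameter, "threshold")
        elif sc == "top10pct":
            cut = np.quantile(d, 0.9)
            fit = _fit(d >= cut, "top10pct")
        else:
            raise ValueError(f"unknown scenario {sc!r}")
        out[sc] = {"fit": fit, "ratio_to_all": fit.decay / all_fit.decay}
    return out


def estimate_lambda(
    series: Sequence,
    sites: Sequence[SiteRecord] | pd.DataFrame,
    band_width: float = 10.0,
    max_band_age: float = 150.0,
    knee: float = 135.0,
    min_mat_span: float = 3.0,
) -> LambdaFit:
    """Age-band temperature sensitivity of ring width (space-for-time).

    For each 10-year age band, the log of a tree's mean ring width within
    the band is regressed on its site's mean annual temperature; the slope
    is the band's sensitivity lambda (per degC). A quadratic in age is
    fitted to the band sensitivities below the ``knee`` age, and the
    plateau is the mean sensitivity of bands at or beyond it. Requires a
    temperature gradient of at least ``min_mat_span`` degC.
    """
    site_df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    mat = dict(zip(site_df["site_id"], site_df["mat_c"]))
    mats = np.array([mat[s.site_id] for s in series])
    if np.ptp(mats[np.isfinite(mats)]) < min_mat_span:
        raise ValueError(
            f"site MAT spans {np.ptp(mats):.2f} degC; need >= {min_mat_span} for sensitivity fits"
        )
    edges = np.arange(0.0, max_band_age + band_width, band_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lambdas = np.full(centers.size, np.nan)
    intercepts = np.full(centers.size, np.nan)
    for k in range(centers.size):
        lo, hi = edges[k], edges[k + 1]
        xs, ys = [], []
        for s, t in zip(series, mats):
            if not np.isfinite(t):
                continue
            w = s.widths[int(lo) : int(hi)]
            if w.size and w.mean() > 0:
                xs.append(t)
                ys.append(np.log(w.mean()))
        if len(xs) >= 10 and np.ptp(xs) > 0:
            coef = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
            lambdas[k] = coef[0]
            intercepts[k] = coef[1]
    below = np.isfinite(lambdas) & (centers < knee)
    if below.sum() < 3:
        raise ValueError("too few informative age bands below the knee")
    c2, c1, c0 = np.polyfit(centers[below], lambdas[below], 2)
    above = np.isfinite(lambdas) & (centers >= knee)
    plateau = float(np.mean(lambdas[above])) if above.any() else float(c2 * knee**2 + c1 * knee + c0)
    scale = float(np.exp(np.nanmean(intercepts))) if np.isfinite(intercepts).any() else np.nan
    return LambdaFit(
        band_edges=edges,
        band_lambdas=lambdas,
        c2=float(c2),
        c1=float(c1),
        c0=float(c0),
        plateau=plateau,
        knee=knee,
        scale=scale,
    )
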