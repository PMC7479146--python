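"""Mortality inference from steady-state stand structure.

Under stand stationarity the diameter number distribution N(D) obeys, per
2-cm class, 0 = dN/dt = I(D) - L(D) - deaths(D), with I the ingrowth into
and L the outgrowth from the class per year, so the annual mortality rate
is mu(D) = (I(D) - L(D)) / N(D). The same accounting over yearly age
classes yields mu(A). Two parametric hazard families are supported:

* diameter-dependent: mu(D) = 0 for D <= D0, else b + k*(D - D0)^4 — a
  sharp rise toward a species maximum size, with the threshold D0 fixed by
  the minimum coring diameter of the field protocol;
* age-dependent: mu(A) = 0 for A <= A0, else a + b*A — the no-trade-off
  comparison model.

Hazards are interpreted as annual death probabilities (Bernoulli per
tree-year) and capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


@dataclass
class MortalityModel:
    """Parametric annual hazard, diameter- or age-dependent.

    For ``kind="diameter"``: ``baseline`` (yr^-1) is the flat hazard just
    above the threshold, ``slope`` (yr^-1 mm^-4) the quartic curvature,
    ``threshold`` (mm) the minimum sampling diameter D0 below which the
    hazard is zero by construction. For ``kind="age"``: hazard is
    ``baseline + slope*A`` above the age threshold A0.
    """

    kind: str
    baseline: float
    slope: float
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("diameter", "age"):
            raise ValueError(f"kind must be 'diameter' or 'age', got {self.kind!r}")

    def hazard(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "diameter":
            h = self.baseline + self.slope * (x - self.threshold) ** 4
        else:
            h = self.baseline + self.slope * x
        h = np.where(x <= self.threshold, 0.0, h)
        return np.clip(h, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "baseline": self.baseline,
            "slope": self.slope,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MortalityModel":
        return cls(d["kind"], d["baseline"], d["slope"], d["threshold"])


#: Published black-spruce constants: mu(D) = 0.025 + 3e-11 (D - 91)^4 above 91 mm.
DIAMETER_MORTALITY_DEFAULTS = MortalityModel("diameter", baseline=0.025, slope=3e-11, threshold=91.0)
#: Published age-hazard constants: mu(A) = 0.021 + 1.5e-6 A above 74 yr.
AGE_MORTALITY_DEFAULTS = MortalityModel("age", baseline=0.021, slope=1.5e-6, threshold=74.0)


def eval_hazard_diameter(D, model: Optional[MortalityModel] = None) -> np.ndarray:
    """Annual death probability at diameter D (mm)."""
    model = model or DIAMETER_MORTALITY_DEFAULTS
    if model.kind != "diameter":
        raise ValueError("model is not diameter-dependent")
    return model.hazard(D)


def eval_hazard_age(A, model: Optional[MortalityModel] = None) -> np.ndarray:
    """Annual death probability at age A (yr)."""
    model = model or AGE_MORTALITY_DEFAULTS
    if model.kind != "age":
        raise ValueError("model is not age-dependent")
    return model.hazard(A)


@dataclass
class SizeDistribution:
    """Stationary stand structure per size class.

    ``bin_edges`` in mm (default 20-mm = 2-cm classes); ``N`` mean count per
    class; ``I`` ingrowth and ``L`` outgrowth, both trees per year.
    """

    bin_edges: np.ndarray
    N: np.ndarray
    I: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        m = self.bin_edges.size - 1
        if not (self.N.size == self.I.size == self.L.size == m):
            raise ValueError("N, I, L must each have one entry per bin")
        if np.any(self.N < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_mm": self.bin_edges[:-1],
                "bin_high_mm": self.bin_edges[1:],
                "N": self.N,
                "I": self.I,
                "L": self.L,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SizeDistribution":
        edges = np.append(df["bin_low_mm"].to_numpy(dtype=float), float(df["bin_high_mm"].iloc[-1]))
        return cls(edges, df["N"].to_numpy(), df["I"].to_numpy(), df["L"].to_numpy())


def estimate_mortality_from_distribution(dist: SizeDistribution) -> np.ndarray:
    """mu(D) = (I - L) / N per size class; NaN where the class is empty.

    Negative estimates (outgrowth exceeding ingrowth, i.e. sampling noise
    or non-stationarity) are returned as-is with a warning.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(dist.N > 0, (dist.I - dist.L) / dist.N, np.nan)
    n_neg = int(np.sum(mu[np.isfinite(mu)] < 0))
    if n_neg:
        logger.warning("%d size classes have negative mortality estimates (noise)", n_neg)
    return mu


def estimate_mortality_by_age(
    death_ages: np.ndarray,
    censored_ages: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Yearly-age-class hazard from a population's ages at death.

    Life-table estimate: mu(A) = deaths at age A / trees at risk at age A,
    the age-class analogue of the stationary size-class balance (every tree
    enters class A from A-1 and leaves to A+1 unless it dies). Trees still
    alive at sampling enter as right-censored at their current age. Classes
    with no trees at risk are undefined (NaN).
    """
    death_ages = np.asarray(death_ages, dtype=int)
    cens = np.asarray(censored_ages, dtype=int) if censored_ages is not None else np.array([], int)
    if death_ages.size == 0 and cens.size == 0:
        raise ValueError("no trees supplied")
    amax = int(max(death_ages.max(initial=0), cens.max(initial=0)))
    ages = np.arange(1, amax + 1)
    d = np.bincount(death_ages, minlength=amax + 1)[1:]
    c = np.bincount(cens, minlength=amax + 1)[1:]
    # at risk at age A: trees whose death or censoring age is >= A
    at_risk = (d + c)[::-1].cumsum()[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(at_risk > 0, d / at_risk, np.nan)
    return pd.DataFrame({"age": ages, "n_at_risk": at_risk, "n_deaths": d, "mu": mu})


class HazardCurveRegressor(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of a parametric hazard to binned rates.

    The threshold (D0 or A0) is fixed by the sampling design, which makes
    both families linear in their free parameters: the design matrix is
    ``[1, (x - threshold)^4]`` for the diameter family and ``[1, x]`` for
    the age family, fitted over classes above the threshold with weights
    equal to the class abundance N.

    Attributes
    ----------
    baseline_, slope_ : float
        Fitted parameters.
    model_ : MortalityModel
        The fitted hazard, ready for simulation.
    rmse_ : float
        Weighted root-mean-square residual.
    """

    def __init__(self, kind: str = "diameter", threshold: float = 91.0):
        self.kind = kind
        self.threshold = threshold

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        ok = np.isfinite(y) & np.isfinite(x) & (x > self.threshold) & (w > 0)
        if ok.sum() < 4:
            raise ValueError(f"need >= 4 informative classes above the threshold, got {int(ok.sum())}")
        x, y, w = x[ok], y[ok], w[ok]
        if self.kind == "diameter":
            feat = (x - self.threshold) ** 4
        elif self.kind == "age":
            feat = x
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        A = np.column_stack([np.ones_like(x), feat])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        if not np.all(np.isfinite(coef)):
            raise RuntimeError("hazard fit did not converge (singular design)")
        self.baseline_, self.slope_ = float(coef[0]), float(coef[1])
        resid = y - A @ coef
        self.rmse_ = float(np.sqrt(np.average(resid**2, weights=w)))
        self.n_bins_ = int(x.size)
        self.model_ = MortalityModel(self.kind, self.baseline_, self.slope_, self.threshold)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.hazard(X)


def fit_hazard_model(
    x: np.ndarray,
    mu: np.ndarray,
    kind: str = "diameter",
    threshold: float = 91.0,
    weights: Optional[np.ndarray] = None,
) -> tuple[MortalityModel, dict]:
    """Fit the parametric hazard to binned mortality estimates.

    ``x`` are class centres (mm for diameter, yr for age), ``mu`` the
    per-class annual rates, ``weights`` the class abundances. Returns the
    fitted model and a residual summary.
    """
    est = HazardCurveRegressor(kind=kind, threshold=threshold).fit(x, mu, sample_weight=weights)
    return est.model_, {"rmse": est.rmse_, "n_bins": est.n_bins_}
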