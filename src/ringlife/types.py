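"""Core record types shared across the package.

A :class:`RingSeries` is one tree's ordered annual ring widths (mm) indexed
by cambial age (1 = first ring from the pith); a :class:`TreeSummary` is the
derived (early growth, age, maximum diameter) triple that the trade-off
analysis consumes; a :class:`SiteRecord` carries the static site covariates
(location, mean annual temperature/precipitation, crown cover, soil).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VALID_STATUSES = ("alive", "dead", "subfossil", "unknown")


@dataclass
class RingSeries:
    """One tree's ring-width series.

    Parameters
    ----------
    tree_id, site_id, species : str
        Identifiers. ``site_id`` and ``species`` may be empty when the
        source format (Tucson RWL) carries no metadata.
    widths : array-like of float
        Ring widths in mm, ordered by cambial age starting at 1.
    last_calendar_year : int, optional
        Calendar year of the outermost measured ring, when dated.
    status : {"alive", "dead", "subfossil", "unknown"}
        Life status at sampling.
    """

    tree_id: str
    widths: np.ndarray
    site_id: str = ""
    species: str = ""
    last_calendar_year: Optional[int] = None
    status: str = "unknown"

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"series {self.tree_id!r}: widths must be a non-empty 1-D array")
        if np.any(self.widths < 0) or not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.tree_id!r}: widths must be finite and >= 0")
        if self.status not in VALID_STATUSES:
            raise ValueError(f"series {self.tree_id!r}: invalid status {self.status!r}")

    @property
    def age(self) -> int:
        """Cambial age = number of measured rings."""
        return int(self.widths.size)

    @property
    def cumulative_diameter(self) -> np.ndarray:
        """Diameter trajectory D(A) = 2 x cumulative ring width, mm."""
        return 2.0 * np.cumsum(self.widths)

    @property
    def max_diameter(self) -> float:
        return float(2.0 * self.widths.sum())


@dataclass
class TreeSummary:
    """Per-tree quantities entering the trade-off fit.

    ``early_growth`` is the mean ring width over the first 10 rings
    (mm yr^-1); ``age`` the total ring count; ``max_diameter`` twice the
    cumulative ring width (one core approximates a radius; no bark
    correction).
    """

    tree_id: str
    early_growth: float
    age: int
    max_diameter: float
    site_id: str = ""
    species: str = ""
    status: str = "unknown"

    def __post_init__(self) -> None:
        if self.early_growth <= 0:
            raise ValueError(f"tree {self.tree_id!r}: early_growth must be > 0")
        if self.age < 10:
            raise ValueError(f"tree {self.tree_id!r}: age must be >= 10 for a defined early growth")


@dataclass
class SiteRecord:
    """Static covariates for one collection site."""

    site_id: str
    lat: float = np.nan
    lon: float = np.nan
    mat: float = np.nan            # mean annual temperature, degC
    map_mm: float = np.nan         # mean annual precipitation, mm yr^-1
    crown_cover_class: int = 0     # ordinal, 0 = unknown
    soil_class: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.lat) and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.site_id!r}: latitude {self.lat} out of range")


SUMMARY_COLUMNS = ["tree_id", "site_id", "species", "early_growth", "age", "max_diameter", "status"]


def summaries_to_frame(summaries: Iterable[TreeSummary]) -> pd.DataFrame:
    """Stack :class:`TreeSummary` records into the canonical DataFrame."""
    rows = [
        (s.tree_id, s.site_id, s.species, s.early_growth, s.age, s.max_diameter, s.status)
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def sites_to_frame(sites: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [
        (s.site_id, s.lat, s.lon, s.mat, s.map_mm, s.crown_cover_class, s.soil_class)
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "lat", "lon", "mat_c", "map_mm", "crown_cover_class", "soil_class"]
    )


def frame_to_sites(df: pd.DataFrame) -> list[SiteRecord]:
    return [
        SiteRecord(
            site_id=str(r.site_id),
            lat=float(r.lat),
            lon=float(r.lon),
            mat=float(r.mat_c),
            map_mm=float(r.map_mm),
            crown_cover_class=int(r.crown_cover_class),
            soil_class=str(r.soil_class),
        )
        for r in df.itertuples()
    ]
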