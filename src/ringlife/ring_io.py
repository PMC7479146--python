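"""Reading, writing and screening of tree-ring data.

Supports the Tucson (ITRDB) decadal RWL dialect and a long-form CSV, merges
duplicate cores from the same stem, derives per-tree summaries, applies the
dead/living classification rule and the site- and species-level screening
used to retain only samples that can support lifespan estimation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    RingSeries,
    SiteRecord,
    TreeSummary,
    frame_to_sites,
    sites_to_frame,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)

# Tucson stop markers by measurement unit (mm per integer count)
_STOP_001 = 999      # 0.01 mm units
_STOP_0001 = -9999   # 0.001 mm units

_LONG_COLUMNS = ["tree_id", "site_id", "species", "cambial_age", "ring_width_mm", "status"]


# ---------------------------------------------------------------------------
# Tucson RWL
# ---------------------------------------------------------------------------

def read_rwl(path) -> list[RingSeries]:
    """Parse a Tucson decadal ring-width file.

    Units are auto-detected from the stop marker: ``999`` terminates a series
    measured in 0.01 mm, ``-9999`` one measured in 0.001 mm. Mixing the two
    in one file is rejected. Site, species and status metadata are not part
    of the format and are left blank.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        logger.warning("RWL file %s is empty", path)
        return []

    scale: Optional[float] = None
    order: list[str] = []
    open_vals: dict[str, list[float]] = {}
    closed: dict[str, np.ndarray] = {}

    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:].split()
        if not sid or len(rest) < 2:
            raise ValueError(f"{path}:{lineno}: malformed decade row: {raw!r}")
        try:
            int(rest[0])
            vals = [int(tok) for tok in rest[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed decade row: {raw!r}") from exc
        if sid in closed:
            raise ValueError(f"{path}:{lineno}: data after stop marker for series {sid!r}")
        if sid not in open_vals:
            open_vals[sid] = []
            order.append(sid)
        for v in vals:
            if v == _STOP_001 or v == _STOP_0001:
                this_scale = 0.01 if v == _STOP_001 else 0.001
                if scale is None:
                    scale = this_scale
                elif scale != this_scale:
                    raise ValueError(f"{path}:{lineno}: mixed measurement units in one file")
                closed[sid] = np.array(open_vals.pop(sid), dtype=float) * scale
                break
            open_vals[sid].append(float(v))

    if open_vals:
        missing = ", ".join(sorted(open_vals))
        raise ValueError(f"{path}: series without stop marker: {missing}")

    out = []
    for sid in order:
        widths = closed[sid]
        if widths.size == 0:
            logger.warning("series %s in %s has no rings; skipped", sid, path)
            continue
        out.append(RingSeries(tree_id=sid, widths=widths))
    return out


def write_rwl(series: Iterable[RingSeries], path, units: float = 0.01) -> None:
    """Write series in Tucson decadal format.

    ``units`` is the measurement resolution in mm (0.01 -> ``999`` stop
    marker, 0.001 -> ``-9999``). Rows are indexed by cambial age starting at
    1 and break at decade boundaries, matching the ITRDB convention.
    """
    if units not in (0.01, 0.001):
        raise ValueError("units must be 0.01 or 0.001 mm")
    stop = _STOP_001 if units == 0.01 else _STOP_0001
    lines = []
    for s in series:
        sid = s.tree_id[:8]
        vals = np.rint(s.widths / units).astype(int)
        if np.any(vals >= abs(stop)):
            raise ValueError(
                f"series {s.tree_id!r}: width collides with the stop marker at {units} mm units"
            )
        tokens = [str(v) for v in vals] + [str(stop)]
        age = 1
        i = 0
        while i < len(tokens):
            # fill to the end of the current decade (ages age .. age//10*10+9)
            n_in_row = 10 - (age % 10) if age % 10 != 0 else 10
            row = tokens[i : i + n_in_row]
            lines.append(f"{sid:<8}{age:>4}" + "".join(f"{t:>6}" for t in row))
            i += len(row)
            age += len(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Long-form CSV
# ---------------------------------------------------------------------------

def write_long_csv(series: Iterable[RingSeries], path) -> None:
    """Write series as long-form CSV (one row per ring)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "tree_id": s.tree_id,
                    "site_id": s.site_id,
                    "species": s.species,
                    "cambial_age": np.arange(1, s.age + 1),
                    "ring_width_mm": s.widths,
                    "status": s.status,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_long_csv(path) -> list[RingSeries]:
    df = pd.read_csv(path)
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("tree_id", sort=False):
        grp = grp.sort_values("cambial_age")
        ages = grp["cambial_age"].to_numpy()
        if not np.array_equal(ages, np.arange(1, len(ages) + 1)):
            raise ValueError(f"{path}: tree {tid!r}: cambial ages not contiguous from 1")
        out.append(
            RingSeries(
                tree_id=str(tid),
                widths=grp["ring_width_mm"].to_numpy(dtype=float),
                site_id=str(grp["site_id"].iloc[0]),
                species=str(grp["species"].iloc[0]),
                status=str(grp["status"].iloc[0]),
            )
        )
    return out


def write_sites_csv(sites: Iterable[SiteRecord], path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)


def read_sites_csv(path) -> list[SiteRecord]:
    return frame_to_sites(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Duplicate-core merging
# ---------------------------------------------------------------------------

_SEPARATORS = "-_./"


def _stem(tree_id: str) -> str:
    """ID minus its final character, minus a trailing separator."""
    if len(tree_id) < 2:
        return tree_id
    stem = tree_id[:-1]
    return stem.rstrip(_SEPARATORS)


def merge_duplicate_cores(series: Sequence[RingSeries], how: str = "mean") -> list[RingSeries]:
    """Combine cores whose IDs differ only in the final character.

    Cores ``01a``/``01b`` or ``ID1-1``/``ID1-2`` are treated as one stem:
    widths are combined per cambial age (mean of the cores present at that
    age, or the first core with ``how="first"``), aligned at the pith, and
    the merged age is the maximum member age. Members from different sites
    or species are refused.
    """
    if how not in ("mean", "first"):
        raise ValueError("how must be 'mean' or 'first'")
    groups: dict[str, list[RingSeries]] = {}
    order: list[str] = []
    for s in series:
        key = _stem(s.tree_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)

    out = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
            continue
        sites = {m.site_id for m in members}
        specs = {m.species for m in members}
        if len(sites) > 1 or len(specs) > 1:
            ids = [m.tree_id for m in members]
            raise ValueError(f"cannot merge {ids}: differing site or species codes")
        max_age = max(m.age for m in members)
        if how == "first":
            widths = np.full(max_age, np.nan)
            for m in members:
                gap = np.isnan(widths[: m.age])
                widths[: m.age][gap] = m.widths[gap]
        else:
            acc = np.zeros(max_age)
            cnt = np.zeros(max_age)
            for m in members:
                acc[: m.age] += m.widths
                cnt[: m.age] += 1
            widths = acc / cnt
        years = [m.last_calendar_year for m in members if m.last_calendar_year is not None]
        statuses = {m.status for m in members}
        logger.info("merged %d cores into stem %r", len(members), key)
        out.append(
            RingSeries(
                tree_id=key,
                widths=widths,
                site_id=members[0].site_id,
                species=members[0].species,
                last_calendar_year=max(years) if years else None,
                status=statuses.pop() if len(statuses) == 1 else "unknown",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries and screening
# ---------------------------------------------------------------------------

def summarize_tree(series: RingSeries) -> TreeSummary:
    """Early growth (mean of first 10 rings), age, and max diameter.

    Raises ``ValueError`` for series shorter than 10 rings — early growth is
    undefined there and such trees are excluded upstream.
    """
    if series.age < 10:
        raise ValueError(f"tree {series.tree_id!r}: fewer than 10 rings ({series.age})")
    rw = float(series.widths[:10].mean())
    if rw <= 0:
        raise ValueError(f"tree {series.tree_id!r}: zero early growth")
    return TreeSummary(
        tree_id=series.tree_id,
        site_id=series.site_id,
        species=series.species,
        early_growth=rw,
        age=series.age,
        max_diameter=series.max_diameter,
        status=series.status,
    )


def summarize_trees(series: Iterable[RingSeries]) -> tuple[pd.DataFrame, int]:
    """Summaries for all eligible trees plus the count excluded (<10 rings)."""
    kept, excluded = [], 0
    for s in series:
        try:
            kept.append(summarize_tree(s))
        except ValueError:
            excluded += 1
    if excluded:
        logger.info("excluded %d trees with fewer than 10 rings", excluded)
    return summaries_to_frame(kept), excluded


def classify_dead(series: RingSeries, cutoff_year: int = 1900) -> str:
    """Life status from the date of the outermost ring.

    Archive records whose last ring formed strictly before ``cutoff_year``
    are assumed dead at sampling (no collections predate it); an explicit
    status flag on the series overrides the rule; no calendar information
    yields ``"unknown"``.
    """
    if series.status != "unknown":
        return series.status
    if series.last_calendar_year is None:
        return "unknown"
    return "dead" if series.last_calendar_year < cutoff_year else "alive"


def filter_sites(
    summaries: pd.DataFrame,
    min_records: int = 20,
    min_cv_age_pct: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain sites with enough trees and an uneven age structure.

    A site is kept iff it has at least ``min_records`` trees and its age
    coefficient of variation, CV_Age = sd(age)/mean(age) x 100 (sample sd,
    n-1 denominator), is at least ``min_cv_age_pct`` percent. Even-aged
    sites cannot constrain maximum lifespan. Returns the retained summaries
    and a per-site report.
    """
    rows = []
    for site, grp in summaries.groupby("site_id", sort=True):
        n = len(grp)
        ages = grp["age"].to_numpy(dtype=float)
        cv = float(ages.std(ddof=1) / ages.mean() * 100.0) if n > 1 else 0.0
        kept = n >= min_records and cv >= min_cv_age_pct
        reason = "" if kept else ("too_few_records" if n < min_records else "cv_age_below_threshold")
        rows.append((site, n, cv, kept, reason))
    report = pd.DataFrame(rows, columns=["site_id", "n", "cv_age_pct", "kept", "reason"])
    kept_sites = set(report.loc[report["kept"], "site_id"])
    retained = summaries[summaries["site_id"].isin(kept_sites)].reset_index(drop=True)
    return retained, report


def filter_species(
    summaries: pd.DataFrame,
    min_sites: int = 3,
    min_series: int = 100,
    min_species_level: int = 30,
    min_within_species: int = 150,
    source: str = "other",
) -> pd.DataFrame:
    """Species eligibility flags for the two analysis levels.

    ``species_level`` (cross-species lifespan estimates) requires at least
    ``min_species_level`` trees; ``within_species`` (per-species trade-off
    fits) requires strictly more than ``min_within_species`` trees from at
    least ``min_sites`` sites. For archive (``source="ITRDB"``) data the
    repository-inclusion rule — >= ``min_sites`` sites and >= ``min_series``
    total series — is applied on top. Site screening is assumed done.
    """
    rows = []
    for spec, grp in summaries.groupby("species", sort=True):
        n = len(grp)
        n_sites = grp["site_id"].nunique()
        included = True
        if source.upper() == "ITRDB":
            included = n_sites >= min_sites and n >= min_series
        species_level = included and n >= min_species_level
        within_species = included and n > min_within_species and n_sites >= min_sites
        rows.append((spec, n, n_sites, included, species_level, within_species))
    return pd.DataFrame(
        rows,
        columns=["species", "n", "n_sites", "source_included", "species_level", "within_species"],
    )
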