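"""Fossil-pollen processing: sample filters, 500-year binning, presence thresholds, gridding.

Site-level pollen archives (grain counts with chronological metadata) are
reduced to presence/absence on the coarse evaluation grid: samples failing
the count/age/depositional filters are dropped, per-site abundances are
aggregated to consecutive 500-year bins with weights combining chronological
precision and temporal distance from the bin centre, taxon-specific relative
abundance thresholds decide presence, and sites are collapsed onto grid cells
("present if at least one site is present"; cells without any retained site
carry no data and are excluded from evaluation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceGrid",
    "DEFAULT_THRESHOLDS",
    "filter_samples",
    "bin_and_average",
    "abundance_to_presence",
    "assign_undetermined_quercus",
    "grid_presence",
]

#: relative-abundance presence thresholds from biome reconstructions
DEFAULT_THRESHOLDS = {
    "Fagus": 0.01,
    "Abies": 0.01,
    "Quercus": 0.025,
    # synthetic-world taxa reuse the oak/beech calibrations
    "oak_like": 0.025,
    "beech_like": 0.01,
}

MIN_GRAIN_COUNT = 200       # retained iff strictly more grains than this
MAX_AGE_UNCERTAINTY = 500   # retained iff strictly less than this (years)

PRESENT, ABSENT, NO_DATA = 1, 0, -1


@dataclass
class PresenceGrid:
    """Per-coarse-cell observed state for one taxon and one time bin.

    ``state`` holds 1 (present), 0 (absent) or -1 (no retained site: no data).
    """

    state: np.ndarray
    taxon: str = ""
    bin_bp: int | None = None

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=np.int8)

    @property
    def data_mask(self) -> np.ndarray:
        return self.state != NO_DATA


def filter_samples(archive: pd.DataFrame) -> pd.DataFrame:
    """Apply the conjunctive sample retention filters.

    A sample is retained iff it has strictly more than 200 grains, an age
    uncertainty strictly below 500 years, and a non-marine depositional
    environment.  Removal counts per criterion are logged and attached to the
    result as ``df.attrs['removals']``.
    """
    required = {"total_count", "age_uncertainty_yr", "depositional_env"}
    missing = required - set(archive.columns)
    if missing:
        raise KeyError(f"archive is missing metadata columns: {sorted(missing)}")
    low_count = ~(archive["total_count"] > MIN_GRAIN_COUNT)
    vague_age = ~(archive["age_uncertainty_yr"] < MAX_AGE_UNCERTAINTY)
    marine = archive["depositional_env"] == "marine"
    keep = ~(low_count | vague_age | marine)
    removals = {
        "low_count": int(low_count.sum()),
        "age_uncertainty": int(vague_age.sum()),
        "marine": int(marine.sum()),
        "retained": int(keep.sum()),
    }
    logger.info("pollen sample filters: %s", removals)
    out = archive.loc[keep].reset_index(drop=True)
    out.attrs["removals"] = removals
    return out


def bin_and_average(
    samples: pd.DataFrame,
    bin_width: int = 500,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-site relative abundances to consecutive time bins.

    Bins are aligned so centres fall at ``bin_width/2 + k*bin_width`` model
    years BP (250, 750, ... for the default width).  Within a site x bin,
    abundances are averaged with weights ``w_i = 1/(sigma_i + 1yr) *
    max(0, 1 - |t_i - t_c| / (bin_width/2))`` — chronological precision times
    a triangular taper towards the bin edges.  If every weight in a non-empty
    bin vanishes (all samples exactly on the edges), the unweighted mean is
    used and the row is flagged.

    Returns rows (site_id, x, y, bin_bp, taxon, relative_abundance,
    effective_weight, fallback_unweighted).
    """
    if taxa is None:
        taxa = [c[len("count_"):] for c in samples.columns if c.startswith("count_")]
    if not taxa:
        raise ValueError("no taxon count columns found")
    half = bin_width / 2.0
    t = samples["sample_age_bp"].to_numpy(dtype=float)
    bin_idx = np.floor(t / bin_width).astype(int)
    bin_centre = bin_idx * bin_width + half
    w = (1.0 / (samples["age_uncertainty_yr"].to_numpy(dtype=float) + 1.0)) * np.clip(
        1.0 - np.abs(t - bin_centre) / half, 0.0, None)

    df = samples.copy()
    df["_bin"] = bin_centre.astype(int)
    df["_w"] = w
    rows = []
    for (site, b), grp in df.groupby(["site_id", "_bin"], sort=True):
        wsum = grp["_w"].sum()
        fallback = wsum <= 0.0
        weights = np.full(len(grp), 1.0 / len(grp)) if fallback else \
            grp["_w"].to_numpy() / wsum
        for taxon in taxa:
            rel = grp[f"count_{taxon}"].to_numpy() / grp["total_count"].to_numpy()
            rows.append({
                "site_id": site,
                "x": float(grp["x"].iloc[0]),
                "y": float(grp["y"].iloc[0]),
                "bin_bp": int(b),
                "taxon": taxon,
                "relative_abundance": float(np.sum(weights * rel)),
                "effective_weight": float(wsum),
                "fallback_unweighted": bool(fallback),
            })
        if fallback:
            logger.warning("all weights zero for %s in bin %s; unweighted mean used",
                           site, b)
    return pd.DataFrame(rows)


def abundance_to_presence(
    relative_abundance: float | np.ndarray,
    taxon: str,
    thresholds: dict[str, float] | None = None,
):
    """Presence iff relative abundance >= the taxon's biome-calibrated threshold."""
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    if taxon not in thresholds:
        raise KeyError(f"no abundance threshold configured for taxon {taxon!r}")
    return np.asarray(relative_abundance) >= thresholds[taxon]


def assign_undetermined_quercus(site_xy, evergreen_range: BaseGeometry) -> str:
    """Classify undetermined oak pollen by the evergreen-oak natural range.

    A site inside (or on the boundary of) the evergreen range polygon counts
    as both evergreen and deciduous occurrence; outside, deciduous only.
    """
    if not evergreen_range.is_valid:
        raise ValueError("invalid evergreen range geometry")
    pt = Point(float(site_xy[0]), float(site_xy[1]))
    return "both" if evergreen_range.covers(pt) else "deciduous-only"


def grid_presence(
    site_presences: pd.DataFrame,
    shape: tuple[int, int],
    taxon: str = "",
    bin_bp: int | None = None,
) -> PresenceGrid:
    """Collapse site-level presence onto the coarse grid.

    ``site_presences`` needs columns x, y (cell units: col, row) and
    ``present`` (bool).  A cell is present iff at least one of its sites is
    present, absent iff it has sites and all are absent, and no-data
    otherwise.  Sites falling outside the grid are logged and skipped.
    """
    nr, nc = shape
    state = np.full((nr, nc), NO_DATA, dtype=np.int8)
    n_outside = 0
    for _, row in site_presences.iterrows():
        c, r = int(np.floor(row["x"])), int(np.floor(row["y"]))
        if not (0 <= r < nr and 0 <= c < nc):
            n_outside += 1
            continue
        if bool(row["present"]):
            state[r, c] = PRESENT
        elif state[r, c] == NO_DATA:
            state[r, c] = ABSENT
    if n_outside:
        logger.warning("%d sites fell outside the grid and were skipped", n_outside)
    return PresenceGrid(state=state, taxon=taxon, bin_bp=bin_bp)
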