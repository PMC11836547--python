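"""Synthetic study system: gridded paleoclimate, virtual species and fossil-pollen archives.

Everything downstream (suitability surrogates, the migration cellular automaton,
pollen processing, dissimilarity, evaluation) is exercised against worlds built
here, where the ground truth is known exactly.

The climate generator emulates a Holocene-like trajectory: an abrupt early
warming at a configurable changepoint followed by near-stationary climate,
delivered as 30-year windows of annual values every 250 model-years, on a
rectangular grid with a latitudinal temperature gradient and a longitudinal
moisture gradient.  All randomness flows through a single NumPy ``Generator``
seeded from the configuration, so identical configurations give bit-identical
worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeConfig",
    "ClimateTrajectory",
    "ClimateSlice",
    "VirtualSpecies",
    "gen_climate_series",
    "downscale_elevation",
    "gen_true_occupancy",
    "gen_pollen_archive",
    "POLLEN_COLUMNS",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Grid geometry shared by every stage.

    The coarse grid carries climate, suitability and pollen presence (the
    0.25-degree analogue); each coarse cell subdivides into
    ``fine_per_coarse ** 2`` fine cells on which dispersal runs (the 500 m
    analogue).
    """

    n_rows: int = 40
    n_cols: int = 40
    coarse_cell_km: float = 25.0
    fine_per_coarse: int = 2
    elevation: np.ndarray | None = None  # metres, coarse grid
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.fine_per_coarse < 1:
            raise ValueError("fine_per_coarse must be >= 1")
        if self.elevation is not None:
            elev = np.asarray(self.elevation, dtype=float)
            if elev.shape != (self.n_rows, self.n_cols):
                raise ValueError("elevation shape must match the coarse grid")
            object.__setattr__(self, "elevation", elev)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_rows * self.fine_per_coarse, self.n_cols * self.fine_per_coarse)

    def elevation_or_zero(self) -> np.ndarray:
        if self.elevation is None:
            return np.zeros(self.shape)
        return self.elevation


@dataclass(frozen=True)
class ClimateTrajectory:
    """Trend specification for the climate series.

    The temperature anomaly is ``-amplitude_c * sigmoid((t - changepoint_bp) /
    transition_yr)`` so that slices much older than the changepoint sit the
    full amplitude below the stable late-period climate, with a smooth ramp of
    width ``transition_yr`` in between.
    """

    start_bp: int = 12_000
    end_bp: int = 500
    step_yr: int = 250
    amplitude_c: float = 8.5
    changepoint_bp: int = 10_750
    transition_yr: float = 350.0
    noise_sd: float = 0.5          # interannual sd of annual temperature, deg C
    n_years_window: int = 30
    # spatial structure of the stable (late) climate: growing-season heat is
    # latitudinal while winter minima are mostly continental (east-west), so
    # the two decouple once the cold-phase anomaly is applied
    tmin_south_c: float = 3.0      # winter-minimum temperature at the mild corner
    lat_range_c: float = 3.0       # south-to-north winter cooling
    tmin_lon_range_c: float = 6.0  # west-to-east (oceanic-to-continental) cooling
    gdd_south: float = 3200.0      # growing degree-days at the southern edge
    gdd_lat_range: float = 1800.0
    gdd_per_degc: float = 40.0     # GDD response to the (winter) temperature anomaly
    precip_base_mm: float = 500.0
    precip_lon_range_mm: float = 400.0
    wb_base_mm: float = -10.0      # summer water balance, dry end
    wb_lon_range_mm: float = 120.0
    wb_per_degc: float = 2.0

    def __post_init__(self):
        if self.step_yr <= 0:
            raise ValueError("slice spacing must be positive")
        if self.end_bp >= self.start_bp:
            raise ValueError("series must run from an older start to a younger end")

    def times(self) -> np.ndarray:
        """Slice times, oldest first, every ``step_yr`` model-years."""
        return np.arange(self.start_bp, self.end_bp - 1, -self.step_yr)

    def anomaly(self, time_bp) -> np.ndarray | float:
        from scipy.special import expit

        return -self.amplitude_c * expit(
            (np.asarray(time_bp, dtype=float) - self.changepoint_bp) / self.transition_yr
        )


# ---------------------------------------------------------------------------
# climate slices
# ---------------------------------------------------------------------------

@dataclass
class ClimateSlice:
    """Per-cell climate summaries for one 30-year window centred on ``time_bp``.

    ``tmin_winter``, ``gdd``, ``precip_total`` and ``water_balance_summer``
    are window means (the covariates the suitability models consume);
    ``seasonal_tmean`` and ``seasonal_prec`` keep the per-year 3-month
    summaries (shape ``(n_years, 4, n_rows, n_cols)``) used by the climatic
    hypervolume analysis.
    """

    time_bp: int
    tmin_winter: np.ndarray
    gdd: np.ndarray
    precip_total: np.ndarray
    water_balance_summer: np.ndarray
    seasonal_tmean: np.ndarray
    seasonal_prec: np.ndarray

    def __post_init__(self):
        if np.any(self.precip_total < 0):
            raise ValueError("total precipitation must be non-negative")
        if np.any(self.seasonal_prec < 0):
            raise ValueError("seasonal precipitation sums must be non-negative")
        if np.any(self.gdd < 0):
            raise ValueError("growing degree-days must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin_winter.shape

    def covariates(self) -> dict[str, np.ndarray]:
        return {
            "tmin_winter": self.tmin_winter,
            "gdd": self.gdd,
            "precip_total": self.precip_total,
            "water_balance_summer": self.water_balance_summer,
        }


COVARIATE_NAMES = ("tmin_winter", "gdd", "precip_total", "water_balance_summer")

# seasonal offsets (deg C) of 3-month mean temperature relative to the winter
# minimum field, and the share of annual precipitation falling in each season
_SEASON_TEMP_OFFSET = np.array([2.0, 10.0, 18.0, 9.0])
_SEASON_PREC_SHARE = np.array([0.28, 0.24, 0.20, 0.28])


def gen_climate_series(
    config: LandscapeConfig, trajectory: ClimateTrajectory | None = None
) -> list[ClimateSlice]:
    """Generate the full climate trajectory as a time-ordered list of slices.

    Deterministic given ``(config, trajectory)``: the generator is seeded from
    ``config.seed``.  With ``noise_sd=0`` every field is an exact function of
    time and position.
    """
    traj = trajectory or ClimateTrajectory()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.shape
    lat = np.linspace(1.0, 0.0, nr)[:, None]   # 1 at the northern edge (row 0)
    lon = np.linspace(0.0, 1.0, nc)[None, :]
    elev_km = config.elevation_or_zero() / 1000.0
    ny = traj.n_years_window

    tmin_base = (traj.tmin_south_c - traj.lat_range_c * lat
                 - traj.tmin_lon_range_c * lon - 6.5 * elev_km)
    gdd_base = traj.gdd_south - traj.gdd_lat_range * lat - 400.0 * elev_km
    precip_base = traj.precip_base_mm + traj.precip_lon_range_mm * lon
    wb_base = traj.wb_base_mm + traj.wb_lon_range_mm * lon

    slices: list[ClimateSlice] = []
    for t in traj.times():
        anom = float(traj.anomaly(t))
        noise_t = rng.normal(0.0, traj.noise_sd, size=(ny, nr, nc))
        noise_p = rng.normal(0.0, 20.0 * (traj.noise_sd / 0.5 if traj.noise_sd else 0.0),
                             size=(ny, nr, nc))
        annual_tmin = tmin_base + anom + noise_t
        annual_gdd = np.clip(gdd_base + traj.gdd_per_degc * anom + 80.0 * noise_t, 0.0, None)
        annual_prec = np.clip(precip_base + noise_p, 0.0, None)
        annual_wb = wb_base + traj.wb_per_degc * anom + 0.5 * noise_p[..., :, :]

        seasonal_tmean = (
            annual_tmin[:, None, :, :]
            + _SEASON_TEMP_OFFSET[None, :, None, None]
            + rng.normal(0.0, traj.noise_sd, size=(ny, 4, nr, nc))
        )
        seasonal_prec = np.clip(
            annual_prec[:, None, :, :] * _SEASON_PREC_SHARE[None, :, None, None]
            + rng.normal(0.0, 5.0 * (traj.noise_sd / 0.5 if traj.noise_sd else 0.0),
                         size=(ny, 4, nr, nc)),
            0.0,
            None,
        )
        slices.append(
            ClimateSlice(
                time_bp=int(t),
                tmin_winter=annual_tmin.mean(axis=0),
                gdd=annual_gdd.mean(axis=0),
                precip_total=annual_prec.mean(axis=0),
                water_balance_summer=annual_wb.mean(axis=0),
                seasonal_tmean=seasonal_tmean,
                seasonal_prec=seasonal_prec,
            )
        )
    return slices


def downscale_elevation(
    coarse: ClimateSlice,
    fine_elevation: np.ndarray,
    coarse_elevation: np.ndarray | None = None,
    lapse_rate: float = 6.5,
) -> ClimateSlice:
    """Elevation-correct a coarse slice onto a nested fine grid.

    Temperatures drop by ``lapse_rate`` deg C per km of elevation above the
    parent coarse cell; precipitation and water balance are copied unchanged.
    ``fine_elevation`` must tile the coarse grid by an integer factor.
    """
    fine_elevation = np.asarray(fine_elevation, dtype=float)
    nr, nc = coarse.shape
    fr, fc = fine_elevation.shape
    if fr % nr or fc % nc or fr // nr != fc // nc:
        raise ValueError("fine grid does not nest in the coarse grid")
    f = fr // nr
    if coarse_elevation is None:
        coarse_elevation = np.zeros(coarse.shape)
    coarse_elevation = np.asarray(coarse_elevation, dtype=float)
    if coarse_elevation.shape != coarse.shape:
        raise ValueError("coarse elevation shape mismatch")

    delta_km = (fine_elevation - np.kron(coarse_elevation, np.ones((f, f)))) / 1000.0
    correction = -lapse_rate * delta_km

    def up(a: np.ndarray) -> np.ndarray:
        return np.kron(a, np.ones((f, f)))

    return ClimateSlice(
        time_bp=coarse.time_bp,
        tmin_winter=up(coarse.tmin_winter) + correction,
        gdd=np.clip(up(coarse.gdd) + 80.0 * correction, 0.0, None),
        precip_total=up(coarse.precip_total),
        water_balance_summer=up(coarse.water_balance_summer),
        seasonal_tmean=np.kron(coarse.seasonal_tmean, np.ones((f, f)))
        + correction[None, None, :, :],
        seasonal_prec=np.kron(coarse.seasonal_prec, np.ones((f, f))),
    )


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualSpecies:
    """Mechanistic response of a virtual tree: three logistic fitness components.

    Fitness = frost survival (winter minimum temperature) x drought survival
    (summer water balance) x reproductive success (growing degree-days), each a
    logistic with midpoint ``*_t50``-style parameter and positive slope (the
    covariate range over which the component rises).
    """

    frost_t50: float = -9.0
    frost_slope: float = 2.0
    drought_w50: float = -60.0
    drought_slope: float = 25.0
    gdd_req: float = 1600.0
    gdd_slope: float = 200.0
    name: str = "virtual"

    def __post_init__(self):
        if min(self.frost_slope, self.drought_slope, self.gdd_slope) <= 0:
            raise ValueError("response slopes must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.frost_t50, self.frost_slope, self.drought_w50,
             self.drought_slope, self.gdd_req, self.gdd_slope]
        )

    @classmethod
    def from_array(cls, a, name: str = "fitted") -> "VirtualSpecies":
        return cls(frost_t50=float(a[0]), frost_slope=float(a[1]),
                   drought_w50=float(a[2]), drought_slope=float(a[3]),
                   gdd_req=float(a[4]), gdd_slope=float(a[5]), name=name)


def perturb_species(species: VirtualSpecies, rel_err: float,
                    rng: np.random.Generator, name: str | None = None
                    ) -> VirtualSpecies:
    """Apply independent measurement error to mechanistic parameters.

    Emulates expert parameterisation from field/laboratory measurements:
    response midpoints are shifted by a normal error scaled to the response
    width (2 x slope), slopes are perturbed lognormally.  ``rel_err=0``
    returns the parameters unchanged.
    """
    if rel_err < 0:
        raise ValueError("relative error must be non-negative")
    p = species
    return VirtualSpecies(
        frost_t50=p.frost_t50 + rng.normal(0.0, rel_err * 2.0 * p.frost_slope),
        frost_slope=p.frost_slope * np.exp(rng.normal(0.0, rel_err)),
        drought_w50=p.drought_w50 + rng.normal(0.0, rel_err * 2.0 * p.drought_slope),
        drought_slope=p.drought_slope * np.exp(rng.normal(0.0, rel_err)),
        gdd_req=p.gdd_req + rng.normal(0.0, rel_err * 2.0 * p.gdd_slope),
        gdd_slope=p.gdd_slope * np.exp(rng.normal(0.0, rel_err)),
        name=name or f"{p.name}_expert",
    )


#: two contrasting default species: a frost-tolerant, drought-tolerant
#: "deciduous oak"-like tree and a more frost- and drought-sensitive
#: "beech"-like tree with a higher thermal requirement.
DEFAULT_SPECIES = (
    VirtualSpecies(gdd_req=2200.0, name="oak_like"),
    VirtualSpecies(frost_t50=-6.0, frost_slope=1.5, drought_w50=-30.0,
                   drought_slope=20.0, gdd_req=1900.0, gdd_slope=180.0,
                   name="beech_like"),
)


def gen_true_occupancy(species, climate_series, kernel, rng, tau: float = 0.25,
                       fine_per_coarse: int = 1, years_per_slice: int = 250):
    """True dispersal-limited occupancy: mechanism fitness pushed through migration.

    Combines the species' mechanistic fitness surface (thresholded at ``tau``
    and rescaled against the maximum over the whole series) with the cellular
    automaton, run on the fine grid (coarse probabilities broadcast by
    ``fine_per_coarse``).  Returns the per-slice fine-grid occupancy series.
    """
    from .dispersal import OccupancyGrid, run_migration, threshold_rescale
    from .surrogates import process_fitness

    fitness = [process_fitness(s, species).values for s in climate_series]
    v_max = max(float(f.max()) for f in fitness)
    if v_max <= tau:
        # nowhere ever suitable: the true range is empty at all times
        shape = tuple(n * fine_per_coarse for n in fitness[0].shape)
        return [OccupancyGrid(occupied=np.zeros(shape, bool), time_bp=s.time_bp)
                for s in climate_series]
    prob_maps = [threshold_rescale(f, tau, v_max) for f in fitness]
    if fine_per_coarse > 1:
        up = np.ones((fine_per_coarse, fine_per_coarse))
        prob_maps = [np.kron(p, up) for p in prob_maps]
    times = [s.time_bp for s in climate_series]
    return run_migration(prob_maps, kernel, years_per_slice=years_per_slice,
                         rng=rng, times_bp=times, check_bound=False)


# ---------------------------------------------------------------------------
# pollen archives
# ---------------------------------------------------------------------------

POLLEN_COLUMNS = (
    "site_id", "x", "y", "sample_age_bp", "age_uncertainty_yr",
    "depositional_env", "total_count",
)


@dataclass(frozen=True)
class PollenSitePlan:
    """Placement and sampling intensity of virtual pollen sites."""

    n_sites: int = 120
    samples_per_site_mean: float = 8.0
    marine_fraction: float = 0.1
    lacustrine_fraction: float = 0.45


@dataclass(frozen=True)
class PollenCountModel:
    """Grain totals and chronological error of virtual samples.

    Totals are lognormal around ~330 grains so a realistic share of samples
    falls under the 200-grain retention filter; age uncertainties are gamma
    with mean 250 yr so some exceed the 500-yr filter.
    """

    total_log_mean: float = math.log(330.0)
    total_log_sd: float = 0.6
    age_uncert_shape: float = 2.5
    age_uncert_scale: float = 100.0


@dataclass(frozen=True)
class PollenDetection:
    """Expected relative abundance of a focal taxon given local occupancy.

    A two-level step function: pollen rain from an occupied coarse cell
    carries the taxon at ``p_occupied`` relative abundance, an unoccupied one
    at ``p_unoccupied`` (long-distance background rain).
    """

    p_occupied: float = 0.08
    p_unoccupied: float = 0.002

    def __post_init__(self):
        for p in (self.p_occupied, self.p_unoccupied):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")


def gen_pollen_archive(
    occupancy_truth: dict[str, list[np.ndarray]],
    times_bp,
    config: LandscapeConfig,
    site_plan: PollenSitePlan | None = None,
    count_model: PollenCountModel | None = None,
    detection: PollenDetection | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a site-based pollen archive from true coarse occupancy.

    ``occupancy_truth`` maps taxon name -> per-slice *coarse* presence grids
    aligned with ``times_bp``.  Each sample draws its grain counts from a
    multinomial over (taxa..., other) with expected shares from the detection
    model evaluated at the site's cell and nearest slice; sample ages are the
    true ages jittered by the sample's stated uncertainty.

    Returns a DataFrame with one row per sample: site metadata, jittered age,
    uncertainty, depositional environment, per-taxon counts (``count_<taxon>``)
    and the grain total.
    """
    site_plan = site_plan or PollenSitePlan()
    count_model = count_model or PollenCountModel()
    detection = detection or PollenDetection()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    times_bp = np.asarray(times_bp)
    taxa = list(occupancy_truth)
    nr, nc = config.shape

    sx = rng.uniform(0, nc, site_plan.n_sites)
    sy = rng.uniform(0, nr, site_plan.n_sites)
    env_draw = rng.random(site_plan.n_sites)
    envs = np.where(
        env_draw < site_plan.marine_fraction, "marine",
        np.where(env_draw < site_plan.marine_fraction + site_plan.lacustrine_fraction,
                 "lacustrine", "terrestrial"),
    )

    rows = []
    t_young, t_old = times_bp.min(), times_bp.max()
    for i in range(site_plan.n_sites):
        n_samp = max(1, rng.poisson(site_plan.samples_per_site_mean))
        true_ages = rng.uniform(t_young, t_old, n_samp)
        sigmas = rng.gamma(count_model.age_uncert_shape, count_model.age_uncert_scale, n_samp)
        totals = np.maximum(20, rng.lognormal(
            count_model.total_log_mean, count_model.total_log_sd, n_samp).astype(int))
        cell = (min(int(sy[i]), nr - 1), min(int(sx[i]), nc - 1))
        for age, sigma, total in zip(true_ages, sigmas, totals):
            k = int(np.argmin(np.abs(times_bp - age)))
            shares = np.array([
                detection.p_occupied if occupancy_truth[tx][k][cell] else detection.p_unoccupied
                for tx in taxa
            ])
            shares = np.append(shares, max(0.0, 1.0 - shares.sum()))
            counts = rng.multinomial(total, shares / shares.sum())
            row = {
                "site_id": f"site_{i:04d}",
                "x": sx[i],
                "y": sy[i],
                "sample_age_bp": float(age + rng.normal(0.0, sigma)),
                "age_uncertainty_yr": float(sigma),
                "depositional_env": envs[i],
                "total_count": int(total),
            }
            for tx, c in zip(taxa, counts[:-1]):
                row[f"count_{tx}"] = int(c)
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["site_id", "sample_age_bp"], ignore_index=True)
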