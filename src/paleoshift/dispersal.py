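"""Dispersal-limited range dynamics: a modified cellular-automaton migration model.

Annual colonisation of a fine grid from occupied cells through a fat-tailed
short-distance kernel, plus rare long-distance events (one propagule per
occupied source per year with probability ``ld_probability``), driven by
suitability maps thresholded and rescaled into colonisation probabilities and
updated every 250 model-years.  Colonisation combines propagule arrival and
establishment multiplicatively: an empty cell with rescaled suitability ``p``
reached by kernel mass ``a`` becomes occupied with probability ``p * a``.
Cells whose suitability falls to zero at a slice update are vacated.  Grid
edges are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import oaconvolve

__all__ = [
    "DispersalKernel",
    "OccupancyGrid",
    "NoSuitableHabitatError",
    "discretize_kernel",
    "threshold_rescale",
    "init_occupancy",
    "disperse_step",
    "run_migration",
    "combine_deciduous",
    "coarsen_occupancy",
]


class NoSuitableHabitatError(RuntimeError):
    """Raised when thresholding leaves no colonisable cell anywhere."""


@dataclass
class DispersalKernel:
    """Discretised dispersal kernel.

    ``short_kernel`` is a (2R+1, 2R+1) matrix of non-negative weights summing
    to one over fine-cell offsets up to radius ``radius`` (cells);
    ``ld_probability`` is the per-source per-year chance of one long-distance
    propagule at a distance drawn from ``ld_distances`` (metres, the tail of
    the continuous kernel beyond the truncation radius) at a uniform angle.
    """

    short_kernel: np.ndarray
    radius: int
    ld_probability: float = 0.01
    ld_distances: np.ndarray | None = None  # inverse-CDF table of tail distances (m)
    cell_size_m: float = 500.0

    def __post_init__(self):
        k = np.asarray(self.short_kernel, dtype=float)
        if np.any(k < 0):
            raise ValueError("kernel weights must be non-negative")
        if not np.isclose(k.sum(), 1.0, atol=1e-9):
            raise ValueError("kernel weights must sum to 1")
        if not 0.0 <= self.ld_probability <= 1.0:
            raise ValueError("ld_probability must lie in [0, 1]")
        self.short_kernel = k

    def sample_ld_distance(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.ld_distances is None or len(self.ld_distances) == 0:
            # no tail table: land just beyond the truncation radius
            return np.full(n, (self.radius + 1) * self.cell_size_m)
        u = rng.random(n)
        idx = (u * (len(self.ld_distances) - 1)).astype(int)
        return self.ld_distances[idx]


@dataclass
class OccupancyGrid:
    """Boolean colonised state on the fine grid at one time."""

    occupied: np.ndarray
    time_bp: int | None = None

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied, dtype=bool)

    @property
    def shape(self):
        return self.occupied.shape

    def area(self) -> int:
        return int(self.occupied.sum())


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------

def _radial_density(form: str, params: dict):
    """2-D dispersal density f(r) and its radial mass density 2*pi*r*f(r)."""
    if form == "exponential-power":
        a, c = float(params["a"]), float(params.get("c", 1.0))
        if a <= 0 or c <= 0:
            raise ValueError("exponential-power kernel needs a > 0, c > 0")
        from scipy.special import gamma

        norm = c / (2.0 * np.pi * a**2 * gamma(2.0 / c))
        return lambda r: norm * np.exp(-((np.asarray(r) / a) ** c))
    if form == "2Dt":
        a, b = float(params["a"]), float(params.get("b", 2.0))
        if a <= 0 or b <= 1:
            raise ValueError("2Dt kernel needs a > 0, b > 1 to be integrable")
        norm = (b - 1.0) / (np.pi * a)
        return lambda r: norm * (1.0 + np.asarray(r) ** 2 / a) ** (-b)
    if form == "point":
        return None
    raise ValueError(f"unknown kernel form: {form!r}")


def kernel_radial_cdf(form: str, params: dict, r: np.ndarray) -> np.ndarray:
    """CDF of dispersal distance for the continuous kernel (numeric quadrature)."""
    f2 = _radial_density(form, params)
    if f2 is None:
        return np.ones_like(np.asarray(r, dtype=float))
    r = np.asarray(r, dtype=float)
    grid = np.linspace(0.0, max(r.max(), 1e-9), 20001)
    mass = 2.0 * np.pi * grid * f2(grid)
    cdf = np.concatenate([[0.0], np.cumsum((mass[1:] + mass[:-1]) / 2.0 * np.diff(grid))])
    return np.interp(r, grid, cdf)


def discretize_kernel(
    form: str,
    params: dict | None = None,
    cell_size_m: float = 500.0,
    coverage: float = 0.99,
    radius: int | None = None,
    ld_probability: float = 0.01,
    max_radius: int = 50,
) -> DispersalKernel:
    """Build a discrete kernel matrix from a continuous 2-D dispersal density.

    The truncation radius (in cells) is grown until the continuous kernel mass
    within it reaches ``coverage`` (default 99%); matrix entries are the
    density at each offset-cell midpoint times the cell area, renormalised to
    one.  The mass beyond the radius defines the long-distance tail sampler.
    ``form='point'`` puts all mass at the source cell.
    """
    params = params or {}
    if form == "point":
        return DispersalKernel(short_kernel=np.ones((1, 1)), radius=0,
                               ld_probability=ld_probability,
                               ld_distances=np.array([cell_size_m]),
                               cell_size_m=cell_size_m)
    f2 = _radial_density(form, params)
    if radius is None:
        radius = 1
        while radius < max_radius:
            if kernel_radial_cdf(form, params,
                                 np.array([(radius + 0.5) * cell_size_m]))[0] >= coverage:
                break
            radius += 1
    # integrate the density over each offset cell on a sub-grid of midpoints
    # (a single central midpoint is too crude for sharply peaked kernels)
    sub = 5
    offsets = np.arange(-radius, radius + 1) * cell_size_m
    frac = (np.arange(sub) + 0.5) / sub - 0.5
    pts = (offsets[:, None] + frac[None, :] * cell_size_m).ravel()
    dx, dy = np.meshgrid(pts, pts)
    dens = f2(np.hypot(dx, dy)).reshape(2 * radius + 1, sub, 2 * radius + 1, sub)
    w = dens.mean(axis=(1, 3)) * cell_size_m**2
    dxc, dyc = np.meshgrid(offsets, offsets)
    w[np.hypot(dxc, dyc) > (radius + 0.5) * cell_size_m] = 0.0
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("kernel parameters give no integrable mass on the grid")

    # inverse-CDF table of tail distances beyond the truncation radius
    r_lo = (radius + 0.5) * cell_size_m
    r_hi = r_lo
    while kernel_radial_cdf(form, params, np.array([r_hi]))[0] < 0.9999 and r_hi < 1e7:
        r_hi *= 1.5
    rr = np.linspace(r_lo, r_hi, 2000)
    cdf = kernel_radial_cdf(form, params, rr)
    cdf = (cdf - cdf[0]) / max(cdf[-1] - cdf[0], 1e-300)
    u = np.linspace(0.0, 1.0, 512)
    tail = np.interp(u, cdf, rr)

    return DispersalKernel(short_kernel=w / total, radius=radius,
                           ld_probability=ld_probability, ld_distances=tail,
                           cell_size_m=cell_size_m)


# ---------------------------------------------------------------------------
# suitability -> colonisation probability
# ---------------------------------------------------------------------------

def threshold_rescale(values: np.ndarray, tau: float, v_max: float | None = None) -> np.ndarray:
    """Threshold suitability at ``tau`` and rescale the rest to [0, 1].

    Cells at or below the threshold get zero (the species cannot survive
    there); above it the output is ``(v - tau) / (v_max - tau)``, the
    probability of a cell to become colonised.  ``v_max`` is the species'
    maximum over the calibration-period domain and is frozen per
    species/model so maps are comparable across slices; values above it clip
    to one.
    """
    values = np.asarray(values, dtype=float)
    if v_max is None:
        v_max = float(values.max())
    if v_max <= tau:
        raise NoSuitableHabitatError(
            f"maximum suitability {v_max:.4g} does not exceed threshold {tau:.4g}")
    out = np.clip((values - tau) / (v_max - tau), 0.0, 1.0)
    out[values <= tau] = 0.0
    return out


def init_occupancy(
    prob_maps: list[np.ndarray],
    start_index: int = 0,
    max_defer: int = 1,
    times_bp: list[int] | None = None,
) -> tuple[OccupancyGrid, int]:
    """Initial occupancy: every cell colonisable at the start slice is occupied.

    If the start slice has no suitable cell the start is deferred slice by
    slice up to ``max_defer`` times (the study's fallback one slice later);
    if still empty, raises :class:`NoSuitableHabitatError`.  Returns the grid
    and the index of the slice actually used.
    """
    for k in range(start_index, min(start_index + max_defer + 1, len(prob_maps))):
        occ = prob_maps[k] > 0
        if occ.any():
            t = times_bp[k] if times_bp is not None else None
            return OccupancyGrid(occupied=occ, time_bp=t), k
    raise NoSuitableHabitatError("no suitable cell in any candidate start slice")


# ---------------------------------------------------------------------------
# annual step and multi-slice run
# ---------------------------------------------------------------------------

def disperse_step(
    occ: OccupancyGrid,
    prob_map: np.ndarray,
    kernel: DispersalKernel,
    rng: np.random.Generator,
    check_bound: bool = True,
) -> OccupancyGrid:
    """One annual dispersal step.

    An unoccupied cell with colonisation probability ``p`` becomes occupied
    with probability ``p * [1 - prod_sources(1 - k(source -> cell))]`` over
    the short kernel; independently each occupied source triggers, with
    probability ``ld_probability``, one long-distance propagule at a sampled
    tail distance and uniform angle that establishes at its landing cell with
    that cell's probability.  Occupied cells stay occupied; zero-probability
    cells never colonise; off-grid propagules are lost.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if occ.shape != prob_map.shape:
        raise ValueError("occupancy and probability grids are misaligned")
    cur = occ.occupied
    if not cur.any():
        return OccupancyGrid(occupied=cur.copy(), time_bp=occ.time_bp)

    # FFT convolution accumulates the per-source log-miss terms; its numerical
    # noise (~1e-13) is floored away: a cell inside the kernel support of any
    # source receives at least the smallest nonzero kernel weight, so arrivals
    # below half that weight can only be FFT noise and are exactly zero
    w = kernel.short_kernel
    log_miss = np.log1p(-np.minimum(w, 1.0 - 1e-12))
    s = oaconvolve(cur.astype(float), log_miss, mode="same")
    arrival = -np.expm1(np.minimum(s, 0.0))
    min_w = w[w > 0].min()
    arrival[arrival < 0.5 * min_w] = 0.0
    arrival[arrival > 1.0 - 1e-9] = 1.0

    p_col = prob_map * arrival
    p_col[cur] = 0.0
    new = cur | (rng.random(cur.shape) < p_col)

    if kernel.ld_probability > 0:
        src_r, src_c = np.nonzero(cur)
        trigger = rng.random(len(src_r)) < kernel.ld_probability
        n_ld = int(trigger.sum())
        if n_ld:
            d_cells = kernel.sample_ld_distance(rng, n_ld) / kernel.cell_size_m
            theta = rng.uniform(0.0, 2.0 * np.pi, n_ld)
            lr = np.rint(src_r[trigger] + d_cells * np.sin(theta)).astype(int)
            lc = np.rint(src_c[trigger] + d_cells * np.cos(theta)).astype(int)
            nr, nc = cur.shape
            ok = (lr >= 0) & (lr < nr) & (lc >= 0) & (lc < nc)
            lr, lc = lr[ok], lc[ok]
            est = rng.random(len(lr)) < prob_map[lr, lc]
            new[lr[est], lc[est]] = True
    elif check_bound:
        # hard bound: without long-distance events the front moves <= R cells/yr
        reach = maximum_filter(cur, size=2 * kernel.radius + 1, mode="constant")
        assert not np.any(new & ~reach), "spread exceeded the kernel radius"

    return OccupancyGrid(occupied=new, time_bp=occ.time_bp)


def run_migration(
    prob_maps: list[np.ndarray],
    kernel: DispersalKernel,
    years_per_slice: int = 250,
    rng: np.random.Generator | None = None,
    times_bp: list[int] | None = None,
    max_defer: int = 1,
    check_bound: bool = True,
) -> list[OccupancyGrid]:
    """Run the automaton across a time-ordered series of colonisation-probability maps.

    Initialises from the first slice with suitable habitat (deferring up to
    ``max_defer`` slices), then performs ``years_per_slice`` annual steps per
    slice with that slice's map.  At each slice update, occupied cells whose
    probability has become zero are vacated (local extinction).  Returns one
    occupancy snapshot per slice; slices before the (possibly deferred) start
    are empty grids.
    """
    if not prob_maps:
        raise ValueError("empty suitability series")
    rng = rng if rng is not None else np.random.default_rng(0)
    occ, start = init_occupancy(prob_maps, max_defer=max_defer, times_bp=times_bp)
    shape = prob_maps[0].shape
    series: list[OccupancyGrid] = []
    for k in range(len(prob_maps)):
        t = times_bp[k] if times_bp is not None else None
        if k < start:
            series.append(OccupancyGrid(occupied=np.zeros(shape, bool), time_bp=t))
            continue
        pmap = np.asarray(prob_maps[k], dtype=float)
        cur = occ.occupied & (pmap > 0.0)  # vacate cells that became unsuitable
        occ = OccupancyGrid(occupied=cur, time_bp=t)
        suitable = pmap > 0.0
        for _ in range(years_per_slice):
            # state is absorbing once every suitable cell is occupied (or none left)
            if not occ.occupied.any() or not np.any(suitable & ~occ.occupied):
                break
            occ = disperse_step(occ, pmap, kernel, rng, check_bound=check_bound)
        occ = OccupancyGrid(occupied=occ.occupied, time_bp=t)
        series.append(occ)
    return series


# ---------------------------------------------------------------------------
# map algebra
# ---------------------------------------------------------------------------

def combine_deciduous(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Elementwise maximum of two suitability maps (the two deciduous oaks)."""
    a, b = np.asarray(map_a, dtype=float), np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("suitability maps have mismatched shapes")
    return np.maximum(a, b)


def coarsen_occupancy(occ: OccupancyGrid | np.ndarray, fine_per_coarse: int) -> np.ndarray:
    """Coarse presence: a coarse cell is present iff any of its fine cells is occupied."""
    grid = occ.occupied if isinstance(occ, OccupancyGrid) else np.asarray(occ, dtype=bool)
    f = int(fine_per_coarse)
    nr, nc = grid.shape
    if nr % f or nc % f:
        raise ValueError("fine grid does not nest in the coarse grid")
    return grid.reshape(nr // f, f, nc // f, f).any(axis=(1, 3))
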