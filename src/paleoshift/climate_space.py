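"""Climatic dissimilarity: bootstrapped KDE hypervolume overlap, novelty, bias correction.

The dissimilarity between a focal period and the reference period is
``1 - Sorensen overlap`` between bootstrapped climatic hypervolumes: seasonal
climate samples (four 3-month temperature means and four 3-month
precipitation sums per cell per year) are projected onto the first three
principal components, each period yields ``n_boot`` hypervolumes (Gaussian
KDE regions containing 95% of a bootstrap resample), and the mean and
standard deviation of ``1 - Sorensen`` over all ``n_boot x n_boot`` pairs is
reported.  Mahalanobis distance to the reference pool gives a per-cell
novelty alternative, and a delta (temperature) / ratio (precipitation)
correction removes constant simulation bias against a reference-window
observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde

from .synthetic_world import ClimateSlice

logger = logging.getLogger(__name__)

__all__ = [
    "Hypervolume",
    "DissimilarityEstimate",
    "seasonal_features",
    "bias_correct",
    "pca_reference",
    "ReferenceProjection",
    "bootstrap_hypervolume",
    "overlap_sorensen",
    "dissimilarity",
    "mahalanobis_novelty",
]

SEASON_LABELS = ("q1", "q2", "q3", "q4")
FEATURE_COLUMNS = tuple(f"tmean_{s}" for s in SEASON_LABELS) + tuple(
    f"prec_{s}" for s in SEASON_LABELS)


def seasonal_features(slc: ClimateSlice, period: str | None = None) -> pd.DataFrame:
    """One row per cell x year with the eight seasonal climate summaries."""
    ny, ns, nr, nc = slc.seasonal_tmean.shape
    t = slc.seasonal_tmean.transpose(0, 2, 3, 1).reshape(-1, ns)
    p = slc.seasonal_prec.transpose(0, 2, 3, 1).reshape(-1, ns)
    df = pd.DataFrame(np.hstack([t, p]), columns=list(FEATURE_COLUMNS))
    df["period"] = period if period is not None else str(slc.time_bp)
    return df


def bias_correct(
    sim_series: list[ClimateSlice],
    sim_reference: ClimateSlice,
    obs_reference: ClimateSlice,
    ratio_cap: tuple[float, float] = (0.2, 5.0),
) -> list[ClimateSlice]:
    """Delta/ratio bias correction of simulated seasonal climate.

    Per cell and season, the reference-window difference (temperature) is
    added to, and the reference-window ratio (precipitation) multiplies, the
    whole simulated series — assuming the simulation bias is constant in
    time.  Where the simulated reference precipitation is below 1 mm the
    ratio is capped to ``ratio_cap`` and the cell is flagged.
    """
    sim_t = sim_reference.seasonal_tmean.mean(axis=0)   # (4, nr, nc)
    obs_t = obs_reference.seasonal_tmean.mean(axis=0)
    sim_p = sim_reference.seasonal_prec.mean(axis=0)
    obs_p = obs_reference.seasonal_prec.mean(axis=0)
    delta = obs_t - sim_t
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sim_p > 0, obs_p / np.where(sim_p > 0, sim_p, 1.0), 1.0)
    tiny = sim_p < 1.0
    if np.any(tiny):
        logger.warning("precipitation ratio capped in %d cell-seasons with "
                       "near-zero simulated reference", int(tiny.sum()))
        ratio = np.where(tiny, np.clip(ratio, *ratio_cap), ratio)

    out = []
    for slc in sim_series:
        out.append(ClimateSlice(
            time_bp=slc.time_bp,
            tmin_winter=slc.tmin_winter + delta[0],
            gdd=slc.gdd,
            precip_total=slc.precip_total * ratio.mean(axis=0),
            water_balance_summer=slc.water_balance_summer,
            seasonal_tmean=slc.seasonal_tmean + delta[None],
            seasonal_prec=slc.seasonal_prec * ratio[None],
        ))
    return out


@dataclass
class ReferenceProjection:
    """Standardisation constants and PCA loadings fixed on a reference table."""

    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance_ratio: np.ndarray

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float) \
            if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
        return ((X - self.mean) / self.std) @ self.components.T


def pca_reference(reference: pd.DataFrame | np.ndarray, k: int = 3) -> ReferenceProjection:
    """PCA projection with loadings and standardisation from the reference only.

    Every period projected with the returned object shares the same axes, so
    coordinates are comparable across periods.
    """
    from sklearn.decomposition import PCA

    X = reference[list(FEATURE_COLUMNS)].to_numpy(dtype=float) \
        if isinstance(reference, pd.DataFrame) else np.asarray(reference, dtype=float)
    if X.shape[0] < k + 1 or X.shape[1] < k:
        raise ValueError("reference table too small for the requested dimension")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    if np.any(std <= 0):
        raise ValueError("rank-deficient reference: a feature has zero variance")
    pca = PCA(n_components=k).fit((X - mean) / std)
    return ReferenceProjection(mean=mean, std=std, components=pca.components_,
                               explained_variance_ratio=pca.explained_variance_ratio_)


@dataclass
class Hypervolume:
    """A KDE-delimited region of climate space from one bootstrap resample.

    The region is where the Gaussian KDE density of the resample exceeds the
    level containing ``density_quantile`` of the resampled points; it is
    represented by a cloud of points sampled uniformly inside it plus the
    (kde, threshold) membership test, and its volume is estimated from the
    rejection-sampling acceptance rate.
    """

    kde: gaussian_kde
    threshold: float
    points: np.ndarray
    volume: float
    bandwidth_factor: float

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("hypervolume must have positive volume")

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.kde(np.asarray(pts, dtype=float).T) >= self.threshold


def _build_hypervolume(
    sample: np.ndarray,
    rng: np.random.Generator,
    density_quantile: float,
    cloud_size: int,
    max_tries: int = 200,
) -> Hypervolume:
    try:
        kde = gaussian_kde(sample.T, bw_method="silverman")
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate sample: KDE covariance is singular") from err
    # leave-self-out densities for the threshold: evaluating the KDE at its
    # own support points (with bootstrap duplicates counted as self too)
    # inflates the density quantile and would shrink the region
    n, d = sample.shape
    dens = kde(sample.T)
    k0 = (2.0 * np.pi) ** (-d / 2.0) / np.sqrt(np.linalg.det(kde.covariance))
    _, inv, mult = np.unique(sample, axis=0, return_inverse=True,
                             return_counts=True)
    m = mult[inv].astype(float)
    dens_loo = np.clip((n * dens - m * k0) / np.maximum(n - m, 1.0), 1e-300, None)
    thr = float(np.quantile(dens_loo, 1.0 - density_quantile))
    bw = float(kde.factor) * np.sqrt(np.diag(kde.covariance / kde.factor**2)).mean()
    pad = 3.0 * float(kde.factor) * sample.std(axis=0, ddof=0)
    lo = sample.min(axis=0) - pad
    hi = sample.max(axis=0) + pad
    box_vol = float(np.prod(hi - lo))

    accepted: list[np.ndarray] = []
    n_drawn = n_acc = 0
    batch = max(4 * cloud_size, 1000)
    for _ in range(max_tries):
        cand = rng.uniform(lo, hi, size=(batch, sample.shape[1]))
        inside = kde(cand.T) >= thr
        n_drawn += batch
        n_acc += int(inside.sum())
        accepted.append(cand[inside])
        if n_acc >= cloud_size:
            break
    if n_acc == 0:
        raise ValueError("rejection sampling accepted no interior points")
    pts = np.vstack(accepted)[:cloud_size]
    volume = box_vol * n_acc / n_drawn
    return Hypervolume(kde=kde, threshold=thr, points=pts, volume=volume,
                       bandwidth_factor=bw)


def bootstrap_hypervolume(
    points: np.ndarray,
    n_boot: int = 20,
    rng: np.random.Generator | None = None,
    density_quantile: float = 0.95,
    cloud_size: int = 5000,
) -> list[Hypervolume]:
    """Bootstrapped hypervolumes of a point sample in (projected) climate space.

    Each bootstrap draws a smooth resample (rows resampled with replacement
    plus kernel jitter, i.e. draws from the sample's own Gaussian KDE — the
    smooth bootstrap, which avoids duplicate atoms that would bias the
    density threshold), fits a Gaussian KDE with Silverman bandwidth and
    delimits the region containing ``density_quantile`` of the resampled
    points.  Warns below 50 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if len(np.unique(pts, axis=0)) <= pts.shape[1]:
        raise ValueError("fewer than dim+1 distinct points")
    if pts.shape[0] < 50:
        logger.warning("hypervolume from only %d points; estimates will be noisy",
                       pts.shape[0])
    rng = rng if rng is not None else np.random.default_rng(0)
    try:
        parent = gaussian_kde(pts.T, bw_method="silverman")
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate sample: KDE covariance is singular") from err
    # variance-corrected smooth bootstrap: shrink towards the mean so the
    # kernel jitter does not inflate the resample covariance
    shrink = 1.0 / np.sqrt(1.0 + parent.factor**2)
    centre = pts.mean(axis=0)
    out = []
    for _ in range(n_boot):
        raw = parent.resample(len(pts), seed=rng).T
        resample = centre + (raw - centre) * shrink
        out.append(_build_hypervolume(resample, rng, density_quantile, cloud_size))
    return out


def overlap_sorensen(a: Hypervolume, b: Hypervolume) -> float:
    """Sorensen overlap 2 V(A&B) / (V(A)+V(B)) via cross point-in-region tests.

    The intersection volume is estimated from the fraction of A's interior
    cloud inside B (scaled by V(A)) and symmetrically, then averaged.
    """
    if a.dim != b.dim:
        raise ValueError("hypervolumes live in different dimensions")
    frac_a_in_b = float(b.contains(a.points).mean())
    frac_b_in_a = float(a.contains(b.points).mean())
    v_int = 0.5 * (frac_a_in_b * a.volume + frac_b_in_a * b.volume)
    return float(np.clip(2.0 * v_int / (a.volume + b.volume), 0.0, 1.0))


@dataclass
class DissimilarityEstimate:
    """Mean and sd of 1 - Sorensen overlap over all bootstrap hypervolume pairs."""

    mean: float
    sd: float
    n_pairs: int

    def __post_init__(self):
        if not 0.0 <= self.mean <= 1.0 or self.sd < 0:
            raise ValueError("invalid dissimilarity estimate")


def dissimilarity(
    focal: pd.DataFrame | np.ndarray,
    reference: pd.DataFrame | np.ndarray,
    n_boot: int = 20,
    rng: np.random.Generator | None = None,
    k: int = 3,
    loadings: str = "pooled",
    density_quantile: float = 0.95,
    cloud_size: int = 5000,
    reference_hypervolumes: list[Hypervolume] | None = None,
    projection: ReferenceProjection | None = None,
) -> DissimilarityEstimate:
    """Climatic dissimilarity between a focal and the reference period.

    ``loadings='pooled'`` standardises and rotates on the pooled focal +
    reference sample for this comparison (the default); ``'reference'`` uses
    reference-only loadings, which lets precomputed ``reference_hypervolumes``
    (with their ``projection``) be shared across many focal periods.
    """
    rng = rng if rng is not None else np.random.default_rng(0)

    def raw(t):
        return t[list(FEATURE_COLUMNS)].to_numpy(dtype=float) \
            if isinstance(t, pd.DataFrame) else np.asarray(t, dtype=float)

    Xf, Xr = raw(focal), raw(reference)
    if reference_hypervolumes is not None:
        if projection is None:
            raise ValueError("precomputed reference hypervolumes need their projection")
        proj = projection
        hv_ref = reference_hypervolumes
    else:
        if loadings == "pooled":
            proj = pca_reference(np.vstack([Xr, Xf]), k=k)
        elif loadings == "reference":
            proj = pca_reference(Xr, k=k)
        else:
            raise ValueError("loadings must be 'pooled' or 'reference'")
        hv_ref = bootstrap_hypervolume(proj.transform(Xr), n_boot=n_boot, rng=rng,
                                       density_quantile=density_quantile,
                                       cloud_size=cloud_size)
    hv_foc = bootstrap_hypervolume(proj.transform(Xf), n_boot=n_boot, rng=rng,
                                   density_quantile=density_quantile,
                                   cloud_size=cloud_size)
    vals = np.array([1.0 - overlap_sorensen(f, r) for f in hv_foc for r in hv_ref])
    return DissimilarityEstimate(mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
                                 n_pairs=len(vals))


def mahalanobis_novelty(
    focal: np.ndarray,
    reference: np.ndarray,
    regularization: float = 1e-6,
) -> np.ndarray:
    """Per-cell climate novelty: minimum Mahalanobis distance to the reference pool.

    The metric uses the reference covariance; a singular covariance is ridge-
    regularised by ``regularization * I`` (scaled by the mean variance).
    """
    focal = np.atleast_2d(np.asarray(focal, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    cov = np.cov(reference, rowvar=False)
    cov = np.atleast_2d(cov)
    scale = max(float(np.trace(cov)) / cov.shape[0], 1.0)
    try:
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov = cov + regularization * scale * np.eye(cov.shape[0])
        try:
            vi = np.linalg.inv(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("reference covariance singular even after "
                             "regularisation") from err
    return cdist(focal, reference, metric="mahalanobis", VI=vi).min(axis=1)
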