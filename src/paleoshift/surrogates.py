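"""Habitat-suitability surrogates: expert process model, correlative SDM, inverse calibration.

Three model families produce comparable suitability maps from a climate slice:

* :func:`process_fitness` / :class:`ProcessSuitabilityModel` — the mechanistic
  response (product of logistic fitness components), the expert
  process-explicit surrogate when given measured parameters;
* :class:`CorrelativeSDM` — a regularised logistic regression on polynomial
  climate features, calibrated on presences plus background points, standing
  in for the correlative SDM family;
* :class:`InverseCalibratedModel` — the same mechanistic structure but with
  parameters estimated from occurrence data by a bounded derivative-free
  evolutionary search maximising AUC, the "fitted" process model.

Thresholding (TSS-maximising) and environmental block cross-validation
utilities live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .synthetic_world import COVARIATE_NAMES, ClimateSlice, VirtualSpecies

__all__ = [
    "SuitabilityMap",
    "ProcessSuitabilityModel",
    "CorrelativeSDM",
    "InverseCalibratedModel",
    "process_fitness",
    "slice_features",
    "sample_background",
    "fit_correlative",
    "inverse_calibrate",
    "max_tss_threshold",
    "env_block_cv",
]


@dataclass
class SuitabilityMap:
    """Continuous per-coarse-cell model output with an optional presence threshold."""

    values: np.ndarray
    species: str = ""
    time_bp: int | None = None
    threshold: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("suitability values must be finite")
        if self.threshold is not None:
            lo, hi = float(self.values.min()), float(self.values.max())
            if not lo <= self.threshold <= hi:
                raise ValueError("threshold must lie within the value range")


def slice_features(slc: ClimateSlice, cells: np.ndarray | None = None) -> np.ndarray:
    """Stack the four slice covariates into an (n, 4) feature matrix.

    ``cells`` is an (n, 2) array of (row, col) indices; with ``None`` every
    cell is returned in row-major order.
    """
    cov = [slc.covariates()[name] for name in COVARIATE_NAMES]
    if cells is None:
        return np.column_stack([c.ravel() for c in cov])
    cells = np.asarray(cells)
    return np.column_stack([c[cells[:, 0], cells[:, 1]] for c in cov])


# ---------------------------------------------------------------------------
# process surrogate
# ---------------------------------------------------------------------------

def _fitness_from_features(X: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Product of the three logistic fitness components on covariate columns
    (tmin_winter, gdd, _, water_balance_summer)."""
    t50, ts, w50, ws, g50, gs = params
    frost = expit((X[:, 0] - t50) / ts)
    repro = expit((X[:, 1] - g50) / gs)
    drought = expit((X[:, 3] - w50) / ws)
    return frost * drought * repro


def process_fitness(slc: ClimateSlice, species: VirtualSpecies) -> SuitabilityMap:
    """Mechanistic fitness surface: frost survival x drought survival x
    reproductive success, each a logistic in its covariate.  Values in [0, 1],
    monotone non-decreasing in every covariate."""
    X = slice_features(slc)
    fit = _fitness_from_features(X, species.as_array())
    return SuitabilityMap(values=fit.reshape(slc.shape), species=species.name,
                          time_bp=slc.time_bp)


class ProcessSuitabilityModel(BaseEstimator):
    """Expert process surrogate: fixed mechanistic parameters, no fitting.

    ``predict_suitability`` evaluates the fitness surface of ``species`` on a
    slice; ``decision_function`` scores raw feature rows (used by the shared
    thresholding and CV machinery).
    """

    def __init__(self, species: VirtualSpecies | None = None):
        self.species = species

    def _params(self) -> np.ndarray:
        if self.species is None:
            raise ValueError("species parameters not set")
        return self.species.as_array()

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return _fitness_from_features(np.asarray(X, dtype=float), self._params())

    def predict_suitability(self, slc: ClimateSlice) -> SuitabilityMap:
        return process_fitness(slc, self.species)


# ---------------------------------------------------------------------------
# correlative surrogate
# ---------------------------------------------------------------------------

class CorrelativeSDM(BaseEstimator, ClassifierMixin):
    """Regularised logistic regression on polynomial climate features.

    One flexible correlative family stands in for the usual basket of
    correlative SDM algorithms: features are standardised, expanded to
    ``degree`` polynomials and fed to an L2-penalised logistic regression.
    Presence probability is ``predict_proba(X)[:, 1]``.
    """

    def __init__(self, degree: int = 2, C: float = 1.0, max_iter: int = 2000):
        self.degree = degree
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=self.degree, include_bias=False)),
            ("logit", LogisticRegression(C=self.C, max_iter=self.max_iter)),
        ])
        self.pipeline_.fit(X, y)
        self.training_auc_ = float(roc_auc_score(y, self.decision_function(X)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict_suitability(self, slc: ClimateSlice) -> SuitabilityMap:
        p = self.decision_function(slice_features(slc))
        return SuitabilityMap(values=p.reshape(slc.shape), species="correlative",
                              time_bp=slc.time_bp)


def sample_background(
    shape: tuple[int, int],
    n: int,
    rng: np.random.Generator,
    replace: bool = True,
    max_n: int = 1_000_000,
) -> np.ndarray:
    """Uniform random background cells on a coarse grid.

    Returns an (n, 2) array of (row, col) indices.  Without replacement and
    ``n`` equal to the number of cells, every cell is returned exactly once.
    """
    if n < 1:
        raise ValueError("background sample size must be >= 1")
    if n > max_n:
        raise ValueError(f"background sample size exceeds the cap ({max_n})")
    nr, nc = shape
    total = nr * nc
    if replace:
        flat = rng.integers(0, total, size=n)
    else:
        if n > total:
            raise ValueError("cannot sample more cells than exist without replacement")
        flat = rng.choice(total, size=n, replace=False)
    return np.column_stack(np.unravel_index(flat, (nr, nc)))


def fit_correlative(
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    training_slices: ClimateSlice | list[ClimateSlice],
    degree: int = 2,
    C: float = 1.0,
) -> CorrelativeSDM:
    """Calibrate the correlative surrogate on reference-period climate.

    ``presence_cells``/``background_cells`` are (n, 2) cell indices; features
    are extracted from the training slice(s) only, mirroring calibration
    restricted to the modern reference period.
    """
    if isinstance(training_slices, ClimateSlice):
        training_slices = [training_slices]
    presence_cells = np.asarray(presence_cells)
    if len(presence_cells) < 20:
        raise ValueError("need at least 20 presences to calibrate")
    X_list, y_list = [], []
    for slc in training_slices:
        X_list.append(slice_features(slc, presence_cells))
        y_list.append(np.ones(len(presence_cells)))
        X_list.append(slice_features(slc, background_cells))
        y_list.append(np.zeros(len(background_cells)))
    model = CorrelativeSDM(degree=degree, C=C)
    model.fit(np.vstack(X_list), np.concatenate(y_list))
    return model


# ---------------------------------------------------------------------------
# inverse calibration
# ---------------------------------------------------------------------------

#: search bounds for (frost_t50, frost_slope, drought_w50, drought_slope,
#: gdd_req, gdd_slope)
DEFAULT_BOUNDS = (
    (-25.0, 5.0), (0.2, 8.0),
    (-150.0, 50.0), (2.0, 80.0),
    (300.0, 3500.0), (20.0, 600.0),
)


def _fast_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), tie-aware; avoids per-call validation cost."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return (r[y > 0].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


class InverseCalibratedModel(BaseEstimator):
    """Process model calibrated on occurrence data, the "fitted" surrogate.

    The mechanistic parameter vector is estimated by a bounded,
    derivative-free, population-based evolutionary search (differential
    evolution) maximising the AUC of the fitness surface against
    presence/background labels; across ``n_restarts`` independent runs the
    best-AUC parameter set is retained.  Budgets smaller than one population
    degrade gracefully to best-of-random-sample.

    Fitted attributes: ``species_`` (the calibrated :class:`VirtualSpecies`),
    ``auc_`` (its training AUC), ``n_evaluations_``.
    """

    def __init__(self, bounds=DEFAULT_BOUNDS, budget: int = 2000,
                 n_restarts: int = 2, random_state: int | None = None,
                 name: str = "fitted"):
        self.bounds = bounds
        self.budget = budget
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.name = name

    def fit(self, X, y):
        from scipy.optimize import differential_evolution

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        bounds = np.asarray(self.bounds, dtype=float)
        ndim = len(bounds)
        rng = np.random.default_rng(self.random_state)

        y01 = (y > 0).astype(float)

        def neg_auc(params):
            return -_fast_auc(y01, _fitness_from_features(X, params))

        popsize = 12
        pop_evals = popsize * ndim
        best = (np.inf, None)
        n_evals = 0
        for _ in range(max(1, self.n_restarts)):
            seed = int(rng.integers(0, 2**31 - 1))
            if self.budget <= pop_evals:
                # degenerate budget: best of a random initial population
                local = np.random.default_rng(seed)
                cand = local.uniform(bounds[:, 0], bounds[:, 1],
                                     size=(max(1, self.budget), ndim))
                vals = np.array([neg_auc(c) for c in cand])
                i = int(np.argmin(vals))
                run = (vals[i], cand[i])
                n_evals += len(cand)
            else:
                maxiter = max(1, (self.budget - pop_evals) // pop_evals)
                res = differential_evolution(
                    neg_auc, bounds, maxiter=maxiter, popsize=popsize,
                    seed=seed, tol=1e-8, polish=False, init="sobol",
                )
                run = (res.fun, res.x)
                n_evals += res.nfev
            if run[0] < best[0]:
                best = run
        self.species_ = VirtualSpecies.from_array(best[1], name=self.name)
        self.auc_ = float(-best[0])
        self.n_evaluations_ = n_evals
        return self

    def decision_function(self, X):
        return _fitness_from_features(np.asarray(X, dtype=float),
                                      self.species_.as_array())

    def predict_suitability(self, slc: ClimateSlice) -> SuitabilityMap:
        return process_fitness(slc, self.species_)


def inverse_calibrate(
    template: VirtualSpecies,
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    slc: ClimateSlice,
    budget: int = 2000,
    rng: np.random.Generator | int | None = None,
    bounds=DEFAULT_BOUNDS,
    n_restarts: int = 2,
) -> tuple[VirtualSpecies, float]:
    """Estimate process parameters from occurrences; returns (species, AUC).

    ``template`` supplies the name of the calibrated parameter set; the search
    itself starts from the bounded prior volume, not from the template values.
    """
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else \
        int(rng.integers(0, 2**31 - 1))
    X = np.vstack([slice_features(slc, np.asarray(presence_cells)),
                   slice_features(slc, np.asarray(background_cells))])
    y = np.concatenate([np.ones(len(presence_cells)), np.zeros(len(background_cells))])
    model = InverseCalibratedModel(bounds=bounds, budget=budget,
                                   n_restarts=n_restarts, random_state=seed,
                                   name=f"{template.name}_fitted")
    model.fit(X, y)
    return model.species_, model.auc_


# ---------------------------------------------------------------------------
# thresholding & cross-validation
# ---------------------------------------------------------------------------

def max_tss_threshold(scores, labels) -> float:
    """Score threshold maximising TSS = sensitivity + specificity - 1.

    A cell is predicted present when its score is >= the threshold; candidate
    thresholds are the observed score values and ties are broken towards the
    smallest maximising threshold (the more permissive choice).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to select a threshold")
    order = np.argsort(scores)
    s, l = scores[order], labels[order]
    n_pos = l.sum()
    n_neg = len(l) - n_pos
    # predicted present iff score >= tau; for tau = s[i], positives captured are
    # labels[i:], negatives misclassified are (~labels)[i:]
    pos_ge = n_pos - np.cumsum(np.concatenate([[0], l[:-1]]))
    neg_ge = n_neg - np.cumsum(np.concatenate([[0], ~l[:-1]]))
    tss = pos_ge / n_pos + (n_neg - neg_ge) / n_neg - 1.0
    # collapse duplicate score values: keep the first index of each value
    first = np.concatenate([[True], s[1:] != s[:-1]])
    s, tss = s[first], tss[first]
    best = tss.max()
    return float(s[np.nonzero(tss >= best - 1e-12)[0][0]])


def env_block_cv(
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    slc: ClimateSlice,
    k: int = 5,
    degree: int = 2,
    C: float = 1.0,
    random_state: int = 0,
) -> np.ndarray:
    """Fivefold environmental block cross-validation of the correlative surrogate.

    Folds are contiguous blocks in climate space: cells are clustered into
    ``k`` groups by k-means on PCA-rotated standardised covariates, each block
    is held out once, and the held-out AUC is reported.  A fold whose test set
    contains a single class is reported as NaN (missing), never dropped.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    presence_cells = np.asarray(presence_cells)
    background_cells = np.asarray(background_cells)
    X = np.vstack([slice_features(slc, presence_cells),
                   slice_features(slc, background_cells)])
    y = np.concatenate([np.ones(len(presence_cells)),
                        np.zeros(len(background_cells))])
    Z = PCA(n_components=min(4, X.shape[1])).fit_transform(StandardScaler().fit_transform(X))
    blocks = KMeans(n_clusters=k, n_init=4, random_state=random_state).fit_predict(Z)

    aucs = np.full(k, np.nan)
    for fold in range(k):
        test = blocks == fold
        train = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            continue  # reported as missing
        model = CorrelativeSDM(degree=degree, C=C).fit(X[train], y[train])
        aucs[fold] = roc_auc_score(y[test], model.decision_function(X[test]))
    return aucs
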