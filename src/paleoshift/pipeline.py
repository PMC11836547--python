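"""End-to-end hindcast experiment: generate -> model -> disperse -> pollen -> evaluate.

One :class:`ExperimentConfig` drives the whole virtual study:

1. generate the synthetic climate trajectory and, per species, the true
   dispersal-limited occupancy;
2. calibrate the three surrogate families on the reference (most recent)
   slice: correlative SDM on presences + background, expert process model
   with the true mechanism parameters, inverse-calibrated process model
   fitted to the same occurrence data;
3. threshold each model's reference output at its TSS-maximising value,
   rescale to colonisation probabilities, and run the migration automaton
   over the whole series;
4. build a virtual pollen archive from the truth, filter/bin/threshold it to
   gridded presence per 500-year bin;
5. score every model x species x bin on data cells (Sorensen, TSS), attach
   the bin's climatic dissimilarity (bootstrapped hypervolume overlap with
   the reference period), and
6. compare model families: Kruskal-Wallis + Conover-Iman on Sorensen scores
   and an ordered beta regression of performance on dissimilarity with the
   dissimilarity sd as predictor measurement error.

Every stochastic stage consumes a named child seed spawned from the master
seed, so a rerun with the same config is reproducible end to end; the
returned manifest records the config digest, stage seeds and content hashes
of every intermediate product.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_space as cs
from . import dispersal as dsp
from . import evaluation as ev
from . import pollen as pol
from . import surrogates as sur
from .ordered_beta import OrderedBetaRegression
from .synthetic_world import (
    perturb_species,
    ClimateTrajectory,
    LandscapeConfig,
    PollenCountModel,
    PollenDetection,
    PollenSitePlan,
    VirtualSpecies,
    gen_climate_series,
    gen_pollen_archive,
    gen_true_occupancy,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "demo_config"]

MODEL_TYPES = ("correlative", "fitted-process", "expert-process")

_STAGES = ("climate", "truth", "pollen", "calibration", "migration",
           "dissimilarity", "regression")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one virtual hindcast experiment."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    trajectory: ClimateTrajectory = field(default_factory=ClimateTrajectory)
    species: tuple[VirtualSpecies, ...] = ()
    kernel_form: str = "exponential-power"
    kernel_params: dict = field(default_factory=lambda: {"a": 600.0, "c": 1.0})
    kernel_ld_probability: float = 0.01
    cell_size_m: float = 500.0
    years_per_slice: int = 250
    truth_tau: float = 0.25
    site_plan: PollenSitePlan = field(default_factory=PollenSitePlan)
    count_model: PollenCountModel = field(default_factory=PollenCountModel)
    detection: PollenDetection = field(default_factory=PollenDetection)
    bin_width: int = 500
    background_multiplier: int = 10
    inverse_budget: int = 1500
    inverse_restarts: int = 2
    expert_param_error: float = 0.1
    n_boot: int = 6
    cloud_size: int = 400
    hv_max_rows: int = 600
    regression_method: str = "ml"
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise ValueError("experiment needs at least one species")
        if self.bin_width <= 0 or self.years_per_slice <= 0:
            raise ValueError("bin width and years per slice must be positive")
        if self.regression_method not in ("ml", "bayes"):
            raise ValueError("regression_method must be 'ml' or 'bayes'")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(c.generate_state(1)[0] % (2**31 - 1))
                for name, c in zip(_STAGES, children)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscape"]["elevation"] = None if self.landscape.elevation is None \
            else np.asarray(self.landscape.elevation).tolist()
        d["species"] = [asdict(s) for s in self.species]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        land = dict(d.pop("landscape"))
        if land.get("elevation") is not None:
            land["elevation"] = np.asarray(land["elevation"], dtype=float)
        d["landscape"] = LandscapeConfig(**land)
        d["trajectory"] = ClimateTrajectory(**d.pop("trajectory"))
        d["species"] = tuple(VirtualSpecies(**s) for s in d.pop("species"))
        d["site_plan"] = PollenSitePlan(**d.pop("site_plan"))
        d["count_model"] = PollenCountModel(**d.pop("count_model"))
        d["detection"] = PollenDetection(**d.pop("detection"))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def demo_config(seed: int = 42) -> ExperimentConfig:
    """The shipped demo scenario: 40x40 coarse grid, 2 species, 12 slices.

    The trajectory runs from the cold start at 12 kyr BP through the abrupt
    warming (changepoint 10.75 kyr BP) into the stable period down to
    9.25 kyr BP; the most recent slice doubles as the modern calibration
    reference.
    """
    from .synthetic_world import DEFAULT_SPECIES

    return ExperimentConfig(
        landscape=LandscapeConfig(n_rows=40, n_cols=40, fine_per_coarse=2, seed=seed),
        trajectory=ClimateTrajectory(start_bp=12_000, end_bp=9_250),
        species=DEFAULT_SPECIES,
        # noisier pollen rain than the class defaults: expected focal-taxon
        # abundance sits close to the presence thresholds, so observed
        # presence carries realistic detection error
        detection=PollenDetection(p_occupied=0.04, p_unoccupied=0.004),
        seed=seed,
    )


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    dissimilarity: pd.DataFrame
    regression: OrderedBetaRegression | None
    kruskal: tuple[float, float] | None
    conover: pd.DataFrame | None
    manifest: dict
    models: dict
    truth_coarse: dict
    presence_grids: dict
    archive: pd.DataFrame


def _hash_arrays(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.shape).encode())
        h.update(str(a.dtype).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def _suitability_series(model, climate):
    return [model.predict_suitability(s).values for s in climate]


def _migrate(prob_coarse, kernel, config, rng, times):
    """Broadcast coarse probabilities to the fine grid and run the automaton.

    A model that predicts no suitable habitat within the allowed start window
    yields an all-empty occupancy series instead of failing the experiment.
    """
    f = config.landscape.fine_per_coarse
    fine = [np.kron(p, np.ones((f, f))) for p in prob_coarse]
    try:
        series = dsp.run_migration(fine, kernel, years_per_slice=config.years_per_slice,
                                   rng=rng, times_bp=times, check_bound=False)
    except dsp.NoSuitableHabitatError:
        logger.warning("model predicts no colonisable habitat in the start window; "
                       "occupancy left empty")
        shape = fine[0].shape
        series = [dsp.OccupancyGrid(occupied=np.zeros(shape, bool), time_bp=t)
                  for t in times]
    return [dsp.coarsen_occupancy(s, f) for s in series]


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None
                   ) -> ExperimentResult:
    seeds = config.stage_seeds()
    manifest: dict = {"config_digest": config.digest(), "seeds": seeds, "stages": {}}

    # -- stage 1: climate ---------------------------------------------------
    land = LandscapeConfig(**{**asdict(config.landscape),
                              "elevation": config.landscape.elevation,
                              "seed": seeds["climate"]})
    climate = gen_climate_series(land, config.trajectory)
    times = [s.time_bp for s in climate]
    ref = climate[-1]
    manifest["stages"]["climate"] = _hash_arrays(
        *[s.tmin_winter for s in climate], *[s.seasonal_prec for s in climate])

    kernel = dsp.discretize_kernel(config.kernel_form, config.kernel_params,
                                   cell_size_m=config.cell_size_m,
                                   ld_probability=config.kernel_ld_probability)

    # -- stage 2: truth -----------------------------------------------------
    rng_truth = np.random.default_rng(seeds["truth"])
    truth_coarse: dict[str, list[np.ndarray]] = {}
    for sp in config.species:
        occ = gen_true_occupancy(sp, climate, kernel, rng_truth, tau=config.truth_tau,
                                 fine_per_coarse=land.fine_per_coarse,
                                 years_per_slice=config.years_per_slice)
        truth_coarse[sp.name] = [dsp.coarsen_occupancy(o, land.fine_per_coarse)
                                 for o in occ]
    manifest["stages"]["truth"] = _hash_arrays(
        *[g for s in truth_coarse.values() for g in s])

    # -- stage 3: virtual pollen -> presence grids --------------------------
    rng_pollen = np.random.default_rng(seeds["pollen"])
    archive = gen_pollen_archive(truth_coarse, times, land,
                                 site_plan=config.site_plan,
                                 count_model=config.count_model,
                                 detection=config.detection, rng=rng_pollen)
    retained = pol.filter_samples(archive)
    binned = pol.bin_and_average(retained, bin_width=config.bin_width)
    binned["present"] = [
        bool(pol.abundance_to_presence(r.relative_abundance, r.taxon))
        for r in binned.itertuples()
    ]
    bins = sorted(b for b in binned["bin_bp"].unique()
                  if min(times) <= b <= max(times))
    presence_grids: dict[tuple[str, int], pol.PresenceGrid] = {}
    for sp in config.species:
        for b in bins:
            sub = binned[(binned["taxon"] == sp.name) & (binned["bin_bp"] == b)]
            presence_grids[(sp.name, b)] = pol.grid_presence(
                sub, land.shape, taxon=sp.name, bin_bp=b)
    manifest["stages"]["pollen"] = hashlib.sha256(
        archive.to_csv(index=False).encode()).hexdigest()

    # -- stage 4: calibrate the three surrogate families --------------------
    rng_cal = np.random.default_rng(seeds["calibration"])
    models: dict[tuple[str, str], object] = {}
    thresholds: dict[tuple[str, str], tuple[float, float]] = {}
    for sp in config.species:
        truth_ref = truth_coarse[sp.name][-1]
        pres = np.column_stack(np.nonzero(truth_ref))
        if len(pres) < 20:
            raise RuntimeError(f"species {sp.name} has too few reference presences "
                               f"({len(pres)}) to calibrate")
        n_bg = min(config.background_multiplier * len(pres), 5 * truth_ref.size)
        bg = sur.sample_background(land.shape, n_bg, rng_cal)
        corr = sur.fit_correlative(pres, bg, ref)
        # expert parameters carry independent measurement error: an expert
        # process model knows the mechanism, not the exact parameter values
        expert_sp = perturb_species(sp, config.expert_param_error, rng_cal)
        expert = sur.ProcessSuitabilityModel(species=expert_sp)
        fitted = sur.InverseCalibratedModel(
            budget=config.inverse_budget, n_restarts=config.inverse_restarts,
            random_state=int(rng_cal.integers(0, 2**31 - 1)), name=f"{sp.name}_fitted")
        X_cal = np.vstack([sur.slice_features(ref, pres), sur.slice_features(ref, bg)])
        y_cal = np.concatenate([np.ones(len(pres)), np.zeros(len(bg))])
        fitted.fit(X_cal, y_cal)
        for mtype, model in (("correlative", corr), ("fitted-process", fitted),
                             ("expert-process", expert)):
            models[(mtype, sp.name)] = model
            scores = model.predict_suitability(ref).values.ravel()
            tau = sur.max_tss_threshold(scores, truth_ref.ravel())
            thresholds[(mtype, sp.name)] = (tau, float(scores.max()))
    manifest["stages"]["calibration"] = hashlib.sha256(json.dumps(
        {f"{k[0]}/{k[1]}": v for k, v in sorted(thresholds.items())},
        sort_keys=True).encode()).hexdigest()

    # -- stage 5: migration per model x species -----------------------------
    rng_mig = np.random.default_rng(seeds["migration"])
    predicted: dict[tuple[str, str], list[np.ndarray]] = {}
    for (mtype, spname), model in sorted(models.items()):
        tau, v_max = thresholds[(mtype, spname)]
        suit = _suitability_series(model, climate)
        if v_max <= tau:
            prob = [np.zeros(land.shape) for _ in suit]
        else:
            prob = [dsp.threshold_rescale(s, tau, v_max) for s in suit]
        predicted[(mtype, spname)] = _migrate(prob, kernel, config, rng_mig, times)
    manifest["stages"]["migration"] = _hash_arrays(
        *[g for k in sorted(predicted) for g in predicted[k]])

    # -- stage 6: climatic dissimilarity per bin ----------------------------
    rng_dis = np.random.default_rng(seeds["dissimilarity"])

    def features_sub(slc_list, rng):
        tables = [cs.seasonal_features(s) for s in slc_list]
        X = pd.concat(tables, ignore_index=True)[list(cs.FEATURE_COLUMNS)].to_numpy()
        if len(X) > config.hv_max_rows:
            X = X[rng.choice(len(X), config.hv_max_rows, replace=False)]
        return X

    X_ref = features_sub([ref], rng_dis)
    proj = cs.pca_reference(X_ref, k=3)
    hv_ref = cs.bootstrap_hypervolume(proj.transform(X_ref), n_boot=config.n_boot,
                                      rng=rng_dis, cloud_size=config.cloud_size)
    dis_rows = []
    dis_by_bin: dict[int, cs.DissimilarityEstimate] = {}
    for b in bins:
        in_bin = [s for s in climate
                  if b - config.bin_width / 2 <= s.time_bp < b + config.bin_width / 2]
        if not in_bin:
            continue
        Xf = features_sub(in_bin, rng_dis)
        est = cs.dissimilarity(Xf, X_ref, n_boot=config.n_boot, rng=rng_dis,
                               cloud_size=config.cloud_size,
                               reference_hypervolumes=hv_ref, projection=proj)
        novelty = float(np.mean(cs.mahalanobis_novelty(Xf, X_ref)))
        dis_by_bin[b] = est
        dis_rows.append({"bin_bp": b, "dissimilarity_mean": est.mean,
                         "dissimilarity_sd": est.sd, "n_pairs": est.n_pairs,
                         "mahalanobis_novelty": novelty})
    dis_df = pd.DataFrame(dis_rows)
    manifest["stages"]["dissimilarity"] = hashlib.sha256(
        dis_df.to_csv(index=False).encode()).hexdigest()

    # -- stage 7: scoring + comparative statistics --------------------------
    records = []
    for (mtype, spname), series in sorted(predicted.items()):
        ref_cm = ev.ConfusionMatrix(
            tp=int(np.sum(series[-1] & truth_coarse[spname][-1])),
            fp=int(np.sum(series[-1] & ~truth_coarse[spname][-1])),
            fn=int(np.sum(~series[-1] & truth_coarse[spname][-1])),
            tn=int(np.sum(~series[-1] & ~truth_coarse[spname][-1])))
        try:
            ref_perf = ev.sorensen_index(ref_cm)
        except ev.EmptyEvaluationError:
            ref_perf = np.nan
        for b in bins:
            if b not in dis_by_bin:
                continue
            grid = presence_grids[(spname, b)]
            k = int(np.argmin(np.abs(np.asarray(times) - b)))
            try:
                cm = ev.confusion(series[k], grid)
                s_idx = ev.sorensen_index(cm)
            except ev.EmptyEvaluationError:
                continue
            try:
                t_val = ev.tss(cm)
            except ev.EmptyEvaluationError:
                t_val = np.nan
            est = dis_by_bin[b]
            records.append({
                "model_type": mtype, "species": spname, "bin_bp": b,
                "sorensen": s_idx, "tss": t_val,
                "dissimilarity_mean": est.mean, "dissimilarity_sd": est.sd,
                "n_data_cells": cm.n,
                "reference_sorensen": ref_perf,
                "transferability": (s_idx - ref_perf) / ref_perf
                if ref_perf and np.isfinite(ref_perf) else np.nan,
            })
    records = pd.DataFrame(records)

    kruskal = conover = regression = None
    if not records.empty:
        groups = [records.loc[records.model_type == m, "sorensen"].to_numpy()
                  for m in MODEL_TYPES]
        if all(len(g) >= 2 for g in groups):
            kruskal = ev.kruskal_wallis(groups)
            conover = ev.conover_iman(groups, labels=list(MODEL_TYPES))
        regression = OrderedBetaRegression(
            method=config.regression_method, random_state=seeds["regression"])
        regression.fit(records["dissimilarity_mean"].to_numpy(),
                       records["sorensen"].to_numpy(),
                       groups=records["model_type"].to_numpy(),
                       x_sd=records["dissimilarity_sd"].to_numpy())
        manifest["stages"]["regression"] = _hash_arrays(regression.slopes_,
                                                        regression.intercepts_)
    manifest["stages"]["records"] = hashlib.sha256(
        records.to_csv(index=False).encode()).hexdigest()

    result = ExperimentResult(
        records=records, dissimilarity=dis_df, regression=regression,
        kruskal=kruskal, conover=conover, manifest=manifest, models=models,
        truth_coarse=truth_coarse, presence_grids=presence_grids, archive=archive)

    if outdir is not None:
        _write_outputs(result, config, Path(outdir))
    return result


def _write_outputs(result: ExperimentResult, config: ExperimentConfig, outdir: Path):
    from . import io as pio

    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "performance.csv", index=False)
    result.dissimilarity.to_csv(outdir / "dissimilarity.csv", index=False)
    pio.write_pollen_csv(result.archive, outdir / "pollen_archive.csv")
    pio.write_yaml(config.to_dict(), outdir / "config.yaml")
    if result.conover is not None:
        result.conover.to_csv(outdir / "conover_iman.csv", index=False)
    if result.regression is not None:
        result.regression.summary().to_csv(outdir / "regression.csv", index=False)
        fit = {
            "groups": [str(g) for g in result.regression.groups_],
            "slopes": result.regression.slopes_.tolist(),
            "slope_ci": result.regression.slope_ci_.tolist(),
            "intercepts": result.regression.intercepts_.tolist(),
            "cutpoints": result.regression.cutpoints_.tolist(),
            "phi": result.regression.phi_,
        }
        (outdir / "regression.json").write_text(json.dumps(fit, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                     sort_keys=True))
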