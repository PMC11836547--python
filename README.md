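# paleoshift

Hindcasting species range shifts against (virtual) fossil-pollen records, to
ask how model predictive skill degrades as climate becomes dissimilar from
the calibration period — and whether models that describe explicit
ecophysiological mechanisms hold up better than correlative ones.

`paleoshift` is a virtual-study pipeline for ecological modellers. It builds
a synthetic world with known ground truth — a gridded Holocene-like climate
trajectory (abrupt early warming, then stability, delivered as 30-year
windows every 250 model-years), virtual tree species with mechanistic
climate responses, and site-based pollen archives with grain counts and
chronological uncertainty — and then runs the full hindcast-evaluation
workflow on it:

1. **Three suitability model families**, calibrated on the modern reference
   period only:
   - a *correlative* SDM (regularised logistic regression on polynomial
     climate features, presences + uniform background points);
   - an *expert process* model (the true mechanistic fitness structure —
     frost survival × drought survival × reproductive success, each a
     logistic response — with parameters measured with error);
   - a *fitted process* model (same mechanism, parameters inverse-calibrated
     from occurrence data by a bounded evolutionary search retaining the
     best-AUC run).
2. **Migration**: a modified cellular automaton at fine resolution. Model
   output is thresholded at the TSS-maximising value and rescaled to a
   colonisation probability; colonisation per year combines fat-tailed
   short-distance kernel arrival with establishment, plus rare long-distance
   events (probability 0.01 per occupied cell per year); cells becoming
   unsuitable are vacated.
3. **Virtual pollen processing**: samples with ≤ 200 grains, age
   uncertainty ≥ 500 yr, or marine deposition are discarded; abundances are
   aggregated to 500-year bins with weights 1/(σ+1) × a triangular taper;
   relative-abundance thresholds (e.g. 2.5% for oaks) give site presence,
   and a grid cell is present if any of its sites is. Cells with no retained
   site are excluded from evaluation.
4. **Skill and climatic dissimilarity**: predictions are scored on data
   cells with the Sørensen index, S = 2·TP / (2·TP + FP + FN) (immune to
   true-negative inflation), and TSS. Each 500-yr bin's climatic
   dissimilarity from the reference period is 1 − Sørensen overlap between
   bootstrapped climatic hypervolumes (Gaussian-KDE regions on the first
   three principal components of 3-month temperature means and precipitation
   sums), with a mean and sd over all bootstrap pairs; Mahalanobis novelty
   is computed alongside.
5. **Comparative statistics**: Kruskal–Wallis and pairwise Conover–Iman
   tests across model families, and an ordered beta regression of Sørensen
   skill on dissimilarity — a bounded-response model with point masses at 0
   and 1 via ordered cutpoints — with the dissimilarity sd entering as
   predictor measurement error (integrated out by Gauss–Hermite quadrature;
   maximum-likelihood or ensemble-MCMC posterior fits).

## Worked example

```bash
paleoshift demo --seed 1 --out results/demo
```

runs the shipped scenario (40×40 coarse grid, two virtual species, twelve
climate slices from 12 000 to 9 250 model-years BP) and prints:

```
performance records: 36
Kruskal-Wallis across model types: H=2.270, p=0.321
decline slope [correlative]: -3.16  (95% CI -4.32, -2.00)
decline slope [expert-process]: -1.28  (95% CI -2.65, 0.10)
decline slope [fitted-process]: -1.86  (95% CI -3.12, -0.61)
manifest config digest: b0131ed38255
```

The 36 records are one Sørensen score per model family × species × 500-yr
bin. The decline slopes are the ordered-beta coefficients of skill against
climatic dissimilarity (logit scale): here the correlative model loses skill
with climatic novelty about 2.5× faster than the expert process model —
in the most dissimilar bin (dissimilarity ≈ 1.0, the cold start of the
series) the correlative surrogate scores ≈ 0.52 against the pollen grid
while the expert process model scores ≈ 0.91, because the frost response
that governs the cold-phase range is not observable in the calibration
period and therefore cannot be learned correlatively. `--out` writes the
performance table, dissimilarity series, regression summaries, pollen
archive and a manifest of stage seeds and content hashes; rerunning with the
same seed reproduces the manifest exactly.

The library API mirrors the pipeline stages (`gen_climate_series`,
`process_fitness`, `fit_correlative`, `inverse_calibrate`,
`max_tss_threshold`, `run_migration`, `filter_samples`, `bin_and_average`,
`dissimilarity`, `sorensen_index`, `OrderedBetaRegression`, ...); the model
families and the regression are scikit-learn-style estimators and compose
with sklearn tooling.

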