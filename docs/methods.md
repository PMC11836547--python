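# Methods

This note documents the models and procedures implemented in `paleoshift`,
the defaults they ship with, and what the synthetic study system does and
does not emulate.

## The virtual world

**Climate.** The grid is rectangular (default 40×40 coarse cells, each
subdivided 2×2 for dispersal). A climate slice holds the four suitability
covariates (winter minimum temperature, growing degree-days > 5 °C, total
precipitation, summer water balance) as 30-year window means, plus per-year
3-month temperature means and precipitation sums used by the hypervolume
analysis. The trajectory is a changepoint trend: a temperature anomaly
−A·σ((t − t_c)/w) with amplitude A = 8.5 °C, changepoint t_c = 10 750
model-years BP and transition width w = 350 yr, added to a stable spatial
field. Slices arrive every 250 model-years; the default timeline is
12 000 → 500 BP (the demo uses 12 000 → 9 250, i.e. twelve slices, so two
500-yr evaluation bins fall in the deep cold phase, two in the transition
and two in the stable period). Interannual noise is Gaussian (sd 0.5 °C on
annual temperatures, scaled analogues on the other covariates).

The spatial structure is deliberate: growing-season heat (GDD) declines
with latitude, while winter minima decline mostly west-to-east (a
continental gradient, 6 °C across the grid, versus 3 °C south-to-north) and
respond strongly to the cold-phase anomaly where GDD responds weakly
(40 degree-days per °C). In the reference period the two are therefore
nearly uninformative about each other, and the species' frost limits lie at
or beyond the observed range of winter minima. In the cold phase the two
fields decouple: frost becomes the dominant range control in a way that was
not observable — and hence not learnable — at calibration time. This is the
niche-truncation mechanism that makes hindcasting discriminate between
correlative and process-explicit models; without it all model families
transfer equally and the comparison is vacuous.

**Species.** A virtual species is three logistic fitness components
multiplied together: frost survival in winter minimum temperature, drought
survival in summer water balance, reproductive success in GDD. The two
default species are an "oak-like" tree (frost midpoint −9 °C, GDD
requirement 2200) and a more frost- and drought-sensitive "beech-like" tree
(frost midpoint −6 °C, GDD 1900). Both retain southwestern refugia through
the cold phase and expand north- and eastward through the warming; the
beech-like species' refugium is small, which is what makes its recolonisation
dispersal-limited. True occupancy is the mechanistic fitness surface pushed
through the same migration automaton used for the models (threshold 0.25,
rescaled against the series maximum).

**Expert parameter error.** The expert process surrogate uses the true
mechanism but not the true parameter values: midpoints are perturbed by a
normal error scaled to the response width and slopes lognormally
(`expert_param_error`, default 10%). An expert model parameterised from
measurements is never exact, and a surrogate with literally true parameters
would hindcast almost perfectly, saturating the skill metric at 1 and
leaving its regression slope unidentified.

**Pollen.** Sites are placed uniformly (default 120; 10% marine, 45%
lacustrine); each has Poisson(8) samples at uniform random true ages. Grain
totals are lognormal (median ≈ 330, so a realistic share falls below the
200-grain filter), age uncertainties gamma (mean 250 yr, some beyond the
500-yr filter), and sample ages are reported jittered by their own stated
uncertainty. Counts are multinomial over (taxa…, other) with expected focal
shares given by a two-level step function of coarse-cell occupancy at the
nearest slice. The class defaults are 8% (occupied) versus 0.2%
(background rain); the demo scenario uses 4% / 0.4%, which sits close
enough to the 1–2.5% presence thresholds that observed presence carries
realistic detection error and per-bin skill stays off the Sørensen = 1
boundary. The detection model is an artifact choice — nothing in the
processing chain depends on its form, only on the thresholds being
meaningful.

What the generator does **not** emulate: daily weather, radiation/PET
physics, real geography or ice masks, taphonomy beyond the depositional-
environment flag, pollen productivity differences among taxa, and age-depth
model structure (age errors are independent across samples rather than
correlated along a core). Passing tests therefore demonstrate the
*pipeline's* correctness and the *direction* of the model-family contrast
under niche truncation, not quantitative skill levels on real archives.

## Migration automaton

Dispersal runs annually on the fine grid. A kernel (`exponential-power` or
`2Dt`) is discretised over cell offsets by averaging the density on a 5×5
sub-grid per cell; the truncation radius is grown until ≥ 99% of the
continuous mass is inside, then weights renormalise to 1. The mass beyond
the radius defines an inverse-CDF sampler for long-distance events (one
propagule per occupied cell per year with probability 0.01, uniform angle;
off-grid propagules are lost; grid edges are absorbing).

An empty cell with rescaled suitability p and kernel arrival mass
a = 1 − Π(1 − k) colonises with probability p·a — arrival and establishment
multiply, which keeps "zero suitability ⇒ never colonised" exact. The
arrival product is computed as an FFT convolution of log(1 − k) with the
occupancy field; arrivals smaller than half the smallest nonzero kernel
weight are floored to zero, which removes FFT round-off exactly (any cell
within the kernel support of a source receives at least that weight).
Suitability maps update every 250 years (configurable); occupied cells that
become unsuitable are vacated at the update. Initialisation occupies every
suitable cell of the first slice, deferring one slice if the first is empty;
a model with no suitable habitat within that window yields an all-empty
occupancy series rather than aborting the experiment. A year in which every
suitable cell is already occupied (or none is occupied) is skipped as
absorbing — this changes no state and keeps runs fast once a slice
saturates. With long-distance events disabled the spread-rate bound
(≤ kernel radius per year) is asserted inside every step.

## Thresholding and calibration

Per model family and species, the presence threshold τ maximises
TSS = sensitivity + specificity − 1 on the reference slice against the true
reference range (presence predicted when score ≥ τ; ties broken towards the
smallest maximising τ). Suitability above τ is rescaled to
(v − τ)/(v_max − τ) with v_max frozen at calibration so maps are comparable
across slices. The correlative family is one regularised logistic
regression on standardised degree-2 polynomial features — the analysis
needs the correlative/mechanistic contrast, not an inter-algorithm spread.
Inverse calibration maximises AUC with differential evolution under box
bounds (budget in function evaluations; best of `n_restarts` runs retained;
budgets below one population fall back to best-of-random-sample so tiny
budgets still return a valid parameter set). Environmental-block
cross-validation clusters cells by k-means on PCA-rotated standardised
covariates; folds whose test set lacks a class are reported as missing
(NaN), never dropped.

## Climatic dissimilarity

Feature tables (one row per cell × year, eight seasonal columns) are
standardised and projected on three principal components; by default the
loadings come from the pooled focal + reference sample per comparison, with
a reference-only option that allows reference hypervolumes to be built once
and shared across bins (the pipeline uses this for determinism and speed —
with a fixed reference it is also statistically cleaner, since all bins are
measured in the same coordinates). Each period yields `n_boot` hypervolumes
(default 20 in the API; the demo uses 6): a variance-corrected smooth
bootstrap draw (resampled rows plus kernel jitter, shrunk to preserve the
covariance), a Gaussian KDE with Silverman bandwidth, and the region whose
density exceeds the level containing 95% of the resample. The threshold is
computed from leave-self-out densities; evaluating a KDE at its own support
points inflates the quantile and shrinks the region (~30% volume bias for a
3-D Gaussian), which the smooth bootstrap plus leave-self-out correction
removes. The region is represented by a uniform interior cloud (rejection
sampling in a padded bounding box; default 5 000 points, demo 400) with the
volume estimated from the acceptance rate. Sørensen overlap between two
hypervolumes is 2·V(A∩B)/(V(A)+V(B)), with the intersection estimated by
symmetrised cross point-in-region tests. Dissimilarity between a focal and
the reference period is the mean and sd of 1 − overlap over all
`n_boot × n_boot` pairs. Bandwidth rule, 95% quantile and cloud size are
explicit parameters because overlap values depend on them; the calibration
tests pin their joint behaviour (self-dissimilarity < 0.15, disjoint ≈ 1,
agreement with direct Monte-Carlo integration, monotonicity in shift).

Bias correction against a reference-window observation is additive for
temperature and multiplicative for precipitation per cell × season, assumed
constant in time; ratios are capped to [0.2, 5] where the simulated
reference is under 1 mm. Mahalanobis novelty is the minimum distance to the
reference pool under the reference covariance (ridge-regularised if
singular).

## Evaluation and regression

Confusion matrices count data cells only; bins with no data cells are
skipped explicitly. Sørensen = 2TP/(2TP+FP+FN) never sees true negatives —
important because pollen absences far outnumber presences. Transferability
is the relative change from reference-period performance. Kruskal–Wallis
uses the tie-corrected statistic (identical samples return H = 0, p = 1);
Conover–Iman t statistics use the pooled rank variance and the
(N−1−H)/(N−k) correction, referred to Student-t with N−k df, unadjusted
(an adjustment hook exists in the API design but the cited reference
implementation reports unadjusted by default).

The ordered beta regression has group-specific intercepts and slopes and
shared cutpoints c₁ < c₂ and precision φ: P(y=0) = 1 − g(η−c₁),
P(y=1) = g(η−c₂), interior density [g(η−c₁) − g(η−c₂)]·Beta(y; g(η), φ)
with logistic g. Predictor measurement error (x_obs ~ N(x_true, sd)) is
integrated out by 15-node Gauss–Hermite quadrature, so no latent variables
are sampled. The ML path uses Nelder–Mead + BFGS from multiple starts with
Wald intervals from a ridge-stabilised numerical Hessian; the Bayesian path
runs an affine-invariant ensemble sampler (emcee) initialised at the ML
solution under weakly-informative priors — N(0,5) on slopes, intercepts and
cutpoints (ordering enforced by a log-gap parameterisation with its
Jacobian), Exponential(0.1) on φ. The cutpoint ordering c₁ < c₂ and the
three-way probability normalisation hold by construction for all parameter
values. The pipeline's default fit is ML with measurement error (the demo
regression on 36 records takes seconds); `--bayes` switches the final fit
to posterior sampling.

## Problem sizes and reproducibility

The shipped demo uses a 40×40 coarse grid (80×80 fine), twelve slices, two
species, 120 pollen sites, six bootstrap hypervolumes of 400-point clouds
on 600-row feature subsamples, and a 1 500-evaluation × 2-restart inverse
calibration — chosen so a full experiment completes in well under a minute
while every stage still has enough data to behave like its full-scale
counterpart. Every stochastic stage consumes a named child seed spawned
from the master seed; reruns with the same configuration reproduce the
manifest (config digest + stage seeds + content hashes of every
intermediate product) bit for bit.

## Known limitations

- The correlative family is a single flexible classifier; the spread among
  correlative algorithms is out of scope.
- Inverse calibration can place unobservable parameters (e.g. the frost
  midpoint when frost never limits the calibration range) anywhere the data
  do not penalise; occasionally the fitted model then predicts no habitat
  in the cold start and its occupancy stays empty — a realistic failure
  mode that is reported, not suppressed.
- Dissimilarity values depend on the hypervolume construction parameters;
  comparisons are meaningful within a configuration, not across
  configurations.
- Chronological jitter blurs bins during the rapid warming: samples whose
  true age falls in a fast-changing interval mix occupancy states, which
  bounds every model's attainable skill in transition bins.
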