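# Methods

This note documents the models and procedures implemented in `sdmsense`,
the parameters that matter, the design of the synthetic study system, and
the limits of what the package's tests can show about real data.

## The niche model

The core model is a presence–background maximum-entropy (Gibbs) density.
Given a training region of background cells $x_1,\dots,x_n$ and presence
cells drawn where the species was recorded, the model estimates

$$q(x) = \frac{\exp\big(\sum_j \lambda_j f_j(x)\big)}{Z},\qquad
  Z = \sum_{i=1}^{n} \exp\Big(\sum_j \lambda_j f_j(x_i)\Big),$$

the maximum-entropy distribution over the background whose feature
expectations match the presence sample means (up to the regularization
slack below). The assumptions are the standard ones of presence-background
modeling: occurrence records are an (effort-weighted) sample proportional
to suitability, background cells characterize available conditions, and
suitability depends on location only through the covariates.

**Features.** Per covariate: one linear, one quadratic, and forward plus
reverse hinge features at `hinge_knots` (default 10) equally spaced
interior knots of the background range. All features are affinely
rescaled to $[0,1]$ using the background minimum/maximum, which bounds
gradients and puts one regularization scale on all features. A covariate
that is constant on the training region produces degenerate features that
are excluded from fitting (with a logged warning). Hinge features are on
by default; they are what gives the model its flexible, piecewise-linear
response curves.

**Fitting.** Weights minimize
$L(\lambda) = -\tfrac1m\sum_i \log q(x_i) + \sum_j \beta_j|\lambda_j|$
with $\beta_j = r\,\hat\sigma_j/\sqrt{m}$, where $m$ is the number of
presences, $\hat\sigma_j$ the background standard deviation of feature
$j$ (floored at $10^{-3}$ so near-constant features are not effectively
unpenalized), and $r$ the regularization multiplier (default 1).
Optimization is cyclic coordinate descent: for each feature a proximal
Newton step with soft-thresholding, backtracked on the penalized
objective until it does not increase. Convergence is declared when a full
cycle decreases the objective by less than `convergence_tol` (default
$10^{-6}$); the iteration cap is 500 cycles. Weights start at zero and
the cycling order is fixed by construction order, so fits are
bit-reproducible; randomness enters the pipeline only upstream (sampling,
thinning, splitting). The fitted model stores $\log Z$, the entropy $H$
of the fitted background distribution, and the per-feature penalties.

**Logistic output and projection.** For interpretability the raw density
is mapped to $p = \tau e^{H} q/(1+\tau e^{H} q)$ with default prevalence
$\tau = 0.5$: a cell with the suitability of a "typical" presence site
(raw density $e^{-H}$) scores $\tau/(1+\tau)$. The transform is strictly
increasing in $q$, so AUC and cell rankings are identical on either
scale. When projecting onto any stack — the training region, the full
map, or a future climate — cells are scored on the *training* scale,
$q(x) = \exp(\sum_j\lambda_j f_j(x) - \log Z_{\text{train}})$, rather
than renormalized per projection region. This keeps logistic values
comparable across regions of different sizes and, in particular, lets a
model trained on a small well-surveyed region show the higher, more
peaked probabilities it earned there; renormalizing per region would
deflate exactly those models (their $H$ is on the small-region scale) and
would make thresholded maps depend on the size of the region being drawn.
A per-region renormalized density remains available through
`MaxentModel.raw_density`. Projection covariates are by default clamped
to the training background range, with clamped cells flagged.

## Pre-modeling treatments

- **Season/year filter**: retains records whose month and year fall in a
  configured window (e.g. June–August 2000–2010 for breeding-season
  data). Synthetic records carry no dates and skip this stage.
- **Spatial thinning** (the "unbiased" treatment): one record per
  occupied cell of a thinning grid, chosen uniformly at random; the
  thinning grid's origin is registered to the covariate grid, not to the
  data's bounding box, for reproducibility. Thinning is applied before
  the train/test split, matching the order in which field datasets are
  usually prepared.
- **Train/test split**: a seeded random partition; the test count is
  `round(test_fraction · N)` (half-up), clamped so both parts are
  non-empty. Default `test_fraction` 0.3.

## Evaluation

- **AUC** is the Mann–Whitney statistic of presence scores against the
  model's background sample (ties count ½), computed from midranks; train
  AUC uses training presences, test AUC held-out presences, both against
  the same background. It is invariant under the logistic transform.
- **Thresholding** uses $p \ge t$ (a cell exactly at threshold is
  present); default thresholds 0.1 (generous) and 0.4 (conservative).
  For $t_1 < t_2$ the conservative range nests inside the generous one.
- **Range similarity** against a reference range is the mean of (i) the
  percentage of the predicted range lying inside the reference and
  (ii) the percentage of the reference covered by the prediction. Both
  components are reported so either reading is recoverable. An empty
  prediction scores 0/0 with a warning rather than aborting a factorial
  run; an empty reference is an error.
- **Range change** between current and future predictions reports
  stable ($|C\cap F|$), lost ($|C\setminus F|$) and gained
  ($|F \setminus C|$) cells and the percentage change in area
  $100\,|F|/|C|$; a species is a **loser** when this is below 100.
  Areas default to raw cell counts (exact on the planar synthetic grid);
  a cos-latitude weighting could be added for geographic grids but is
  deliberately not applied anywhere by default.
- **Spearman's rho** (Pearson correlation of midranks) relates AUC to
  similarity across all cells of a factorial run.

## The synthetic study system

The generator replaces the external inputs of a real range-forecasting
study with objects whose truth is known, at a scale a laptop can run.
Defaults (all in `ExperimentConfig`, units in covariate-grid cells and
standard deviations of the standardized covariate fields):

| parameter | default | why |
| --- | --- | --- |
| grid | 100×100 planar, unit cells | large enough for regional structure, small enough for hundreds of fits |
| covariates | 6 layers: 2 informative + 4 nuisance | a scaled-down stand-in for a large correlated bioclim stack; the nuisance layers give L1 regularization real work, and give a biased fit material with which to "explain" effort clumps |
| field autocorrelation | Gaussian kernel, sd 15 cells | regional-scale climate structure, so sub-regions of the map differ systematically (a surveyed west vs an environmentally distinct unsurveyed east), not just cell-to-cell noise |
| species | 6; niche optima uniform in [−1, 1] sd, breadths 0.35–0.7 sd, Gaussian suitability, max 1.0 | habitat specialists of the kind range modeling is typically applied to; suitability $s(z)=\exp(-\sum_k (z_k-\mu_k)^2/2\sigma_k^2)$ |
| reference range | true suitability ≥ 0.1 | the stand-in for a published range map: expert maps are broad, including marginal habitat, so the cutoff sits low relative to the core |
| occurrences | 3,000 per species | portal-scale data volumes (real biased sets run 10² –10⁴ records) |
| observer effort | 90% on 3 Gaussian clusters (sd 5 cells), 10% uniform, all inside the surveyed western 55% of the map | clumped monitoring effort plus a hard survey-coverage gap (the analogue of a neighboring region with no records); cluster centers are drawn independently of suitability, so the bias reflects effort, not biology |
| thinning cell | 2.5 covariate cells | coarse enough that saturated effort clusters collapse to a few records each, mirroring field practice of thinning on a much coarser grid than the covariates |
| future climate | +0.5 sd on every layer, scaled 2× at the north edge to 0 at the south | a poleward change gradient producing a mix of range losers and gainers |
| background | min(10,000, all training cells) | the conventional default; on these grids it is the full training region, which also keeps the entropy term of the logistic output on the same scale as projected densities |

Occurrences are drawn cell-wise with probability ∝ suitability × effort
(with replacement — portals contain many records per cell), then placed
uniformly within their cell. The "biased" dataset of the factorial is the
raw clustered sample; the "unbiased" dataset is its spatially thinned
version, so the two treatments differ only in the treatment, not in an
independent redraw. The "restricted" training extent is the convex hull
of the training records (padded by one cell), rasterized by cell-center
containment — the region the data actually cover — while projection is
always onto the full map. All generators are pure functions of their
parameters and a seed; per-species and per-stage seeds are spawned
deterministically from one master seed.

**What the generator does *not* emulate:** detection error and false
presences, coordinate imprecision, niche responses that are not smooth
and unimodal in the covariates, dispersal limitation and biotic
interactions decoupling the realized range from the suitable range, and
reference maps that are themselves wrong — all of which real studies
face. A passing directional test here therefore shows that the pipeline
*can* reproduce the qualitative effects of these decisions under
controlled conditions with a correct reference; it does not certify
effect sizes for any real dataset.

## Numerical choices and degenerate inputs

- Grid compatibility is exact to 1e-9; mismatched rasters are errors,
  never resampling triggers (reprojection is out of scope).
- Cell membership uses half-open intervals (a point on a shared edge
  belongs to the cell to its east/south); points outside the grid or on
  nodata cells are flagged, not dropped.
- Ties in the one-per-cell thinning lottery (including exact duplicate
  coordinates) are resolved uniformly at random under the stage seed.
- The coordinate-descent curvature estimate is floored at 1e-8; steps
  that overflow the shifted exponentials are halved until finite.
- Convergence is measured on the penalized objective, not weight
  movement, matching the usual "convergence threshold" semantics.
- A factorial cell that fails (e.g. an empty predicted current range at
  the conservative threshold makes percent change undefined) is recorded
  with `status="failed"`; summaries proceed with reduced n and say so.

## Known limitations

- Feature classes are limited to linear, quadratic and hinge; product,
  threshold and categorical features are not implemented.
- Raster I/O is single-band ESRI ASCII grid only, with GeoJSON polygons
  for extents; everything must arrive on one grid.
- AUC is presence-vs-background, not presence-vs-absence; its known
  weaknesses as a model-quality score are, in fact, part of what the
  factorial experiment is designed to expose.
- The logistic output's absolute scale depends on the default-prevalence
  assumption τ = 0.5; thresholds applied to it inherit that assumption.
- `max_probability` values from this implementation are not expected to
  numerically match those printed by other maxent implementations for
  real datasets; all statistics are defined on this package's own fits.
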