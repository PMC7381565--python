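# Methods

`divpart` implements the statistical chain used to separate contemporary
(climatic, soil) from historical (post-glacial climate change) drivers of
soil faunal diversity and community composition. This note documents the
models, the defaults and why they were chosen, and what the synthetic-data
tests do and do not establish.

## The scientific problem

Soil nematode surveys along large latitudinal gradients show diversity and
composition correlating both with present-day climate/soil and with the
magnitude and velocity of climate change since the Last Glacial Maximum
(LGM, ~21 kyr BP). Because these predictor sets are strongly collinear
along latitude, single-predictor correlations cannot say whether history
has an effect *beyond* what current conditions already explain. The chain
here answers that with variation partitioning: the explained variance of a
diversity response is decomposed into pure and shared fractions across the
three predictor sets, with permutation-based significance per fraction.

## Historical predictors (paleoclimate module)

- **Anomaly** (TA, PA): cell-wise present-minus-LGM difference in mean
  annual temperature / precipitation. Signed by default when used as a
  predictor; the velocity always uses its magnitude. Multiple paleoclimate
  model outputs (e.g. CCSM, MIROC) are combined by a cell-wise mean with
  strict nodata propagation.
- **Spatial gradient**: central differences over the four rook neighbours,
  `sqrt(((E-W)/2dx)^2 + ((N-S)/2dy)^2)`, in variable units per km. Edge
  cells and cells with a nodata neighbour are nodata — no one-sided
  stencils, so the gradient is symmetric wherever it is defined. On
  geographic (degree) grids, east-west spans are scaled by cos(latitude).
- **Change velocity** (TCV, PCV): `|anomaly| / max(gradient, floor)` in km
  — the displacement an organism must track to keep constant climate. The
  gradient floor (default 1e-6 units/km) keeps velocity finite on flat
  terrain; a per-year option divides by the 21,000 years elapsed.
- **Log transform**: velocities are strongly right-skewed, so TCV/PCV are
  `log10(raw + offset)` with offset 0 by default (an error is raised if a
  raw velocity is non-positive then — make the offset explicit rather than
  silently shifting).

Only plain-text ESRI ASCII grids are supported; no raster library in the
runtime environment reads GeoTIFF, and the analysis needs nothing beyond a
regular grid with a georeferenced origin.

## Diversity metrics

Genus richness counts strictly positive abundances (site values may be
fractional after plot averaging, so any positive mean is a presence).
Shannon's diversity is `-sum p_i ln p_i` (natural log). Jaccard
dissimilarity is incidence-based `(b+c)/(a+b+c)`; Bray-Curtis is
abundance-based `sum|x_ij - x_ik| / sum(x_ij + x_ik)`. Bray-Curtis against
an all-zero site is undefined by the formula; the implementation applies
the d = 1 limit convention with a warning (containers normally forbid
all-zero sites, so the case arises only through deliberate construction).

## Elastic-net variation partitioning

Predictor collinearity plus small n rule out plain multiple regression, so
each predictor-set combination is fit by the elastic net: penalty blend
`alpha` in [0, 1] (ridge to lasso) and strength `lambda`, both tuned by
5-fold cross-validation minimizing validation RMSE, then refit on all rows.
Specifics:

- Predictors are standardized (zero mean, unit population SD) before
  penalization — the penalty is not scale-invariant. Standardization is on
  the full data once; within CV folds, columns and the response are
  re-centred on the training rows so each fold carries its own intercept.
- Default alpha grid 0.05, 0.10, ..., 1.00; 50-point geometric lambda path
  from the smallest lambda zeroing all slopes down by a factor 1e-3. Ties
  in CV RMSE break toward the smallest alpha, then the largest lambda.
- Performance is the adjusted R², `1 - (1-R²)(n-1)/(n-p-1)`, with `p` the
  number of predictors *offered* (the formula's "number of predictors");
  counting only survivors of shrinkage is available as an option. R² is
  in-sample on the refit model.
- A single CV split is unstable at n = 16, so the adjusted R² is averaged
  over repeated CV reruns (default 100 reshuffles).
- The seven combination values {C, S, H, CS, CH, SH, CSH} are decomposed by
  inclusion-exclusion into three pure fractions, three pairwise overlaps
  and the triple overlap; the fractions sum to the full-model value by
  construction (asserted to 1e-10). Negative fractions are reported as-is:
  they are differences of adjusted R² values and mean "negligible".
- Significance: the response is permuted (default 999 times), the entire
  seven-combination partition recomputed per permutation — including
  re-tuning (alpha, lambda), the more conservative choice — and each
  fraction/total compared one-sidedly to its null distribution
  (`p = (1 + #{null >= obs}) / (1 + n_perm)`; the significance flag uses
  the observed-exceeds-95%-null-quantile rule). Null partitions default to
  10 CV repeats versus 100 for the observed value to keep 999 x 7 refits
  tractable; set them equal for full fidelity.
- Residuals of the full model can be checked for spatial autocorrelation
  with Moran's I under row-standardized inverse great-circle-distance
  weights (the weighting is a free choice; an explicit weight matrix can be
  supplied) and a two-sided permutation test.

The inner solver is a numba-compiled cyclic coordinate descent on the
Gram matrix (scikit-learn's objective convention; agreement with
`sklearn.linear_model.ElasticNet` is asserted to ~1e-9 in the tests). This
is purely a performance decision: the permutation schedule needs millions
of path solves, three orders of magnitude beyond what per-call library
overhead allows.

## Composition analyses

- **NMDS**: SMACOF with isotonic regression (scikit-learn backend),
  k = 2 by default, best of 50 starts — one deterministic classical-scaling
  (PCoA) start plus random starts. The PCoA start makes stress effectively
  non-increasing in k and solves embeddable configurations exactly. Scores
  are centred and rotated to principal axes with a fixed sign convention,
  so reported configurations are deterministic. Stress is the normalized
  (Kruskal-type) stress in [0, 1].
- **envfit**: each variable is regressed on the ordination scores; r² of
  that regression scores the fit and the unit coefficient vector gives the
  arrow direction; significance from permuting the variable across sites.
- **Mantel test**: Pearson correlation of strictly-lower triangles, null
  from simultaneous row/column permutations of one matrix (never
  independent entries), one-sided. Spatial distance is great-circle km from
  site lon/lat.
- **Distance-based variation partitioning**: per predictor set, variables
  are standardized, PCA computed, and Euclidean distance taken over *all*
  components (identical to distance on the standardized variables — the
  PCA is an explicit change of basis, kept for fidelity to the procedure).
  Response distances are regressed on the 1-3 set-distance vectors by OLS
  for each combination; adjusted R² uses n = n(n-1)/2 pairs and p = number
  of distance predictors. Pairs are not independent, so these adjusted R²
  values are descriptive; inference comes from matrix (site-label)
  permutations, which respect the dependence.

One-sided permutation p-values are used throughout the partitioning
machinery, matching the exceeds-the-95%-null-quantile convention.

## The synthetic world

The generator emulates the survey design: 16 sites evenly spanning
22-40°N, 3 plots per site, multinomial draws of 150 identified individuals
per plot, plot counts averaged (possibly fractionally) to site level, and
the 4 + 3 + 4 variable roster (MAT, MAP, TS, PS / SOC, TN, pH / TA, PA,
TCV, PCV) with baselines and slopes loosely matching a temperate gradient.

Structure:

- Each predictor set has one latent factor
  `sqrt(rho) * L + sqrt(1-rho) * noise`, with L the standardized latitude:
  any two set latents correlate at exactly `rho` (default 0.6 — the
  real-world sets are strongly collinear) and couple to latitude at
  `sqrt(rho)`. Setting `rho = 0` makes the sets independent, the clean
  regime for effect-recovery experiments. At `rho = 0` the latents are
  necessarily latitude-free: exact correlation control and a fixed
  latitudinal loading cannot coexist.
- The diversity driver is a linear combination of the set latents
  (`effect_sizes`, per-set standardized slopes) plus Gaussian noise
  (default SD 0.5). Because the driver is linear in jointly Gaussian
  latents, the population pure/shared variance fractions have a closed form
  recorded as `truth` — the generating ground truth for the driver itself.
- Communities follow Gaussian niche curves along the standardized driver
  (common breadth, optima uniform over the gradient span), multiplied by a
  genus-rank dominance term whose exponent decays with the driver: high
  driver values flatten the abundance distribution, so richness and Shannon
  diversity rise with the driver after multinomial subsampling. Plot-level
  gradient jitter (SD 0.3) creates within-site variance; the plot-to-site
  variance ratio is a free parameter because the field design does not pin
  it down.
- Paleoclimate grid pairs are planar (optionally noisy) analytic fields
  with exactly known anomaly and gradient everywhere.
- All randomness flows from one master seed through named SHA-based
  substreams, so generating one component never perturbs another.

What a green test establishes: the inference machinery is calibrated (type
I error within [0.01, 0.12] at nominal 0.05 on null data) and powerful
enough to attribute a planted single-set effect to the right pure fraction.
What it does not: realism of spatial covariance in real climate rasters,
phylogenetic or trophic structure among genera, or the field study's actual
effect sizes — those depend on the deposited field data, not on this
package.

## Numerical and design choices

- Coordinate-descent tolerance 1e-7 (max 500 sweeps) inside CV; 1e-12 for
  single fixed-penalty fits used in oracle comparisons.
- The CV validation SSE comparison uses strict improvement, making the
  (alpha, lambda) selection deterministic under ties.
- Monte-Carlo acceptance tests run with a reduced fixed tuning
  configuration (alpha = {0.5}, 10-point lambda path, 199 permutations,
  1-2 CV repeats) chosen for a single-CPU time budget before outcomes were
  measured; bands and replicate counts are not adjusted afterwards.
- `run_all` writes every numeric output deterministically (exact float
  `repr`), and readers parse with round-trip float precision, so rerunning
  under one seed reproduces files byte-for-byte; the JSON run record also
  stores wall time and is therefore excluded from byte comparisons.

## Known limitations

- At n = 16 with 11 predictors the full-model adjusted R² divides by
  n - p - 1 = 4; individual fractions are noisy and frequently negative.
  This is faithful to the method at survey scale, not a defect of the
  implementation.
- Distance-based adjusted R² treats pairs as exchangeable units for the
  point estimate; only the permutation p-values are inferentially safe.
- The cos(latitude) correction approximates great-circle cell spans;
  sub-percent error at survey latitudes, growing toward the poles.
- TS/PS (seasonality) derivation from monthly grids is out of scope; the
  synthetic generator supplies them directly.
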