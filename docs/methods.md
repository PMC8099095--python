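# Methods

## Compilation screening and site averaging

Records enter as rows with site, coordinates, δ³⁴S (‰ VCDT), optional
elemental data and annotation flags. Atomic C/S, N/S and C/N ratios are
derived from weight percents (masses 12.011, 14.007, 32.06) when not
reported directly. A record is kept iff

- none of the flags *diagenesis reported*, *non-local reported* (origin
  more than 100 km away per the source publication), or *aquatic/fish
  consumer* is set, and
- its preservation ratios satisfy the strict inequalities C/S < 300 and
  N/S < 100, **or** it is a sulfur-only record (no C/N data reported),
  which passes unscreened.

Records lacking both ratios and the sulfur-only flag are treated as
sulfur-only (kept, with a warning): such rows predate uniform elemental
reporting, and rejecting them would silently bias the compilation toward
recent publications. Rejections carry exactly one reason, evaluated in
the fixed order diagenesis → non-local → aquatic → elemental-ratio, so
the partition kept ∪ rejected is deterministic and auditable.

Sites are grouped by `site_id` (falling back to coordinates rounded to
4 decimals); the site mean is the arithmetic mean of record δ³⁴S and the
site SD is the sample SD (n − 1 denominator), undefined for single-record
sites. Summary statistics pool site SDs only over multi-record sites.
Non-locality is consumed as a pre-annotated flag and never recomputed
from distances, since the underlying designations are archaeological,
not geometric. A Shapiro–Wilk statistic on the site means is reported as
a normality diagnostic.

## Grids

All spatial work happens on one equal-area projected grid with square
cells, row-major with origin at the upper-left. Cells are half-open,
`[x, x + cell) × (y − cell, y]`: a point on a shared edge belongs to the
cell to its right/below, one deterministic rule verified against an
exhaustive containment oracle. Because the grid is equal-area, area
ratios are cell-count ratios throughout.

Rasters are serialized as single-band ESRI ASCII text grids with an
explicit nodata value; the package implements this reader/writer itself
and a minimal coordinate-transform registry (an identity "local" metric
frame and an equirectangular lon/lat→metre approximation) rather than
depending on a GDAL stack. Resampling supports nearest and majority-vote
("mode") for discrete layers and bilinear for continuous layers, with
nodata propagating; it is exact on the identity case and idempotent on
the target grid. Distance to coast is the exact Euclidean distance
transform (cell-center to cell-center, km), cross-checked against an
O(n²) brute force.

## δ³⁴S isoscape regression

The response is the vector of screened site-mean δ³⁴S values; the design
matrix holds covariates extracted at the site cells. The regressor is a
random forest with `n_trees = 500`, `max_features = max(1, round(p/3))`
(the standard regression-forest third), and `min_leaf = 5`. These
hyperparameters are conventional defaults, exposed in the config; forest
predictions are means of training responses and therefore stay inside
the training range.

**Variable selection** is two-stage, in the style of ranking-then-adding
selection under random forests:

1. *Ranking.* Permutation importance is computed on each tree's
   out-of-bag sample (increase in OOB MSE when a variable is permuted)
   and averaged over `n_rank_forests = 10` independently seeded forests.
   Variables whose mean importance falls below
   `importance_sd_multiplier (=1) × SD` of the importances in the lower
   half of the ranking — the noise tail — are eliminated.
2. *Addition.* Survivors are added greedily in rank order; an addition
   is kept only if it lowers the OOB RMSE by more than
   `addition_tolerance (=0)` relative to the best model so far. The
   baseline is the RMSE of predicting the response mean, so a dataset
   with no usable signal legitimately selects nothing.

The per-tree out-of-bag index sets are reconstructed with the same
bootstrap recipe the forest implementation uses; a unit test asserts the
reconstruction reproduces the forest's own OOB predictions exactly, so
any upstream change in the recipe fails loudly instead of silently
skewing importances.

**Cross-validation.** The scheme is `folds × repeats` random splits
holding out `1 − train_fraction` of the sites each (defaults 10 × 5 at
80% training, i.e. 50 random 80/20 splits); classic repeated k-fold is
available via `train_fraction = None`. RMSE and R² are computed on the
held-out predictions pooled over all splits, never on training folds,
and a Shapiro–Wilk statistic of the pooled residuals is reported.

**Prediction.** The fitted forest is evaluated over the covariate stack;
a cell is nodata wherever any required layer is nodata. The uncertainty
surface is a constant equal to the cross-validated RMSE — a deliberate
simplification: the forest gives no spatially explicit predictive
variance, and residual kriging or quantile forests are out of scope.
Permutation and impurity importances and partial-dependence curves
(mean prediction with one covariate swept, all others at observed
values) are available as diagnostics.

## Oxygen conversion chain

Enamel structural carbonate δ¹⁸O is reported on VPDB, while the
phosphate and drinking-water calibrations operate on VSMOW. The chain is

1. VPDB → VSMOW: δ′ = 1.03091 δ + 30.91 (Coplen relation),
2. carbonate → phosphate: δ¹⁸Op = (δ¹⁸Oc − 8.79 (±0.79)) / 1.015 (±0.043),
3. phosphate → water: δ¹⁸Ow = (δ¹⁸Op − 21.28 (±0.51)) / 0.68 (±0.04).

Every step is a strictly increasing affine map, exactly invertible, and
each value carries explicit scale and mineral-fraction tags so that a
step applied to the wrong representation raises instead of silently
producing nonsense. Whether the source tooth values should be rescaled
VPDB → VSMOW before step 2 is genuinely ambiguous in parts of the
calibration literature; the pipeline applies the rescaling by default
and exposes `assume_input_scale` to skip it.

The combined calibration uncertainty of steps 2–3 is taken as the
summary 1.0‰ rather than re-derived, and is folded into the
precipitation isoscape SD in quadrature by default (`additive` is
available, since "added" could be read either way). A first-order
analytic propagation from the printed coefficient SDs is provided for
comparison (`propagate="analytic"`).

## Probabilistic assignment

For measurement x\* against isoscape (μ_c, σ_c), each valid cell gets
z_c = (x\* − μ_c)/σ_c (measurement SD, if any, inflates σ in quadrature)
and the standard-normal density f(z_c) = exp(−z_c²/2)/√(2π). Densities
are normalized over the valid cells into a probability-of-origin
surface. All densities are computed in log space and normalized by
max-subtraction, so assignments survive |z| well beyond 30; the
linear-space `normalize` raises with a pointer to the log path when it
underflows. Under independence between isotopic systems, surfaces
multiply cell-wise (log-sum) and renormalize over the intersected mask.

"Highest 33.3% of the probability distribution" is implemented as
cumulative posterior mass: cells are ranked by probability descending
and the shortest prefix reaching mass q is included, with all cells tied
at the cut value included so the region is permutation-invariant. The
alternative reading — the top q *fraction of cells* by probability —
is available as `threshold_mode="area_fraction"`. Precision is
100 × (1 − |region| / |valid cells|), which on an equal-area grid is the
percentage of study area removed. The joint surface is renormalized
(rather than kept as a raw density product); the area metric is
rank-based and insensitive to this choice, but stored surfaces sum to 1.

## Synthetic world

The generator emulates the structure, not the geography, of the real
problem on a default 120 × 120 grid of 10-km cells (scale-free; the
1-km continental grid of a real application would only change cell
counts). A sinuous north–south coastline bounds a western sea band.
Covariates:

- `r.ssa` — sea-salt deposition, `20 · exp(−d/100 km)` kg/ha/yr of
  coastal distance d (computed by the grid module's distance transform);
- `r.dust` — a north–south gradient plus low-frequency noise, positive
  in g/m²/yr;
- `r.bouguer` — a smooth random field (±120 mGal) at a finer correlation
  scale than the aerosol fields and explicitly decorrelated from the
  dust field, so the two responses on the true surface are separately
  identifiable — heavily smoothed random fields on a small grid
  otherwise correlate strongly by chance and their contributions can
  cancel;
- five pure-noise decoys, checked at generation to have |r| < 0.2 with
  the true surface.

The true δ³⁴S surface is a coastal plateau with a softplus decline:
`μ = plateau − slope · w · log(1 + exp((d − breakpoint)/w))` with
plateau 15.5‰, breakpoint 150 km, slope 0.021‰/km and width w = 60 km,
re-expressed through the sea-salt covariate so the regression sees the
signal; bounded (tanh-squashed) dust and gravity terms of ±2.5‰ are
added. The resulting surfaces span roughly −5…21‰, matching the range
of compiled collagen values.

**Noise calibration.** Within-site replicate scatter is fixed at 1.77‰.
The between-site effect SD is derived at sampling time from the
empirical variance of the true surface so that a configured
`signal_fraction` (default 0.65) of the site-mean variance is signal;
with `signal_fraction = None` a fixed 1.8‰ site SD is used instead.
This makes the cross-validated R² target an honest property of the
generator rather than a tuned coincidence; an R² slightly below the
signal fraction is expected, since the forest is not an oracle.

Individuals are drawn uniformly over valid land cells; each measurement
is the assignment isoscape's mean at the true cell plus Normal noise
with that isoscape's SD — the well-specified case under which the
q-mass region of a correct posterior covers the true origin at ≥ its
nominal rate. A noise multiplier produces the mis-specified case, where
coverage drops below nominal (verified as a directional test). One seed
drives a splittable stream (world / sites / individuals), so components
regenerate independently and all tabular outputs are byte-reproducible.

**What the synthetic world does not emulate:** real European geography,
the actual covariate data products and their error structure, spatial
autocorrelation of site placement (sites are uniform, real compilations
cluster by research history), period effects, and any dependence between
isotope systems. Passing recovery tests therefore demonstrates the
machinery is correct and calibrated under its own assumptions, not that
a real-data isoscape would reach the same skill.

## Problem sizes and defaults

End-to-end experiments use 200 sites × 5 records, 10 × 5 CV splits,
500-tree forests, and 500-individual assignment ensembles for coverage
(25 for the per-seed summaries); five seeded worlds per run. These sizes
give stable estimates (binomial 95% margin ≈ 0.04 on coverage at
n = 500) while keeping a full run in the minutes range on one CPU.

## Known limitations

- The constant-RMSE uncertainty understates coastal/inland differences
  in predictive error; quantile forests or residual kriging would refine
  it.
- Greedy OOB-based addition can admit a decoy whose chance correlation
  with the response is real *within the sample* (it generalizes to OOB
  cells of the same dataset but not to new data); at the default sizes
  this is infrequent but not impossible, and the addition tolerance is
  exposed for stricter selection.
- The equirectangular transform is an approximation suitable for
  regional grids only; a production deployment on continental real data
  would substitute a proper projection library behind the same
  interfaces.
- Independence between isotope systems is assumed at combination, as is
  standard; shared climatic drivers can violate it in real data.
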