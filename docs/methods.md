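# Methods

This note documents the models and procedures implemented in `beescape`,
the assumptions behind them, the synthetic data the package generates, and
the numerical choices made where the design was genuinely open.

## Community metrics

Per-site **abundance** is the square root of the mean per-visit total count,
with *Apis mellifera* excluded by name: honeybees are a managed input to
agricultural landscapes and would obscure the wild-bee response to land
cover. The order of operations matters and is fixed: average across visits
first, then square-root. Visits where only excluded species were recorded
still count in the denominator.

**Diversity** is Simpson's `1 − D` on counts pooled over visits, honeybees
included (they are part of the realized community even if managed). Two
variants are provided: the plug-in form `1 − Σ pᵢ²` (default, matching the
common ecology-package convention) and the finite-sample form
`1 − Σ nᵢ(nᵢ−1) / (N(N−1))`. A site with zero bees over all visits has no
community to describe; the per-site aggregation reports 0 with a warning,
while the scalar function raises on all-zero input.

**Composition** is the oriented first axis of an NMDS ordination. The
community matrix is processed as season means → element-wise square root →
Wisconsin double standardization (each species divided by its column
maximum, then each site by its row total; all-zero rows/columns stay zero).
Dissimilarity is Bray–Curtis, `Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ)`, with a 0/0 pair
defined as distance 0 (warned). Because NMDS axes are arbitrary up to
rotation and reflection, axis 1 is reflected when necessary so that it
correlates nonnegatively with wind-pollinated-crop cover; the positive end
of the axis therefore always means annual-crop-associated communities.

### NMDS engine

Kruskal stress-1, `sqrt(Σ(d* − d̂)² / Σ d̂²)`, is minimized by alternating
(i) isotonic (pool-adjacent-violators) regression of the configuration
distances `d̂` on the rank order of the input dissimilarities, giving the
monotone targets `d*`, with ties handled by the primary (weak) approach —
pairs tied in dissimilarity are pre-sorted by current `d̂` and impose no
constraint among themselves — and (ii) a Guttman (SMACOF) update toward
`d*` under a backtracking line search that only accepts steps that lower
the full stress. The stress trace within a start is therefore non-increasing
by construction. The first start is the classical-scaling configuration of
the dissimilarities; the remaining starts (20 by default) are random.
Convergence is declared when the relative stress change drops below 1e-7
(or stress falls below 1e-8); the best start is returned.

Two numerical guards deserve note. First, weak-tie stress minimization
admits *degenerate cluster solutions*: when the dissimilarities are roughly
ultrametric, collapsing sites into a few coincident clusters drives stress
toward zero while destroying all within-cluster information (on one
synthetic dataset the unguarded optimizer reached stress 5 × 10⁻⁵ where
vegan's `metaMDS` reports 0.20). Line-search steps that would push the
minimum configuration distance below 0.5% of the maximum are therefore
shortened — but only when the input dissimilarities themselves keep all
pairs apart, so genuinely coincident sites may still coincide. Second,
stress-1 is scale-invariant, so the final configuration is rescaled to make
the mean configuration distance equal the mean input dissimilarity, putting
axis scores on an interpretable scale.

**Vector fitting** regresses each (centred) environmental variable on the
(centred) ordination scores; the direction is the unit coefficient vector,
`r²` the squared multiple correlation, and the p-value a permutation tail
probability `(1 + #{r²_perm ≥ r²_obs}) / (n_perm + 1)`. **SIMPER**
attributes mean between-group Bray–Curtis dissimilarity to species: for
each between-group pair the per-species share is `|xᵢₛ−xⱼₛ| / Σₜ(xᵢₜ+xⱼₜ)`,
averaged over pairs; the shares sum exactly to the mean between-group
dissimilarity, which the tests assert against the independent distance
computation. Groups are the sites with positive vs negative oriented
NMDS-axis-1 scores.

## Land-cover models

Each metric is regressed on the proportions of grassland, forest,
wind-pollinated crops, and flowering annual crops within 1,500 m of the
site. All 16 predictor subsets (including intercept-only) are fitted by
OLS. AICc is `−2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` counting the error
variance (`k = p_regression + 1`), the Gaussian-likelihood convention.
Akaike weights are `exp(−Δᵢ/2)` normalized over the set. Averaged
coefficients use shrinkage — a model that omits a variable contributes a
zero coefficient — and by default the whole 16-model set is averaged (a
ΔAICc cutoff is available by option). Variable weights are the summed
Akaike weights of models containing the variable. Fit quality is reported
as a pseudo-R², the squared Pearson correlation between observations and
model-averaged predictions. AICc ties are broken by fewer parameters, then
lexicographic subset identity, so output order is deterministic.

Residual spatial structure is checked with a distance-binned Moran's I
correlogram: equal-width bins over (0, max pairwise distance], Moran's I
per bin, and a 95% two-sided envelope from random relabelings of the
residuals (199 by default). Under the null the statistic centres on
`−1/(n−1)`; a bin outside its envelope is flagged. This binned-permutation
form supports the same decision — is residual autocorrelation detectable? —
as a spline correlogram, without the spline machinery.

## Moving windows and projection

A cell belongs to the window of a focal cell iff its centre lies within
Euclidean distance `radius` (inclusive) of the focal cell centre; the same
definition serves site buffers and per-pixel surfaces, which the tests
cross-check. Near edges the denominator counts in-bounds window cells only
(synthetic sites are placed at least one radius from the edge, so buffers
never truncate). The fast path is FFT convolution of class-indicator
rasters with the disc kernel; because both operands are 0/1, outputs are
rounded back to exact integer counts, so the fast path agrees with a
brute-force per-pixel loop exactly, and far-field pixels of a change map
are exactly zero rather than within float tolerance.

Predictions apply the averaged model per pixel on the analysis scale
(square-root abundance, Simpson index, NMDS score); no back-transformation
is applied. Percent change `((Yₛ − Y_c)/Y_c) × 100` is used for abundance
and diversity; pixels with `|Y_c| < 1e-6` are masked (NaN), counted, and
excluded from summaries. Composition uses the plain difference `Yₛ − Y_c`
because axis scores cross zero. Landscape-level summaries cover all pixels
currently in grassland, wind-pollinated, or flowering-annual cover;
local-level summaries cover changed pixels dilated by one cell in the queen
(8-neighbor) sense (rook available by option). No clamping of predictions
to plausible metric ranges is applied.

## Conversion scenarios

Marginal land is the boolean soil mask (the analogue of land-capability
classes 3–8). Eligible cells for a conversion line are the marginal cells
of its source class. Exactly `round(area_ha / cell_area_ha)` cells are
drawn uniformly at random without replacement; any rounding residual is
logged. The annual scenario's corn/soy target split is quoted as 0.58/0.41,
which sums to 0.99; the shares are normalized to 0.5859/0.4141 before
apportionment so the requested total area is preserved exactly. Target
classes within a line are assigned by largest-remainder quota rather than
per-cell Bernoulli draws, so realized class shares are deterministic given
the cell count. The perennial scenario uses two fixed quota lines
(wind-pollinated → grassland, flowering annual → grassland) rather than a
split proportional to eligible areas. Cells, not contiguous patches, are
the conversion unit. Invariants asserted in tests: mass balance within one
cell area, containment of changes in the eligible set, bit-identical
marginal mask and unconverted classes, and uniformity of selection over
seeds (chi-square).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular region.

**Landscape.** A Gaussian random field smoothed to the `patchiness`
correlation length (default 600 m) is thresholded at its own empirical
quantiles, so realized class fractions over the nine grouped cover classes
match the target weights up to integer rounding while patches stay
contiguous; class order along the field is shuffled per seed. Default
weights describe an agriculture-dominated region (30% wind-pollinated
crops, 15% flowering annuals, 20% grassland, 20% forest, 15% minor
classes). The marginal mask is a second smoothed field thresholded
class-by-class (defaults: 55% of grassland, 25% of each annual-crop class),
giving patchy marginal soils with exact per-class coverage.

**Sites.** Rejection sampling with a minimum pairwise separation (3 km by
default, 20 sites) and an edge margin of one buffer radius. The pipeline
additionally stratifies sites across the quantiles of the grassland
proportion surface, emulating a field design in which sites are chosen
deliberately to span the gradient from annual-crop-dominated to
grassland-dominated landscapes; uniform placement remains the default of
the library function.

**Surveys.** The site-level truth operates on the analysis scale: the
square root of the expected per-visit wild-bee count is
`b + g·G + f·F + w·W + a·A + ε`, `ε ~ N(0, 0.25)`. Defaults for
`(b, g, f, w, a)` are `(0.95, 1.13, 2.84, −0.04, −0.50)`, i.e. positive
grassland and forest effects and weak negative crop effects, on a scale
that yields roughly 0–7 bees per hour. Per-visit totals are Poisson with
mean `μ²`; a second linear gradient (defaults
`(−0.33, −0.76, −0.42, 1.26, 0.62)`) shifts the softmax shares of a
12-species wild-bee pool through per-species loadings, so composition turns
along the same landscape gradient that drives abundance; diversity emerges
from those shares rather than being dialled directly (only two of the three
metrics have independent generative dials — the third is a consequence, as
it is in nature). Honeybees receive a fixed 25% share of total visitation
so the exclusion path is always exercised. Each site gets 3–5 visits. All
randomness derives from one integer seed split deterministically into named
substreams.

What the generator does *not* emulate: bee phenology and weather, observer
effects, patch-contiguity of conversions, geodesic distance, and the
long-tailed species-abundance distributions of real assemblages. Passing
tests therefore demonstrate correctness of the computational chain and
calibration of its inferential machinery under the assumed data-generating
process, not ecological validity for any real region.

## Problem sizes and tolerances

The default desk-scale configuration is a 400 × 400 grid of 100-m cells
(160,000 ha), 20 sites, 1,500-m windows, 6,000 ha converted per scenario —
large enough for non-trivial spatial structure while a full pipeline run
completes in a few seconds. Oracle-equivalence tests run to 1e-9 or better;
permutation calibrations use 199 permutations and 200 replicates; parameter
recovery uses 100 simulated 20-site datasets and requires ≥ 90% coverage of
the truth by full-model 95% confidence intervals. With 20 sites the
coefficient sampling error is substantial, and model-averaged contrasts can
change sign between seeds; this is a property of the design being emulated,
and the reported pseudo-R² and correlograms carry that uncertainty rather
than hiding it.

## Known limitations

- Unconditional standard errors of averaged coefficients are not computed
  (point estimates only).
- SIMPER is two-group only; PERMANOVA, rarefaction, and
  species-accumulation analyses are out of scope.
- Proportions are taken relative to all window cells, not renormalized to
  the mapped predictor classes.
- The spline-correlogram formulation of the residual check is replaced by
  the binned Moran's I described above.
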