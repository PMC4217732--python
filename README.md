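# beescape

Empirical land-cover models of wild-bee communities, and spatially explicit
projection of those models under contrasting bioenergy land-conversion
scenarios.

Agricultural policy that expands bioenergy production changes what grows
where: marginal grassland can be converted to annual row crops (corn,
soybean), or marginal annual cropland can be converted to perennial
grassland. Flower-visiting bees respond strongly to the composition of the
surrounding landscape, so these two policy directions pull pollinator
communities in opposite directions. `beescape` implements the full analysis
chain a landscape ecologist would use to quantify that trade-off, together
with a synthetic-data generator that stands in for field surveys and
land-cover/soil rasters, so every stage is testable end to end without
external downloads.

## What it computes

**Community metrics per site.** Abundance is `sqrt(mean per-visit count)`
with the managed honeybee *Apis mellifera* excluded; diversity is Simpson's
`1 − D` on pooled counts; composition is the first axis of a non-metric
multidimensional scaling (NMDS, minimizing Kruskal stress-1) of Bray–Curtis
dissimilarities computed on a season-mean, square-root, Wisconsin
double-standardized site × species matrix, with environmental vector
fitting and SIMPER used to interpret the axis.

**Land-cover models.** Each metric `Y_j` is modelled as a linear function of
the proportions of grassland `G`, forest `F`, wind-pollinated crops `W`,
and flowering annual crops `A` within a 1,500-m radius:

    Y_ij = b_j + g_j·G_i + f_j·F_i + w_j·W_i + a_j·A_i

All 2⁴ subsets of the four predictors are fitted by OLS, ranked by
bias-corrected AICc, and combined by Akaike-weighted model averaging with
shrinkage (a coefficient counts as zero in models that omit it). Residuals
are screened for spatial autocorrelation with a distance-binned Moran's I
correlogram and permutation envelope.

**Scenario projection.** Moving-window proportion surfaces turn the fitted
model into a per-pixel prediction map. Two conversion scenarios are applied
to marginal soils (the analogue of USDA land-capability classes 3–8): the
*annual* scenario converts marginal grassland to wind-pollinated and
flowering annual crops in a 0.58/0.41 corn/soy split, and the *perennial*
scenario converts marginal annual cropland to grassland. Changes are
summarized as percent change (abundance, diversity) or difference
(composition, which is an axis score and crosses zero), both over all
grassland-and-cropland pixels (landscape level) and over changed pixels
plus their immediate neighbors (local level).

## Worked example

```python
from beescape import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="out", seed=1))

print(f"NMDS stress (2-D): {report['stages']['community']['nmds_stress']:.3f}")
labels = {"grassland": "g", "forest": "f", "wind": "w", "flowering_annual": "a"}
for metric in ("abundance", "diversity", "composition"):
    m = report["stages"]["lmselect"][metric]
    coefs = " ".join(f"{labels[k]}={v:+.2f}" for k, v in m["coefficients"].items())
    print(f"{metric:12s} b={m['intercept']:+.2f} {coefs}  pseudo-R2={m['pseudo_r2']:.2f}")
for row in report["stages"]["project"]["summaries"]:
    if row["metric"] == "abundance":
        print(f"{row['scenario']:9s} {row['domain']:9s} "
              f"mean abundance change {row['mean']:+.1f}%")
```

prints

```
NMDS stress (2-D): 0.200
abundance    b=+0.18 g=+1.71 f=+3.87 w=+1.80 a=-1.39  pseudo-R2=0.77
diversity    b=+0.77 g=+0.01 f=+0.02 w=+0.03 a=-0.00  pseudo-R2=0.10
composition  b=+0.18 g=-0.64 f=-0.47 w=+0.15 a=+0.03  pseudo-R2=0.48
annual    landscape mean abundance change -2.8%
annual    local     mean abundance change -7.2%
perennial landscape mean abundance change +3.3%
perennial local     mean abundance change +7.9%
```

The ordination fits the 20 synthetic sites with a stress of 0.20; the
shrinkage-averaged abundance model puts large positive weight on forest and
grassland cover (pseudo-R² 0.77 against observations). Converting marginal
grassland to annual crops lowers predicted bee abundance (−2.8% averaged
over all grassland and cropland pixels; −7.2% next to the converted cells),
while converting marginal cropland to perennial grassland raises it (+3.3%
and +7.9%). Local means exceed landscape means in magnitude because the
landscape average dilutes sparse conversions — the mechanism the two
summary levels are designed to expose. Every number above is a draw from a
stochastic simulation: a different seed gives different fitted coefficients
(their sampling error at 20 sites is substantial, which the correlogram and
pseudo-R² report faithfully).

The same pipeline is scriptable from the shell:

```sh
beescape run-all --config run.yaml --outdir out --seed 42
beescape report --outdir out
```

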