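# phenouav

Plot-level plant height from UAV photogrammetry products, for wheat
breeding trials — with a fully synthetic trial generator so that every step
of the workflow can be tested against known truth.

## The problem

Manual plant height (PH) measurement in breeding nurseries is slow: a
ruler, four culms per plot, thousands of plots, four growth stages. A
drone carrying an RGB camera can cover the same trial in minutes; structure
-from-motion photogrammetry turns the images into a digital surface model
(DSM, top-of-canopy elevation) and a bare-soil flight into a digital
terrain model (DTM). Their difference is the crop surface model

    CSM = DSM − DTM,

a per-pixel canopy height raster. Aerial plant height for a plot
(`PHaerial`) is then a zonal statistic of the CSM pixels inside a buffered
plot polygon — by default the **mean of the pixels above the plot's 75th
percentile**, which tracks the canopy top while ignoring furrow and leaf-
flank pixels. Downstream, genotype means and heritabilities come from the
alpha-lattice mixed model

    y_ijk = μ + g_i + r_j + b_k(j) + ε_ijk

fitted by REML, with genotype fixed (BLUEs) or random (BLUPs, broad-sense
heritability H²g = σ²g / (σ²g + σ²ε/r) on an entry-mean basis), and a
pedigree model g ~ N(0, A σ²a) (A = twice the coefficient of parentage)
for narrow-sense heritability h²a under genotype × year interaction.

## What the package does

| module | role |
|---|---|
| `phenouav.simulate` | synthetic trials: terrain, alpha-lattice layout of two-bed plots, per-stage canopy DSMs, 4-culm ground measurements, GCP/checkpoint targets, pedigrees — all seeded, with exact truth tables |
| `phenouav.grids` | GeoTIFF elevation rasters, `compute_csm`, target-height sampling |
| `phenouav.extraction` | inward-buffered plot ROIs (default 0.10 m), center-in-polygon pixel extraction, percentile height statistics |
| `phenouav.georef` | checkpoint ΔX/ΔY and vertical-regression accuracy, GSD-multiple pass criteria (2×GSD horizontal, 3×GSD vertical) |
| `phenouav.genetics` | EM+scoring REML, BLUE/BLUP, H²g / h²a with delta-method SEs, tabular-method A-matrix, G×E fits, Spearman rank tests, multi-flight adjustment |
| `phenouav.agreement` | ground-vs-aerial regression, Bonferroni-screened studentized-residual outliers, cross-stage RMSE_dev |
| `phenouav.pipeline` / `phenouav.cli` | one-command reproducible runs with hashing manifest (`phpipe run`) |

## Worked example

```python
from phenouav.pipeline import run_pipeline
run_pipeline({"seed": 42, "simulation": {"n_genotypes": 50,
              "n_blocks_per_rep": 10, "cell_size_m": 0.02}}, "demo_out")
```

or, equivalently, `phpipe run --seed 42 --out demo_out` with the same
config in a YAML file. This simulates a 100-plot trial (50 lines × 2
replicates, 2 cm/pixel), writes the DTM, four per-stage DSMs and CSMs,
extracts aerial heights, and analyses them. From `demo_out/agreement.json`
(seed 42):

| stage | n | R² | raw RMSE (cm) | bias (cm) |
|---|---|---|---|---|
| E+40 | 100 | 0.84 | 2.49 | −0.74 |
| B    | 100 | 0.89 | 2.07 | −0.51 |
| A+7  | 100 | 0.87 | 2.21 | −0.61 |
| M    | 100 | 0.84 | 2.42 | −0.23 |

with pooled `rmse_dev = 2.31 cm`. R² is the squared correlation between
aerial and manual plot heights; the raw RMSE absorbs both scatter and the
small negative bias left by furrow pixels in the top-quartile statistic.
`genetics.json` reports entry-mean H²g of 0.89–0.93 (±0.02–0.04 SE) for
the simulated manual measurements and ≈1.0 for the aerial ones (the
generator places no plot-level error beyond the design effects, so aerial
repeatability is limited only by extraction noise), and aerial-vs-ground
BLUP rank correlations ρ ≈ 0.94 (p < 1e-22) at every stage.
`georef.json` shows the checkpoint accuracy flags; with the default
noiseless georeferencing the vertical regression gives R² = 1.0 and
RMSE = 0.15 cm, passing both the 2×GSD horizontal and 3×GSD vertical
criteria.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline on the demo-sized trial at the given seed (any
stage failure exits non-zero) and writes the acceptance JSON. The
scientific acceptance checks themselves — brute-force oracles for the CSM
and zonal extraction, closed-form REML equivalences, heritability and
interaction-variance recovery under the stated simulation world, outlier
calibration, and the zero-noise end-to-end identity — live in
`tests/test_acceptance.py` and run with the ordinary test suite.

See `docs/methods.md` for the models, numerical choices, and limitations.
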