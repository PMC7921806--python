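# Methods

This note documents the models and numerical conventions the package
implements, what the synthetic-data generator does and does not emulate,
and the design choices made where the workflow is genuinely underspecified.

## 1. Rasters and the crop surface model

Elevation rasters use one convention everywhere: pixel-is-area, north-up,
origin at the top-left corner, positive cell width `dx`, negative cell
height `dy`, half-open cells (a point on a shared edge belongs to the cell
to its lower-right). The same center rule drives zonal extraction and
target sampling, so the brute-force point-in-polygon oracle and the
vectorized implementation agree cell for cell.

`compute_csm` subtracts the bare-soil DTM from each per-flight DSM on the
DSM's grid. The default alignment policy is **exact** (identical
transforms and shapes required); `snap` (nearest-neighbor) and `bilinear`
resampling are explicit opt-ins, because silently resampling co-gridded
photogrammetry products hides georeferencing bugs. Nodata in either input
propagates to the output. Negative canopy heights are kept by default —
they diagnose DTM error — with zero-clamping opt-in.

Rasters are stored as single-band float64 GeoTIFF (nodata −9999). Double
precision is deliberate: the pipeline's zero-noise identity contract
(aerial height = truth to 1e-6 cm) is below float32 resolution at meter
scale.

## 2. Plot extraction

Plot polygons are shrunk inward by a mitred buffer, default **0.10 m**, to
exclude edge pixels contaminated by neighboring plots. Pixels whose
centers fall strictly inside the shrunken polygon form the sample; plots
with fewer than 30 valid pixels (a guard that only degenerate
configurations trigger) are flagged missing rather than estimated.

The default height statistic is `mean_above_p75`: the 75th percentile of
the sample is computed with the linear-interpolation definition (the
common default in scientific software; the convention is fixed here so
results are bit-stable), and the result is the mean of the values
**strictly greater** than that threshold. When no value strictly exceeds
the threshold — a constant sample, or exact ties at the top such as a
noise-free simulated canopy — the mean of the values *equal* to the
threshold is returned instead of a missing value. This tie rule reduces
to "return the constant" for constant samples and preserves the exact
zero-noise identity; falling back to the whole-sample mean would drag
furrow pixels into the estimate. Alternative statistics (`mean`,
`median`, `p90`, `p95`, `p99`) use the same percentile definition.
"Pixels above the top quartile" and "pixels greater than the 75th
percentile" are treated as synonyms.

## 3. The synthetic trial

The generator emulates a bed-planted spring-wheat breeding nursery
phenotyped by UAV. Defaults state the world once and are not tuned:

| parameter | default | meaning |
|---|---|---|
| design | 150 genotypes × 2 reps, 30 blocks/rep | resolvable alpha-lattice |
| plot | 2 beds × 0.8 m, 0.36 m inter-bed, 0.24 m inter-row, 4 m long | two-bed plot, width 1.96 m |
| cell size | 0.017 m | 1.7 cm/pixel ground sampling distance |
| stage means | 55 / 85 / 95 / 90 cm | E+40, booting, anthesis+7 d, maturity |
| σ genotype / rep / block | 5 / 1 / 2 cm | Normal effects, drawn once, shared across stages |
| culm SD | 4 cm | within-plot canopy texture scale and culm-to-culm spread |
| measurement SD | 1 cm | ruler/reading error on the 4-culm plot mean |
| surface noise SD | 1 cm | photogrammetric elevation noise |
| terrain relief | 10 cm | peak-to-peak smooth terrain amplitude |
| targets | 9 GCPs + 11 checkpoints, 0–120 cm pillar ladder | perimeter placement |

Terrain is Gaussian-filtered white noise (correlation length 2 m) rescaled
to the stated peak-to-peak amplitude — simple, seedable, no external noise
library. The alpha-lattice uses a cyclic generating permutation per
replicate with seeded block and within-block shuffles; resolvability (each
genotype exactly once per replicate, equal blocks nested in replicates) is
the invariant, design optimality is not claimed.

**Canopy-top truth convention.** A plot's true height `h` is the top of
its canopy. Within bed footprints the DSM is `h` plus culm-scale texture:
a smoothed Gaussian field (3 cm correlation length), standardized per plot
and shifted by `−κ·σ_culm` with `κ = φ(z₀.₇₅)/0.25 ≈ 1.2711` — the mean of
a standard normal above its own 75th percentile. By construction the
top-quartile mean of within-bed pixels equals `h`, which *defines* what
"canopy-top truth" means in this world; it also makes the plain pixel mean
biased low by ≈1.27 σ_culm, reproducing the qualitative reason the
top-quartile statistic is preferred over the mean. Outside the beds the
canopy tapers exponentially (e-folding 5 cm) into furrows and alleys, so
inter-bed furrow pixels sit far below 0.25 `h`. Manual measurements are
the mean of 4 culms ~ Normal(h, σ²_culm) plus one reading error. Wind is
an optional lateral Gaussian blur of the canopy field only; there is no
lodging geometry, no RGB rendering, and no structure-from-motion
emulation — the simulation starts at the elevation-product level.

What a green end-to-end test establishes: the extraction and statistics
recover the generator's truth under its stated noise. What it does not
establish: performance on real photogrammetry artifacts (doming, point
-cloud voids, mixed soil pixels inside beds, lodging). One visible
consequence: the truth model has no plot-level micro-environment term
beyond block effects, so simulated *aerial* repeatability is ≈1 by
construction, while simulated manual heights show realistic H² ≈ 0.85–0.95.

## 4. Georeferencing accuracy

Checkpoint deltas are measured − surveyed, in projected meters ("X/Y" are
axis labels only). SD uses the population convention (divide by n) so the
identity `RMSE² = mean² + SD²` is exact; sample SD is available via
`ddof=1`. Vertical accuracy regresses **measured on surveyed** target
heights (the direction is not universal in the field; it is fixed here and
reported with slope, intercept, R² and residual RMSE). Acceptance follows
the usual ground-sampling-distance multiples: SD ≤ 2×GSD per horizontal
axis and ≤ 3×GSD vertically, with the stricter 1×/2× thresholds reported
alongside. Target heights are sampled from the CSM as the **median** of
the pillar footprint, robust to cells straddling the pillar wall.

## 5. REML mixed models

`fit_reml` estimates variance components by REML in two phases:

1. **EM** on the mixed-model equations (coefficient matrix
   `W'W + diag(0, σ²ε/σ²_k)`), updates
   `σ²_k ← (û'û + σ²ε·tr(C^kk))/q_k`,
   `σ²ε ← (y'y − θ̂'W'y)/(n − p)`. Monotone in the restricted likelihood
   and cheap; runs until the components stabilize coarsely (≤60
   iterations).
2. **Fisher scoring** on (σ²₁…σ²_m, σ²ε) with the expected information
   `I_ij = ½ tr(P V_i P V_j)`, step-halved so the restricted likelihood
   never decreases; terminal convergence is quadratic and the final
   gradient norm is stored.

Variances are constrained nonnegative; a component collapsing below
1e-10 × var(y) is pinned to zero and flagged as a boundary estimate. A
residual variance at its floor (perfect-fit data) is likewise a flagged
boundary, not an error. A tiny ridge (1e-10 of the mean MME diagonal)
keeps the equations factorizable in that degenerate case. Convergence
tolerance 1e-8 relative; genuine interior non-convergence raises an error
carrying the iteration trace. The asymptotic covariance of the estimates
is the inverse expected information; heritability standard errors follow
by the delta method.

Fixed effects are GLS at the estimates; genotype BLUEs are reported as the
estimable contrast *intercept + genotype effect* (reference-level coding;
equivalent to sum-to-zero up to the common intercept), with other fixed
factors averaged at their observed distribution. BLUPs come from
`û = σ²_g Z' P y`. Correlated genotype effects `g ~ N(0, A σ²a)` are
reduced to independent effects by post-multiplying the genotype design
with a Cholesky factor of A (ridge 1e-8 if the factorization fails);
predictions are mapped back through the same factor.

**Heritability bases.** "Total variance" is ambiguous; both conventions
are implemented and reported side by side. Entry-mean (default, the
plant-breeding "repeatability" of a genotype mean):
`H² = σ²g / (σ²g + σ²ε/r)`; plot basis divides by the sum of all
components. For the G×E model, entry-mean
`h²a = σ²a / (σ²a + σ²ge/y + σ²ε/(y·r))`. Any stage/cycle row filter
(e.g. dropping a poorly measured stage from the G×E run) is configuration,
not code.

The A-matrix uses the tabular method: founders `A_ii = 1`; offspring k of
(s, d): `A_ki = ½(A_si + A_di)`, `A_kk = 1 + ½A_sd`; an unknown parent
contributes as an unrelated non-inbred founder.

Multi-flight adjustment fits the additive two-way fixed-effects model
(plot + flight) by least squares; the adjusted plot value is the plot
effect plus the average flight effect, so a single flight passes through
unchanged.

Spearman ρ is the Pearson correlation of average ranks, tested with
`t = ρ√((n−2)/(1−ρ²))` on n−2 df. The default confidence interval is
Fisher-z; the linear half-width `1.96(1−ρ)/(n−2)` occasionally printed
with prediction-accuracy figures is kept verbatim as an option despite its
odd dimensions.

## 6. Agreement and outlier screening

Outliers are screened by regressing **ground on aerial** (the manual
measurement carries the gross errors; the direction is a flag), computing
externally studentized residuals from the hat matrix, and flagging pairs
whose two-sided t probability (n−3 df) survives the Bonferroni correction
`p·n < α` with α = 0.01. Flagged pairs are removed from both vectors.

Two RMSEs are reported as distinct named quantities, because conflating
them is a recurring source of confusion: the **regression RMSE** (scatter
about the fitted ground–aerial line, small when the relationship is tight
even under bias) and the **raw-difference RMSE**
`√mean((aerial−ground)²)`, which absorbs bias; `rmse_dev` pools the raw
squared differences over all plot × stage pairs.

## 7. Pipeline

`phpipe run` executes simulate → csm → extract → validate-georef →
genetics → agreement from one YAML config (unknown keys rejected, defaults
filled: buffer 0.1 m, statistic `mean_above_p75`, α 0.01, entry-mean H²).
Stage caching is by content hash of inputs and config, not timestamps.
All randomness derives from a single root seed split into fixed per-stage
streams, so each stage is independently reproducible and identical seeds
give byte-identical tables. A failing stage aborts the run with its name;
its outputs keep a `.partial` suffix.

## 8. Known limitations

- No spatial-correlation residual models, multi-trait models, or genomic
  relationship matrices.
- No point-cloud processing or DTM-from-vegetation classification; the
  bare-soil DTM is an input.
- The within-plot texture model is a calibration device for testing the
  percentile statistic, not a claim about real wheat canopies.
- EM+scoring REML is designed for trial-sized problems (hundreds to a few
  thousand plots); it builds dense n×n matrices for the likelihood audit
  and information matrix.
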