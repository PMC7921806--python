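"""Synthetic wheat-trial generator with known ground truth.

Emulates a bed-planted spring-wheat breeding trial phenotyped by UAV: an
alpha-lattice layout of two-bed plots, a smooth bare-soil terrain (the DTM
flight), per-growth-stage canopy surfaces (the DSM flights), 4-culm manual
height measurements, surveyed square ground targets, and a pedigree.  Every
output is a pure, seeded function of the configuration, so the downstream
extraction and genetics stages can be tested against exact truth.

The simulation starts at the elevation-product level (DTM/DSM rasters); no
imagery or structure-from-motion step is emulated.  Surface imperfection is
reduced to three knobs: culm-scale canopy texture, Gaussian elevation noise,
and an optional lateral blur standing in for plant movement in wind.

Canopy-top truth convention: each plot's true height ``h`` is defined as the
top of its canopy.  The within-bed surface texture is a standardized smooth
random field shifted down by ``kappa = phi(z_.75)/0.25 ~ 1.271`` (the mean of
a standard normal above its 75th percentile), so by construction the mean of
within-bed pixels above their 75th percentile equals ``h``.  Manual culm
draws are centered on ``h`` likewise.  See docs/methods.md.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import Polygon, box

from .grids import ElevationGrid, GridTransform
from .trial import FieldLayout, GroundTarget, Pedigree, Plot, HEIGHT_COLUMNS

__all__ = [
    "SimulationConfig",
    "TrueGenetics",
    "simulate_terrain",
    "simulate_layout",
    "simulate_genotype_truth",
    "simulate_canopy_surface",
    "simulate_ground_measurements",
    "place_targets",
    "stamp_targets",
    "measure_targets",
    "simulate_pedigree",
]

#: mean of a standard normal above its own 75th percentile
KAPPA_P75 = float(stats.norm.pdf(stats.norm.ppf(0.75)) / 0.25)

#: e-folding length of the canopy taper into furrows/alleys (meters)
TAPER_SCALE_M = 0.05

#: correlation length of the culm-scale canopy texture (meters)
CULM_TEXTURE_SCALE_M = 0.03

#: correlation length of the terrain relief (meters)
TERRAIN_SCALE_M = 2.0

MAX_CELLS = 10**8

# fixed sub-stream ids so each simulate_* draws from an independent stream
_STREAM_TERRAIN = 1
_STREAM_LAYOUT = 2
_STREAM_TRUTH = 3
_STREAM_SURFACE = 4
_STREAM_GROUND = 5
_STREAM_PEDIGREE = 6
_STREAM_TARGETS = 7

#: growth stages in chronological order (days after emergence 40, booting,
#: anthesis + 7 days, physiological maturity)
STAGES = ("E+40", "B", "A+7", "M")


class ResourceError(RuntimeError):
    """Requested raster exceeds the configured cell budget."""


class LayoutError(ValueError):
    """Plot grid does not tile the requested extent."""


class PlacementError(ValueError):
    """A ground target would overlap a plot polygon."""


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, extra]))


def _stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        # stable across processes (builtin hash is salted per run)
        return 1000 + (zlib.crc32(stage.encode()) % 1000)


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of one simulated trial.

    Defaults follow the largest of the real trials this generator emulates:
    150 lines in an alpha-lattice with 2 replicates and 30 incomplete blocks
    per replicate, two-bed plots (beds 0.8 m wide, 0.24 m inter-row and
    0.36 m inter-bed spacing), 4 m plot length, 1.7 cm/pixel ground sampling
    distance, and heights measured on 4 culms per plot.
    """

    seed: int = 0
    extent_m: tuple[float, float] | None = None  # None: derived from the layout
    cell_size_m: float = 0.017
    n_genotypes: int = 150
    n_replicates: int = 2
    n_blocks_per_rep: int = 30
    plot_length_m: float = 4.0
    bed_width_m: float = 0.8
    inter_row_m: float = 0.24
    inter_bed_m: float = 0.36
    alley_m: float = 0.5
    margin_m: float = 1.5
    stage_means_cm: dict[str, float] = field(
        default_factory=lambda: {"E+40": 55.0, "B": 85.0, "A+7": 95.0, "M": 90.0}
    )
    genotype_sd_cm: float = 5.0
    replicate_sd_cm: float = 1.0
    block_sd_cm: float = 2.0
    culm_sd_cm: float = 4.0
    n_culms: int = 4
    measurement_sd_cm: float = 1.0
    surface_noise_sd_cm: float = 1.0
    terrain_relief_cm: float = 10.0
    base_elevation_m: float = 100.0
    wind_smear_px: int = 0
    n_gcps: int = 9
    n_checkpoints: int = 11
    target_side_m: float = 0.3
    target_height_ladder_m: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9, 1.2)
    georef_bias_m: tuple[float, float] = (0.0, 0.0)
    georef_noise_sd_m: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "genotype_sd_cm",
            "replicate_sd_cm",
            "block_sd_cm",
            "culm_sd_cm",
            "measurement_sd_cm",
            "surface_noise_sd_cm",
            "georef_noise_sd_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        if self.n_genotypes % self.n_blocks_per_rep != 0:
            raise ValueError(
                f"n_genotypes={self.n_genotypes} not divisible into "
                f"{self.n_blocks_per_rep} equal blocks"
            )

    # --- derived geometry ----------------------------------------------------

    @property
    def plot_width_m(self) -> float:
        """Two beds plus the inter-bed furrow."""
        return 2 * self.bed_width_m + self.inter_bed_m

    @property
    def block_size(self) -> int:
        return self.n_genotypes // self.n_blocks_per_rep

    def grid_columns(self) -> int:
        total = self.n_genotypes * self.n_replicates
        px = self.plot_width_m + self.alley_m
        py = self.plot_length_m + self.alley_m
        if self.extent_m is not None:
            ncols = int((self.extent_m[0] - 2 * self.margin_m + self.alley_m) // px)
            if ncols < 1:
                raise LayoutError("extent too narrow for a single plot column")
            return ncols
        return max(1, round(math.sqrt(total * py / px)))

    def field_extent(self) -> tuple[float, float]:
        if self.extent_m is not None:
            return self.extent_m
        total = self.n_genotypes * self.n_replicates
        ncols = self.grid_columns()
        nrows = math.ceil(total / ncols)
        px = self.plot_width_m + self.alley_m
        py = self.plot_length_m + self.alley_m
        width = ncols * px - self.alley_m + 2 * self.margin_m
        height = nrows * py - self.alley_m + 2 * self.margin_m
        return (width, height)

    def raster_shape(self) -> tuple[int, int]:
        w, h = self.field_extent()
        ncol = int(round(w / self.cell_size_m))
        nrow = int(round(h / self.cell_size_m))
        if nrow * ncol > MAX_CELLS:
            raise ResourceError(
                f"raster {nrow}x{ncol} exceeds {MAX_CELLS} cells; coarsen cell_size_m"
            )
        return nrow, ncol

    def transform(self) -> GridTransform:
        _, h = self.field_extent()
        return GridTransform(x0=0.0, y0=h, dx=self.cell_size_m, dy=-self.cell_size_m)


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A desk-sized trial (50 lines, 2 reps, 10 blocks, 2 cm GSD) with the
    default noise levels; handy for examples and end-to-end tests."""
    kwargs = dict(n_genotypes=50, n_blocks_per_rep=10, cell_size_m=0.02)
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


@dataclass
class TrueGenetics:
    """Ground-truth effects and per-plot canopy-top heights (cm).

    ``truth`` has one row per plot x stage with the pre-noise height
    ``true_cm = stage mean + genotype + replicate + block effect``.
    """

    genotype_effects_cm: dict[str, float]
    replicate_effects_cm: dict[int, float]
    block_effects_cm: dict[tuple[int, int], float]
    stage_means_cm: dict[str, float]
    truth: pd.DataFrame  # plot_id, genotype, rep, block, stage, true_cm

    def plot_height_m(self, plot_id: str, stage: str) -> float:
        sel = self.truth[(self.truth.plot_id == plot_id) & (self.truth.stage == stage)]
        if sel.empty:
            raise KeyError(f"no truth for plot {plot_id!r} at stage {stage!r}")
        return float(sel.true_cm.iloc[0]) / 100.0


# ---------------------------------------------------------------------------
# terrain


def simulate_terrain(config: SimulationConfig) -> ElevationGrid:
    """Smooth bare-soil terrain: Gaussian-filtered white noise rescaled to
    peak-to-peak amplitude ``terrain_relief_cm``."""
    nrow, ncol = config.raster_shape()
    rng = _rng(config.seed, _STREAM_TERRAIN)
    z = np.full((nrow, ncol), config.base_elevation_m, dtype=np.float64)
    if config.terrain_relief_cm > 0:
        noise = rng.standard_normal((nrow, ncol))
        sigma_px = max(TERRAIN_SCALE_M / config.cell_size_m, 1.0)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        span = smooth.max() - smooth.min()
        if span > 0:
            smooth = (smooth - smooth.min()) / span  # [0, 1]
            z += (smooth - 0.5) * (config.terrain_relief_cm / 100.0)
    return ElevationGrid(z, config.transform(), crs_label="local-meters")


# ---------------------------------------------------------------------------
# layout


def _coprime_multiplier(j: int, v: int) -> int:
    a = 2 * j + 1
    while math.gcd(a, v) != 1:
        a += 1
    return a


def simulate_layout(config: SimulationConfig) -> FieldLayout:
    """Resolvable alpha-lattice-style layout of two-bed plot polygons.

    Each genotype appears exactly once per replicate; within a replicate the
    genotypes are partitioned into ``n_blocks_per_rep`` equal incomplete
    blocks via a cyclic generating permutation (resolvability, not design
    optimality, is the contract).  Block and within-block order are
    randomized per replicate from the seed.
    """
    v = config.n_genotypes
    k = config.block_size
    s = config.n_blocks_per_rep
    rng = _rng(config.seed, _STREAM_LAYOUT)
    genotypes = [f"G{i + 1:03d}" for i in range(v)]

    ncols = config.grid_columns()
    px = config.plot_width_m + config.alley_m
    py = config.plot_length_m + config.alley_m
    width, height = config.field_extent()
    total = v * config.n_replicates
    nrows_grid = math.ceil(total / ncols)
    need_w = ncols * px - config.alley_m + 2 * config.margin_m
    need_h = nrows_grid * py - config.alley_m + 2 * config.margin_m
    if need_w > width + 1e-9 or need_h > height + 1e-9:
        raise LayoutError(
            f"{total} plots need {need_w:.1f}x{need_h:.1f} m, extent is {width:.1f}x{height:.1f} m"
        )

    plots: list[Plot] = []
    idx = 0
    for rep in range(1, config.n_replicates + 1):
        a = _coprime_multiplier(rep - 1, v)
        blocks: dict[int, list[str]] = {b: [] for b in range(s)}
        for g in range(v):
            blocks[((a * g + rep - 1) % v) // k].append(genotypes[g])
        order = list(range(s))
        rng.shuffle(order)
        for b in order:
            members = list(blocks[b])
            rng.shuffle(members)
            for geno in members:
                col = idx % ncols
                row = idx // ncols
                x = config.margin_m + col * px
                y_top = height - config.margin_m - row * py
                poly = box(x, y_top - config.plot_length_m, x + config.plot_width_m, y_top)
                plots.append(
                    Plot(
                        plot_id=f"P{idx + 1:04d}",
                        genotype=geno,
                        rep=rep,
                        block=b + 1,
                        polygon=poly,
                    )
                )
                idx += 1
    return FieldLayout(
        plots=plots,
        bed_width_m=config.bed_width_m,
        inter_bed_m=config.inter_bed_m,
        crs_label="local-meters",
    )


# ---------------------------------------------------------------------------
# genetic truth


def simulate_genotype_truth(config: SimulationConfig, layout: FieldLayout) -> TrueGenetics:
    """Draw genotype/replicate/block effects and tabulate per-plot truth.

    Effects are drawn once and shared across growth stages (the height
    ranking of lines is stable through the season); stage means shift the
    whole trial.  All draws are Normal with the configured SDs.
    """
    rng = _rng(config.seed, _STREAM_TRUTH)
    genotypes = sorted({p.genotype for p in layout})
    g_eff = {
        g: float(e)
        for g, e in zip(genotypes, rng.normal(0.0, config.genotype_sd_cm, len(genotypes)))
    }
    reps = sorted({p.rep for p in layout})
    r_eff = {r: float(e) for r, e in zip(reps, rng.normal(0.0, config.replicate_sd_cm, len(reps)))}
    rep_blocks = sorted({(p.rep, p.block) for p in layout})
    b_eff = {
        rb: float(e)
        for rb, e in zip(rep_blocks, rng.normal(0.0, config.block_sd_cm, len(rep_blocks)))
    }
    rows = []
    for stage, mu in config.stage_means_cm.items():
        for p in layout:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "genotype": p.genotype,
                    "rep": p.rep,
                    "block": p.block,
                    "stage": stage,
                    "true_cm": mu + g_eff[p.genotype] + r_eff[p.rep] + b_eff[(p.rep, p.block)],
                }
            )
    return TrueGenetics(
        genotype_effects_cm=g_eff,
        replicate_effects_cm=r_eff,
        block_effects_cm=b_eff,
        stage_means_cm=dict(config.stage_means_cm),
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# canopy surface (per-flight DSM)


def simulate_canopy_surface(
    terrain: ElevationGrid,
    layout: FieldLayout,
    truth: TrueGenetics,
    config: SimulationConfig,
    stage: str,
) -> ElevationGrid:
    """DSM for one growth stage: terrain + canopy relief + elevation noise.

    Within each plot's two bed footprints the surface sits at the plot's
    true height plus culm-scale texture; it tapers exponentially
    (e-folding 5 cm) into the inter-bed furrow and the alleys.  Gaussian
    elevation noise of SD ``surface_noise_sd_cm`` is added everywhere; an
    optional lateral blur emulates plant movement during image capture.
    """
    if stage not in truth.stage_means_cm:
        raise KeyError(f"stage {stage!r} missing from truth")
    t = terrain.transform
    cell = t.dx
    canopy = np.zeros(terrain.shape, dtype=np.float64)
    rng = _rng(config.seed, _STREAM_SURFACE, _stage_index(stage))
    truth_stage = truth.truth[truth.truth.stage == stage].set_index("plot_id")

    nrow, ncol = terrain.shape
    for plot in layout:
        h = float(truth_stage.loc[plot.plot_id, "true_cm"]) / 100.0
        if h <= 0:
            continue
        beds = layout.bed_footprints(plot)
        xmin, ymin, xmax, ymax = plot.polygon.bounds
        pad = 5 * TAPER_SCALE_M
        r0, c0 = t.world_to_cell(xmin - pad, ymax + pad)
        r1, c1 = t.world_to_cell(xmax + pad, ymin - pad)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, nrow - 1), min(c1, ncol - 1)
        xs = t.x0 + (np.arange(c0, c1 + 1) + 0.5) * t.dx
        ys = t.y0 + (np.arange(r0, r1 + 1) + 0.5) * t.dy
        X, Y = np.meshgrid(xs, ys)
        # distance from each cell center to the nearest bed rectangle
        dist = np.full(X.shape, np.inf)
        inside_bed = np.zeros(X.shape, dtype=bool)
        for bx0, by0, bx1, by1 in beds:
            ddx = np.maximum(np.maximum(bx0 - X, X - bx1), 0.0)
            ddy = np.maximum(np.maximum(by0 - Y, Y - by1), 0.0)
            d = np.hypot(ddx, ddy)
            dist = np.minimum(dist, d)
            inside_bed |= (X >= bx0) & (X < bx1) & (Y > by0) & (Y <= by1)
        factor = np.exp(-dist / TAPER_SCALE_M)
        factor[factor < 0.02] = 0.0
        factor[inside_bed] = 1.0
        local = h * factor
        if config.culm_sd_cm > 0 and inside_bed.any():
            noise = rng.standard_normal(X.shape)
            sigma_px = max(CULM_TEXTURE_SCALE_M / cell, 0.5)
            tex = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
            bed_vals = tex[inside_bed]
            sd = bed_vals.std()
            if sd > 0:
                u = (tex - bed_vals.mean()) / sd
                local = local + np.where(
                    inside_bed, (config.culm_sd_cm / 100.0) * (u - KAPPA_P75), 0.0
                )
        np.maximum(local, 0.0, out=local)
        block = canopy[r0 : r1 + 1, c0 : c1 + 1]
        np.maximum(block, local, out=block)

    if config.wind_smear_px > 0:
        canopy = ndimage.gaussian_filter(canopy, sigma=config.wind_smear_px, mode="reflect")
    dsm = terrain.values.astype(np.float64) + canopy
    if config.surface_noise_sd_cm > 0:
        dsm += rng.normal(0.0, config.surface_noise_sd_cm / 100.0, size=dsm.shape)
    return ElevationGrid(dsm, t, nodata=terrain.nodata, crs_label=terrain.crs_label)


# ---------------------------------------------------------------------------
# ground measurements


def simulate_ground_measurements(
    layout: FieldLayout,
    truth: TrueGenetics,
    config: SimulationConfig,
    stage: str,
) -> pd.DataFrame:
    """Manual ruler protocol: plot height = mean of ``n_culms`` random culms.

    Each culm is Normal(true height, culm_sd^2); a single ruler/reading
    error Normal(0, measurement_sd^2) is added to the plot mean.
    """
    if stage not in truth.stage_means_cm:
        raise KeyError(f"stage {stage!r} missing from truth")
    rng = _rng(config.seed, _STREAM_GROUND, _stage_index(stage))
    truth_stage = truth.truth[truth.truth.stage == stage].set_index("plot_id")
    rows = []
    for plot in layout:
        h = float(truth_stage.loc[plot.plot_id, "true_cm"])
        culms = rng.normal(h, config.culm_sd_cm, size=config.n_culms)
        ph = culms.mean() + rng.normal(0.0, config.measurement_sd_cm)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "genotype": plot.genotype,
                "rep": plot.rep,
                "block": plot.block,
                "stage": stage,
                "platform": "ground",
                "ph_cm": float(ph),
            }
        )
    return pd.DataFrame(rows, columns=HEIGHT_COLUMNS)


# ---------------------------------------------------------------------------
# ground targets


def place_targets(config: SimulationConfig, layout: FieldLayout) -> list[GroundTarget]:
    """Distribute square pillar targets in the field margins.

    Default 9 bundle-adjustment GCPs and 11 independent checkpoints, with
    pillar heights cycling a 0–120 cm ladder.  Raises
    :class:`PlacementError` if a target footprint would overlap a plot.
    """
    width, height = config.field_extent()
    n_total = config.n_gcps + config.n_checkpoints
    m = config.margin_m / 2.0
    # perimeter positions, clockwise from the lower-left corner
    perim = 2 * (width - 2 * m) + 2 * (height - 2 * m)
    targets: list[GroundTarget] = []
    ladder = config.target_height_ladder_m
    for i in range(n_total):
        d = perim * i / n_total
        w, h2 = width - 2 * m, height - 2 * m
        if d < w:
            x, y = m + d, m
        elif d < w + h2:
            x, y = width - m, m + (d - w)
        elif d < 2 * w + h2:
            x, y = width - m - (d - w - h2), height - m
        else:
            x, y = m, height - m - (d - 2 * w - h2)
        role = "gcp" if i < config.n_gcps else "checkpoint"
        tgt = GroundTarget(
            target_id=f"{'GCP' if role == 'gcp' else 'CP'}{i + 1:02d}",
            role=role,
            surveyed_x=float(x),
            surveyed_y=float(y),
            surveyed_z=float(ladder[i % len(ladder)]),
            side_m=config.target_side_m,
        )
        half = tgt.side_m / 2.0
        foot = box(x - half, y - half, x + half, y + half)
        for plot in layout:
            if foot.intersects(plot.polygon):
                raise PlacementError(f"target {tgt.target_id} overlaps plot {plot.plot_id}")
        targets.append(tgt)
    return targets


def stamp_targets(
    dsm: ElevationGrid,
    terrain: ElevationGrid,
    targets: Iterable[GroundTarget],
    noise_sd_m: float = 0.0,
    seed: int = 0,
) -> ElevationGrid:
    """Return a copy of the DSM with pillar tops stamped at terrain + height.

    ``noise_sd_m`` re-applies the surface elevation noise to the stamped
    pixels (stamping happens after the canopy noise draw, so pillars would
    otherwise be unrealistically clean).
    """
    out = dsm.values.copy()
    t = dsm.transform
    rng = _rng(seed, _STREAM_TARGETS, 1)
    for tgt in targets:
        half = tgt.side_m / 2.0
        r0, c0 = t.world_to_cell(tgt.surveyed_x - half, tgt.surveyed_y + half)
        r1, c1 = t.world_to_cell(tgt.surveyed_x + half, tgt.surveyed_y - half)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1 = min(r1, dsm.shape[0] - 1)
        c1 = min(c1, dsm.shape[1] - 1)
        if r1 < r0 or c1 < c0:
            continue
        patch = terrain.values[r0 : r1 + 1, c0 : c1 + 1] + tgt.surveyed_z
        if noise_sd_m > 0:
            patch = patch + rng.normal(0.0, noise_sd_m, size=patch.shape)
        out[r0 : r1 + 1, c0 : c1 + 1] = patch
    return ElevationGrid(out, t, nodata=dsm.nodata, crs_label=dsm.crs_label)


def measure_targets(
    targets: list[GroundTarget],
    config: SimulationConfig,
    csm: ElevationGrid | None = None,
) -> list[GroundTarget]:
    """Fill measured XY (orthomosaic reading: surveyed + bias + noise) and,
    if a CSM is given, measured Z from the pillar footprint median."""
    from .grids import sample_target_height

    rng = _rng(config.seed, _STREAM_TARGETS)
    bx, by = config.georef_bias_m
    out = []
    for tgt in targets:
        mx = tgt.surveyed_x + bx + rng.normal(0.0, config.georef_noise_sd_m)
        my = tgt.surveyed_y + by + rng.normal(0.0, config.georef_noise_sd_m)
        mz = float("nan")
        if csm is not None:
            samp = sample_target_height(
                csm, tgt.surveyed_x, tgt.surveyed_y, footprint_m=tgt.side_m * 0.6
            )
            mz = samp.height_m
        out.append(
            replace(tgt, measured_x=float(mx), measured_y=float(my), measured_z=float(mz))
        )
    return out


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(n_founders: int, n_crosses: int, seed: int = 0) -> Pedigree:
    """Random crossing scheme: unrelated non-inbred founders, each cross
    sampling two distinct parents from all prior individuals."""
    if n_founders < 1:
        raise ValueError("need at least one founder")
    if n_crosses > 0 and n_founders < 2:
        raise ValueError("crosses need at least two founders")
    rng = _rng(seed, _STREAM_PEDIGREE)
    ped = Pedigree()
    ids = []
    for i in range(n_founders):
        name = f"F{i + 1:03d}"
        ped.add(name)
        ids.append(name)
    for i in range(n_crosses):
        p1, p2 = rng.choice(len(ids), size=2, replace=False)
        name = f"X{i + 1:03d}"
        ped.add(name, ids[p1], ids[p2])
        ids.append(name)
    return ped
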