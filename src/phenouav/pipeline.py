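"""End-to-end pipeline: simulate -> CSM -> extract -> georef -> genetics -> agreement.

One YAML config drives the whole run; every stage writes plain files
(GeoTIFF, GeoJSON, CSV, JSON) into the output directory, and a manifest
records the config snapshot, seed, and a content hash of each input and
output.  A stage whose config and inputs hash identically to the previous
manifest is skipped; deterministic stages therefore reproduce byte-identical
outputs under the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement, flag_outliers, rmse_dev
from .extraction import DEFAULT_BUFFER_M, DEFAULT_MIN_PIXELS, STATISTICS, build_rois, extract_trial
from .genetics import (
    blue_spec,
    blup_spec,
    broad_sense_heritability,
    compute_blues,
    compute_blups,
    fit_reml,
    spearman_with_test,
)
from .georef import check_accuracy_criteria, horizontal_deltas, vertical_accuracy
from .grids import GridAlignment, compute_csm, read_elevation_raster, write_elevation_raster
from .simulate import (
    SimulationConfig,
    measure_targets,
    place_targets,
    simulate_canopy_surface,
    simulate_genotype_truth,
    simulate_ground_measurements,
    simulate_layout,
    simulate_pedigree,
    simulate_terrain,
    stamp_targets,
)
from .trial import (
    read_layout_geojson,
    read_targets_csv,
    write_layout_geojson,
    write_pedigree_csv,
    write_targets_csv,
)

log = logging.getLogger("phenouav")

__all__ = ["validate_config", "run_pipeline", "PipelineError", "DEFAULT_CONFIG"]

STAGE_ORDER = ["simulate", "csm", "extract", "validate-georef", "genetics", "agreement"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "simulation": {},  # SimulationConfig field overrides
    "extraction": {
        "buffer_m": DEFAULT_BUFFER_M,
        "statistic": "mean_above_p75",
        "min_pixels": DEFAULT_MIN_PIXELS,
    },
    "georef": {"gsd_m": None},  # None: use the simulation cell size
    "genetics": {"h2_basis": "entry_mean"},
    "agreement": {"alpha": 0.01},
    "pedigree": {"n_founders": 20, "n_crosses": 0},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


def _merge_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and key != "simulation":
                if not isinstance(uval, dict):
                    raise ConfigError(f"{path}{key}: expected a mapping")
                out[key] = _merge_defaults(uval, dval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = json.loads(json.dumps(dval)) if isinstance(dval, (dict, list)) else dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(f'{path}{k}' for k in unknown)}")
    return out


def validate_config(config: str | os.PathLike | dict | None) -> dict:
    """Normalize a YAML config file (or dict): fill defaults, reject unknown
    keys, and range-check the values the pipeline depends on."""
    if config is None:
        user = {}
    elif isinstance(config, dict):
        user = config
    else:
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge_defaults(user, DEFAULT_CONFIG)
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(cfg["simulation"]) - sim_fields
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    ex = cfg["extraction"]
    if ex["buffer_m"] < 0:
        raise ConfigError("extraction.buffer_m must be >= 0")
    if ex["statistic"] not in STATISTICS:
        raise ConfigError(f"extraction.statistic must be one of {STATISTICS}")
    if not 0 < cfg["agreement"]["alpha"] < 1:
        raise ConfigError("agreement.alpha must be in (0, 1)")
    if cfg["genetics"]["h2_basis"] not in ("entry_mean", "plot"):
        raise ConfigError("genetics.h2_basis must be entry_mean or plot")
    unknown_stages = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Runner:
    def __init__(self, cfg: dict, out: Path, seed: int | None):
        self.cfg = cfg
        self.out = out
        self.seed = int(cfg["seed"] if seed is None else seed)
        self.manifest: dict = {
            "version": __version__,
            "seed": self.seed,
            "config": cfg,
            "stages": {},
        }
        self.previous: dict = {}
        mpath = out / "manifest.json"
        if mpath.exists():
            try:
                self.previous = json.loads(mpath.read_text()).get("stages", {})
            except (json.JSONDecodeError, OSError):
                self.previous = {}
        sim_kwargs = dict(cfg["simulation"])
        sim_kwargs["seed"] = self.seed
        if "extent_m" in sim_kwargs and sim_kwargs["extent_m"] is not None:
            sim_kwargs["extent_m"] = tuple(sim_kwargs["extent_m"])
        self.sim = SimulationConfig(**sim_kwargs)
        self.stages_done: list[str] = []

    # -- bookkeeping ---------------------------------------------------------

    def _stage_key(self, stage: str, inputs: list[Path]) -> dict:
        return {
            "config": _config_hash(
                {"seed": self.seed, "cfg": self.cfg, "stage": stage}
            ),
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        }

    def _can_skip(self, stage: str, key: dict, outputs: list[Path]) -> bool:
        prev = self.previous.get(stage)
        if not prev:
            return False
        if prev.get("config") != key["config"] or prev.get("inputs") != key["inputs"]:
            return False
        for p in outputs:
            if not p.exists() or _sha256(p) != prev.get("outputs", {}).get(str(p)):
                return False
        return True

    def _record(self, stage: str, key: dict, outputs: list[Path], skipped: bool) -> None:
        self.manifest["stages"][stage] = {
            **key,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "skipped": skipped,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def run_stage(self, stage: str, inputs: list[Path], outputs: list[Path], fn) -> None:
        key = self._stage_key(stage, inputs)
        if self._can_skip(stage, key, outputs):
            log.info("stage %s: inputs unchanged, skipped", stage)
            self._record(stage, key, outputs, skipped=True)
            return
        log.info("stage %s: running", stage)
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            for p in outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(stage, str(exc)) from exc
        log.info("stage %s: done in %.1f s", stage, time.time() - t0)
        self._record(stage, key, outputs, skipped=False)
        self.stages_done.append(stage)

    # -- paths ----------------------------------------------------------------

    def p(self, name: str) -> Path:
        return self.out / name

    @property
    def stage_names(self) -> list[str]:
        return sorted(self.sim.stage_means_cm)

    # -- stages ----------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.sim
        terrain = simulate_terrain(cfg)
        layout = simulate_layout(cfg)
        truth = simulate_genotype_truth(cfg, layout)
        targets = place_targets(cfg, layout)
        write_elevation_raster(self.p("dtm.tif"), terrain)
        write_layout_geojson(self.p("layout.geojson"), layout)
        truth.truth.to_csv(self.p("truth.csv"), index=False)
        grounds = []
        for stage in self.stage_names:
            dsm = simulate_canopy_surface(terrain, layout, truth, cfg, stage)
            dsm = stamp_targets(
                dsm, terrain, targets,
                noise_sd_m=cfg.surface_noise_sd_cm / 100.0, seed=cfg.seed,
            )
            write_elevation_raster(self.p(f"dsm_{_slug(stage)}.tif"), dsm)
            grounds.append(simulate_ground_measurements(layout, truth, cfg, stage))
        pd.concat(grounds, ignore_index=True).to_csv(self.p("heights_ground.csv"), index=False)
        measured = measure_targets(targets, cfg)
        write_targets_csv(self.p("targets.csv"), measured)
        ped_cfg = self.cfg["pedigree"]
        ped = simulate_pedigree(ped_cfg["n_founders"], ped_cfg["n_crosses"], seed=self.seed)
        write_pedigree_csv(self.p("pedigree.csv"), ped)

    def stage_csm(self) -> None:
        dtm = read_elevation_raster(self.p("dtm.tif"))
        for stage in self.stage_names:
            dsm = read_elevation_raster(self.p(f"dsm_{_slug(stage)}.tif"))
            csm = compute_csm(dsm, dtm, GridAlignment("exact"))
            write_elevation_raster(self.p(f"csm_{_slug(stage)}.tif"), csm)

    def stage_extract(self) -> None:
        layout = read_layout_geojson(self.p("layout.geojson"))
        ex = self.cfg["extraction"]
        rois = build_rois(layout, buffer_m=ex["buffer_m"])
        csms = {
            stage: read_elevation_raster(self.p(f"csm_{_slug(stage)}.tif"))
            for stage in self.stage_names
        }
        table = extract_trial(
            csms, rois, layout, statistic=ex["statistic"], min_pixels=ex["min_pixels"]
        )
        table.to_csv(self.p("heights_aerial.csv"), index=False)

    def stage_georef(self) -> None:
        targets = read_targets_csv(self.p("targets.csv"))
        stage0 = self.stage_names[0]
        csm = read_elevation_raster(self.p(f"csm_{_slug(stage0)}.tif"))
        gsd = self.cfg["georef"]["gsd_m"] or self.sim.cell_size_m
        report = horizontal_deltas(targets)
        vert = vertical_accuracy(targets, csm)
        report.z = vert.z
        report.slope, report.intercept = vert.slope, vert.intercept
        report.r_squared, report.rmse_z = vert.r_squared, vert.rmse_z
        check_accuracy_criteria(report, gsd)
        self.p("georef.json").write_text(json.dumps(report.to_dict(), indent=2))

    def stage_genetics(self) -> None:
        aerial = pd.read_csv(self.p("heights_aerial.csv"))
        ground = pd.read_csv(self.p("heights_ground.csv"))
        basis = self.cfg["genetics"]["h2_basis"]
        results: dict = {}
        values = []
        for platform, table in (("aerial", aerial), ("ground", ground)):
            for stage, grp in table.groupby("stage"):
                grp = grp.dropna(subset=["ph_cm"])
                blue_fit = fit_reml(grp, blue_spec())
                blup_fit = fit_reml(grp, blup_spec())
                n_rep = int(grp["rep"].nunique())
                h2, h2_se = broad_sense_heritability(blup_fit.vc, n_rep, basis=basis)
                blues = compute_blues(blue_fit)
                blups = compute_blups(blup_fit)
                results[f"{platform}/{stage}"] = {
                    "H2g": h2,
                    "H2g_se": h2_se,
                    "variance_components": blup_fit.vc.components,
                    "sigma2_e": blup_fit.vc.sigma2_e,
                    "n": int(len(grp)),
                }
                df = blues.join(blups.rename("blup"))
                df["platform"] = platform
                df["stage"] = stage
                values.append(df.reset_index())
        merged = pd.concat(values, ignore_index=True)
        merged["rank"] = merged.groupby(["platform", "stage"])["blup"].rank(ascending=False)
        merged.to_csv(self.p("genotype_values.csv"), index=False)
        # rank concordance of aerial vs ground genotype predictions per stage
        for stage in sorted(aerial["stage"].unique()):
            a = merged[(merged.platform == "aerial") & (merged.stage == stage)].set_index("genotype")
            g = merged[(merged.platform == "ground") & (merged.stage == stage)].set_index("genotype")
            common = a.index.intersection(g.index)
            if len(common) >= 3:
                sp = spearman_with_test(a.loc[common, "blup"], g.loc[common, "blup"])
                results[f"concordance/{stage}"] = sp
        self.p("genetics.json").write_text(json.dumps(results, indent=2, default=float))

    def stage_agreement(self) -> None:
        aerial = pd.read_csv(self.p("heights_aerial.csv"))
        ground = pd.read_csv(self.p("heights_ground.csv"))
        alpha = self.cfg["agreement"]["alpha"]
        merged = ground.merge(
            aerial[["plot_id", "stage", "ph_cm"]],
            on=["plot_id", "stage"],
            suffixes=("_ground", "_aerial"),
        ).dropna(subset=["ph_cm_ground", "ph_cm_aerial"])
        out: dict = {"per_stage": {}}
        dev_rows = []
        for stage, grp in merged.groupby("stage"):
            ids = grp["plot_id"].tolist()
            flagged = flag_outliers(grp["ph_cm_ground"], grp["ph_cm_aerial"], alpha=alpha, ids=ids)
            keep = ~grp["plot_id"].isin(flagged)
            rep = agreement(
                grp.loc[keep, "ph_cm_ground"],
                grp.loc[keep, "ph_cm_aerial"],
                outliers_removed=flagged,
            )
            out["per_stage"][str(stage)] = rep.to_dict()
            kept = grp.loc[keep]
            dev_rows.append(
                pd.DataFrame(
                    {
                        "stage": kept["stage"],
                        "ground_cm": kept["ph_cm_ground"],
                        "aerial_cm": kept["ph_cm_aerial"],
                    }
                )
            )
        dev = rmse_dev(pd.concat(dev_rows, ignore_index=True))
        out["rmse_dev_cm"] = dev.rmse_dev_cm
        out["rmse_dev_per_stage"] = dev.per_stage
        out["n_total"] = dev.n_total
        self.p("agreement.json").write_text(json.dumps(out, indent=2, default=float))


def _slug(stage: str) -> str:
    return stage.replace("+", "p").replace(" ", "_")


def run_pipeline(
    config: str | os.PathLike | dict | None,
    out_dir: str | os.PathLike,
    seed: int | None = None,
) -> dict:
    """Run every configured stage in order and return the manifest dict.

    Stages whose config and inputs are unchanged since the previous manifest
    are skipped.  On a stage failure the run aborts with the stage named and
    that stage's outputs renamed with a ``.partial`` suffix.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = _Runner(cfg, out, seed)
    stage_names = r.stage_names
    slug = _slug
    dsms = [out / f"dsm_{slug(s)}.tif" for s in stage_names]
    csms = [out / f"csm_{slug(s)}.tif" for s in stage_names]
    plans = {
        "simulate": (
            [],
            [out / "dtm.tif", *dsms, out / "layout.geojson", out / "truth.csv",
             out / "heights_ground.csv", out / "targets.csv", out / "pedigree.csv"],
            r.stage_simulate,
        ),
        "csm": ([out / "dtm.tif", *dsms], csms, r.stage_csm),
        "extract": (
            [out / "layout.geojson", *csms],
            [out / "heights_aerial.csv"],
            r.stage_extract,
        ),
        "validate-georef": (
            [out / "targets.csv", csms[0]],
            [out / "georef.json"],
            r.stage_georef,
        ),
        "genetics": (
            [out / "heights_aerial.csv", out / "heights_ground.csv"],
            [out / "genotype_values.csv", out / "genetics.json"],
            r.stage_genetics,
        ),
        "agreement": (
            [out / "heights_aerial.csv", out / "heights_ground.csv"],
            [out / "agreement.json"],
            r.stage_agreement,
        ),
    }
    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        inputs, outputs, fn = plans[stage]
        r.run_stage(stage, inputs, outputs, fn)
    (out / "manifest.json").write_text(json.dumps(r.manifest, indent=2, default=str))
    return r.manifest
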