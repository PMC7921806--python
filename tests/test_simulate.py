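"""The synthetic trial generator: terrain, layout, truth, surfaces, targets."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from phenouav.genetics import additive_relationship
from phenouav.grids import compute_csm
from phenouav.simulate import (
    PlacementError,
    ResourceError,
    SimulationConfig,
    place_targets,
    simulate_canopy_surface,
    simulate_genotype_truth,
    simulate_ground_measurements,
    simulate_layout,
    simulate_pedigree,
    simulate_terrain,
    stamp_targets,
)


class TestTerrain:
    def test_zero_relief_is_flat(self):
        cfg = SimulationConfig(seed=1, extent_m=(5, 5), cell_size_m=0.05, terrain_relief_cm=0)
        g = simulate_terrain(cfg)
        assert np.all(g.values == cfg.base_elevation_m)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, extent_m=(5, 5), cell_size_m=0.05)
        a = simulate_terrain(cfg)
        b = simulate_terrain(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_relief_amplitude(self, seed):
        cfg = SimulationConfig(
            seed=seed, extent_m=(20, 20), cell_size_m=0.05, terrain_relief_cm=10
        )
        g = simulate_terrain(cfg)
        span_cm = (g.values.max() - g.values.min()) * 100
        assert 5 <= span_cm <= 20

    def test_cell_budget(self):
        cfg = SimulationConfig(seed=0, extent_m=(2000, 2000), cell_size_m=0.01)
        with pytest.raises(ResourceError):
            simulate_terrain(cfg)


class TestLayout:
    def test_full_trial_cardinality(self):
        cfg = SimulationConfig(seed=0, n_genotypes=150, n_replicates=2, n_blocks_per_rep=30)
        layout = simulate_layout(cfg)
        assert len(layout) == 300
        df = layout.frame()
        sizes = df.groupby(["rep", "block"]).size()
        assert (sizes == 5).all()

    def test_single_plot(self):
        cfg = SimulationConfig(seed=0, n_genotypes=1, n_replicates=1, n_blocks_per_rep=1)
        layout = simulate_layout(cfg)
        assert len(layout) == 1

    def test_each_genotype_once_per_replicate(self, tiny_layout, tiny_config):
        df = tiny_layout.frame()
        counts = df.groupby(["rep", "genotype"]).size()
        assert (counts == 1).all()
        assert df.genotype.value_counts().eq(tiny_config.n_replicates).all()

    def test_polygons_disjoint(self, tiny_layout):
        plots = tiny_layout.plots
        for i in range(len(plots)):
            for j in range(i + 1, len(plots)):
                assert not plots[i].polygon.intersects(plots[j].polygon)

    def test_indivisible_blocks_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SimulationConfig(n_genotypes=10, n_blocks_per_rep=3)

    def test_too_small_extent_rejected(self):
        from phenouav.simulate import LayoutError

        cfg = SimulationConfig(
            seed=0, n_genotypes=12, n_replicates=2, n_blocks_per_rep=3, extent_m=(8, 8)
        )
        with pytest.raises(LayoutError):
            simulate_layout(cfg)


class TestGenotypeTruth:
    def test_zero_sd_gives_zero_effects(self, tiny_layout, tiny_config):
        cfg = replace(tiny_config, genotype_sd_cm=0.0)
        truth = simulate_genotype_truth(cfg, tiny_layout)
        assert all(v == 0.0 for v in truth.genotype_effects_cm.values())

    def test_effect_sd_matches_config(self):
        cfg = SimulationConfig(
            seed=0, n_genotypes=10000, n_replicates=1, n_blocks_per_rep=100,
            cell_size_m=1.0, genotype_sd_cm=5.0,
        )
        layout = simulate_layout(cfg)
        truth = simulate_genotype_truth(cfg, layout)
        sd = np.std(list(truth.genotype_effects_cm.values()), ddof=1)
        # chi-square bound on a 10,000-draw sample SD
        assert abs(sd - 5.0) < 0.15

    def test_stage_means_ordering(self, tiny_config, tiny_layout):
        truth = simulate_genotype_truth(tiny_config, tiny_layout)
        med = truth.truth.groupby("stage").true_cm.median()
        assert med["E+40"] < med["B"] < med["M"] < med["A+7"]

    def test_truth_is_sum_of_effects(self, tiny_config, tiny_layout, tiny_truth):
        row = tiny_truth.truth.iloc[17]
        expected = (
            tiny_truth.stage_means_cm[row.stage]
            + tiny_truth.genotype_effects_cm[row.genotype]
            + tiny_truth.replicate_effects_cm[row.rep]
            + tiny_truth.block_effects_cm[(row.rep, row.block)]
        )
        assert row.true_cm == pytest.approx(expected, abs=1e-12)


def zero_noise(cfg):
    return replace(
        cfg, culm_sd_cm=0.0, measurement_sd_cm=0.0, surface_noise_sd_cm=0.0,
        terrain_relief_cm=0.0,
    )


class TestCanopySurface:
    def test_zero_noise_beds_equal_truth(self, tiny_config, tiny_layout):
        cfg = zero_noise(tiny_config)
        truth = simulate_genotype_truth(cfg, tiny_layout)
        terrain = simulate_terrain(cfg)
        dsm = simulate_canopy_surface(terrain, tiny_layout, truth, cfg, "M")
        csm = compute_csm(dsm, terrain)
        t = csm.transform
        for plot in tiny_layout.plots[:4]:
            h = truth.plot_height_m(plot.plot_id, "M")
            for bx0, by0, bx1, by1 in tiny_layout.bed_footprints(plot):
                # probe well inside the bed
                r, c = t.world_to_cell((bx0 + bx1) / 2, (by0 + by1) / 2)
                assert csm.values[r, c] == pytest.approx(h, abs=1e-9)

    def test_furrow_below_quarter_height(self, tiny_config, tiny_layout):
        cfg = zero_noise(tiny_config)
        truth = simulate_genotype_truth(cfg, tiny_layout)
        terrain = simulate_terrain(cfg)
        dsm = simulate_canopy_surface(terrain, tiny_layout, truth, cfg, "M")
        csm = compute_csm(dsm, terrain)
        t = csm.transform
        for plot in tiny_layout.plots[:4]:
            h = truth.plot_height_m(plot.plot_id, "M")
            xmin, ymin, xmax, ymax = plot.polygon.bounds
            furrow_x = (xmin + xmax) / 2  # center of the inter-bed gap
            r, c = t.world_to_cell(furrow_x, (ymin + ymax) / 2)
            assert csm.values[r, c] < 0.25 * h

    def test_nonnegative_up_to_noise_tail(self, tiny_config, tiny_layout, tiny_truth):
        terrain = simulate_terrain(tiny_config)
        dsm = simulate_canopy_surface(terrain, tiny_layout, tiny_truth, tiny_config, "B")
        diff = dsm.values - terrain.values
        sd = tiny_config.surface_noise_sd_cm / 100.0
        # only the Gaussian elevation noise can push below ground: over ~1e5
        # pixels the minimum sits in the extreme-value range of N(0, sd)
        assert np.quantile(diff, 0.001) >= -3.5 * sd
        assert diff.min() >= -6.0 * sd

    def test_missing_stage_raises(self, tiny_config, tiny_layout, tiny_truth):
        terrain = simulate_terrain(tiny_config)
        with pytest.raises(KeyError):
            simulate_canopy_surface(terrain, tiny_layout, tiny_truth, tiny_config, "harvest")

    def test_determinism(self, tiny_config, tiny_layout, tiny_truth):
        terrain = simulate_terrain(tiny_config)
        a = simulate_canopy_surface(terrain, tiny_layout, tiny_truth, tiny_config, "M")
        b = simulate_canopy_surface(terrain, tiny_layout, tiny_truth, tiny_config, "M")
        np.testing.assert_array_equal(a.values, b.values)


class TestGroundMeasurements:
    def test_exact_when_noiseless(self, tiny_config, tiny_layout):
        cfg = zero_noise(tiny_config)
        truth = simulate_genotype_truth(cfg, tiny_layout)
        table = simulate_ground_measurements(tiny_layout, truth, cfg, "M")
        merged = table.merge(truth.truth[truth.truth.stage == "M"], on="plot_id")
        np.testing.assert_allclose(merged.ph_cm, merged.true_cm, atol=1e-12)

    def test_four_culm_standard_error(self):
        cfg = SimulationConfig(
            seed=5, n_genotypes=400, n_replicates=1, n_blocks_per_rep=20,
            cell_size_m=1.0, culm_sd_cm=4.0, measurement_sd_cm=0.0,
        )
        layout = simulate_layout(cfg)
        truth = simulate_genotype_truth(cfg, layout)
        table = simulate_ground_measurements(layout, truth, cfg, "M")
        merged = table.merge(truth.truth[truth.truth.stage == "M"], on="plot_id")
        err_sd = np.std(merged.ph_cm - merged.true_cm, ddof=1)
        assert err_sd == pytest.approx(4.0 / np.sqrt(4), rel=0.15)

    def test_n_culms_configurable(self, tiny_config, tiny_layout, tiny_truth):
        assert tiny_config.n_culms == 4
        cfg = replace(tiny_config, n_culms=8, measurement_sd_cm=0.0)
        table = simulate_ground_measurements(tiny_layout, tiny_truth, cfg, "M")
        assert len(table) == len(tiny_layout)


class TestTargets:
    def test_default_role_counts(self, tiny_config, tiny_layout):
        targets = place_targets(tiny_config, tiny_layout)
        assert sum(t.role == "checkpoint" for t in targets) == 11
        assert sum(t.role == "gcp" for t in targets) == 9

    def test_pillar_heights_in_csm(self, tiny_config, tiny_layout):
        cfg = zero_noise(tiny_config)
        truth = simulate_genotype_truth(cfg, tiny_layout)
        terrain = simulate_terrain(cfg)
        dsm = simulate_canopy_surface(terrain, tiny_layout, truth, cfg, "M")
        targets = place_targets(cfg, tiny_layout)
        dsm = stamp_targets(dsm, terrain, targets)
        csm = compute_csm(dsm, terrain)
        t = csm.transform
        for tgt in targets[:6]:
            r, c = t.world_to_cell(tgt.surveyed_x, tgt.surveyed_y)
            assert csm.values[r, c] == pytest.approx(tgt.surveyed_z, abs=1e-9)

    def test_overlap_rejected(self, tiny_config, tiny_layout):
        cfg = replace(tiny_config, target_side_m=4.0)
        with pytest.raises(PlacementError):
            place_targets(cfg, tiny_layout)


class TestPedigree:
    def test_founders_only_gives_identity(self):
        ped = simulate_pedigree(n_founders=6, n_crosses=0, seed=1)
        A = additive_relationship(ped)
        np.testing.assert_array_equal(A.values, np.eye(6))

    def test_full_sibs(self):
        from phenouav.trial import Pedigree

        ped = Pedigree()
        ped.add("F1")
        ped.add("F2")
        ped.add("S1", "F1", "F2")
        ped.add("S2", "F1", "F2")
        A = additive_relationship(ped)
        assert A.loc("S1", "S2") == pytest.approx(0.5)

    def test_seeded_reproducibility(self):
        a = simulate_pedigree(5, 10, seed=3)
        b = simulate_pedigree(5, 10, seed=3)
        assert a.records == b.records
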