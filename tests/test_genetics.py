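"""REML machinery, heritability, pedigree kinship, and rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenouav.genetics import (
    MixedModelSpec,
    RandomTerm,
    RankError,
    additive_relationship,
    adjust_for_flights,
    blue_spec,
    blup_spec,
    broad_sense_heritability,
    compute_blues,
    compute_blups,
    fit_gxe,
    fit_reml,
    narrow_sense_heritability,
    reml_loglik,
    spearman_with_test,
)
from phenouav.simulate import simulate_pedigree
from phenouav.trial import Pedigree


def one_way_data(seed, g=30, n=4, sg=3.0, se=2.0, mu=10.0):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sg, g)
    rows = [
        {"genotype": f"g{i:03d}", "ph_cm": mu + eff[i] + rng.normal(0, se)}
        for i in range(g)
        for _ in range(n)
    ]
    return pd.DataFrame(rows)


def one_way_closed_form(df, n):
    ybar = df.groupby("genotype").ph_cm.mean()
    grand = df.ph_cm.mean()
    g = len(ybar)
    msb = n * ((ybar - grand) ** 2).sum() / (g - 1)
    msw = ((df.ph_cm - df.genotype.map(ybar)) ** 2).sum() / (g * (n - 1))
    return max(0.0, (msb - msw) / n), msw


ONE_WAY_SPEC = MixedModelSpec(response="ph_cm", fixed=(), random=(RandomTerm(("genotype",)),))


def lattice_data(seed):
    """Small alpha-lattice-style dataset used in several tests (fixed seed 42
    reproduces the frozen external REML oracle below)."""
    rng = np.random.default_rng(seed)
    rows = []
    ge = rng.normal(0, 4, 12)
    for rep in range(1, 3):
        re_ = rng.normal(0, 1.5)
        order = rng.permutation(12).reshape(4, 3)
        for b in range(4):
            be = rng.normal(0, 2)
            for gi in order[b]:
                rows.append(
                    {
                        "genotype": f"G{gi + 1:02d}",
                        "rep": rep,
                        "block": b + 1,
                        "ph_cm": 90 + ge[gi] + re_ + be + rng.normal(0, 2.5),
                    }
                )
    return pd.DataFrame(rows)


class TestREMLCore:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_balanced_one_way_closed_form(self, seed):
        df = one_way_data(seed)
        fit = fit_reml(df, ONE_WAY_SPEC)
        s2g, s2e = one_way_closed_form(df, 4)
        assert fit.vc.components["genotype"] == pytest.approx(s2g, abs=1e-6)
        assert fit.vc.sigma2_e == pytest.approx(s2e, abs=1e-6)

    def test_external_reml_oracle(self):
        """Frozen variance components from an independent REML fit (lme4
        1.1-37, lmer ph_cm ~ 1 + (1|genotype) + (1|rep) + (1|rep:block),
        synthetic 12-genotype fixture)."""
        fit = fit_reml(lattice_data(42), blup_spec())
        assert fit.vc.components["genotype"] == pytest.approx(19.146616702899, abs=2e-4)
        assert fit.vc.components["rep"] == pytest.approx(0.365125755172, abs=2e-4)
        assert fit.vc.components["rep:block"] == pytest.approx(1.337970895836, abs=2e-4)
        assert fit.vc.sigma2_e == pytest.approx(2.625655894889, abs=2e-4)
        assert fit.loglik == pytest.approx(-62.9070608714, abs=1e-6)
        assert fit.beta[0] == pytest.approx(89.1480764105, abs=1e-6)
        blups = compute_blups(fit)
        assert blups["G04"] == pytest.approx(5.679823, abs=1e-3)
        assert blups["G05"] == pytest.approx(-6.615296, abs=1e-3)

    def test_all_equal_response(self):
        df = pd.DataFrame(
            {"genotype": ["a", "a", "b", "b", "c", "c"], "ph_cm": [7.0] * 6}
        )
        fit = fit_reml(df, ONE_WAY_SPEC)
        assert fit.vc.components["genotype"] == 0.0
        assert fit.vc.sigma2_e == 0.0
        assert fit.beta[0] == 7.0

    def test_optimum_beats_random_admissible_points(self):
        from phenouav.genetics import _fixed_design, _random_designs

        df = one_way_data(9, g=20, n=3)
        fit = fit_reml(df, ONE_WAY_SPEC)
        y = df.ph_cm.to_numpy(float)
        X, _ = _fixed_design(df, ())
        Zs, _, _ = _random_designs(df, ONE_WAY_SPEC.random)
        rng = np.random.default_rng(0)
        vy = np.var(y)
        for _ in range(200):
            ll = reml_loglik(y, X, Zs, [rng.uniform(0, 3 * vy)], rng.uniform(1e-3, 3 * vy))
            assert ll <= fit.loglik + 1e-8

    def test_variances_nonnegative_and_boundary_flagged(self):
        # no genotype signal at all: sigma_g pins to zero
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"genotype": [f"g{i}" for i in range(20)] * 4, "ph_cm": rng.normal(0, 1, 80)}
        )
        fit = fit_reml(df, ONE_WAY_SPEC)
        assert fit.vc.components["genotype"] >= 0.0
        if fit.vc.components["genotype"] == 0.0:
            assert fit.vc.boundary["genotype"]

    def test_rank_deficient_design_named(self):
        df = lattice_data(1)
        df["dup"] = df["genotype"]  # perfectly aliased factor
        spec = MixedModelSpec(
            response="ph_cm", fixed=("genotype", "dup"), random=(RandomTerm(("rep",)),)
        )
        with pytest.raises(RankError, match="aliased"):
            fit_reml(df, spec)


class TestBLUE:
    def test_zero_noise_balanced_recovers_means(self):
        df = lattice_data(3).copy()
        truth = {g: 90 + i for i, g in enumerate(sorted(df.genotype.unique()))}
        df["ph_cm"] = df.genotype.map(truth)
        fit = fit_reml(df, blue_spec())
        blues = compute_blues(fit)
        for g, v in truth.items():
            assert blues.loc[g, "blue"] == pytest.approx(v, abs=1e-6)

    def test_shift_equivariance(self):
        df = lattice_data(4)
        b0 = compute_blues(fit_reml(df, blue_spec()))
        df2 = df.assign(ph_cm=df.ph_cm + 13.0)
        b1 = compute_blues(fit_reml(df2, blue_spec()))
        np.testing.assert_allclose(b1.blue, b0.blue + 13.0, atol=1e-5)

    def test_invariant_to_rep_relabeling(self):
        df = lattice_data(5)
        b0 = compute_blues(fit_reml(df, blue_spec()))
        df2 = df.assign(rep=df.rep.map({1: 9, 2: 4}))
        b1 = compute_blues(fit_reml(df2, blue_spec()))
        np.testing.assert_allclose(b1.blue, b0.blue, atol=1e-6)


class TestBLUP:
    def test_balanced_shrinkage_closed_form(self):
        df = one_way_data(11, g=25, n=4)
        fit = fit_reml(df, ONE_WAY_SPEC)
        s2g, s2e = fit.vc.components["genotype"], fit.vc.sigma2_e
        lam = s2g / (s2g + s2e / 4)
        centered = df.groupby("genotype").ph_cm.mean() - df.ph_cm.mean()
        blups = compute_blups(fit).sort_index()
        np.testing.assert_allclose(blups, lam * centered.sort_index(), atol=1e-6)

    def test_blups_center_near_zero(self):
        fit = fit_reml(lattice_data(6), blup_spec())
        assert abs(compute_blups(fit).sum()) < 1e-6

    def test_shrinkage_limits(self):
        # strong signal, tiny noise: BLUPs approach the centered means
        df = one_way_data(12, g=15, n=4, sg=20.0, se=0.01)
        fit = fit_reml(df, ONE_WAY_SPEC)
        centered = (df.groupby("genotype").ph_cm.mean() - df.ph_cm.mean()).sort_index()
        np.testing.assert_allclose(compute_blups(fit).sort_index(), centered, rtol=1e-3)


class TestHeritability:
    def test_formula_arithmetic(self):
        vc = _vc({"genotype": 25.0}, 9.0)
        h2, _ = broad_sense_heritability(vc, n_rep=2)
        assert h2 == pytest.approx(25 / (25 + 4.5))

    def test_zero_genotypic_variance(self):
        h2, _ = broad_sense_heritability(_vc({"genotype": 0.0}, 5.0), 2)
        assert h2 == 0.0

    def test_zero_residual(self):
        h2, _ = broad_sense_heritability(_vc({"genotype": 4.0}, 0.0), 2)
        assert h2 == 1.0

    def test_plot_basis_denominator(self):
        vc = _vc({"genotype": 25.0, "rep": 1.0, "rep:block": 4.0}, 9.0)
        h2, _ = broad_sense_heritability(vc, 2, basis="plot")
        assert h2 == pytest.approx(25 / 39)

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            broad_sense_heritability(_vc({"genotype": 0.0}, 0.0), 2)

    def test_se_from_simulation_spread(self):
        # the delta-method SE should be on the scale of the seed-to-seed spread
        h2s, ses = [], []
        for seed in range(15):
            fit = fit_reml(one_way_data(seed, g=40, n=3, sg=3, se=3), ONE_WAY_SPEC)
            h2, se = broad_sense_heritability(fit.vc, 3)
            h2s.append(h2)
            ses.append(se)
        assert np.median(ses) == pytest.approx(np.std(h2s, ddof=1), rel=0.8)


def _vc(components, s2e):
    from phenouav.genetics import VarianceComponents

    names = list(components) + ["residual"]
    k = len(names)
    return VarianceComponents(
        components=components, sigma2_e=s2e, cov=np.zeros((k, k)), names=names,
        boundary={}, n_iter=1, converged=True, grad_norm=0.0,
    )


class TestRelationshipMatrix:
    def test_parent_offspring(self):
        ped = Pedigree()
        ped.add("A")
        ped.add("B")
        ped.add("C", "A", "B")
        A = additive_relationship(ped)
        assert A.loc("A", "C") == pytest.approx(0.5)
        assert A.loc("C", "C") == pytest.approx(1.0)

    def test_selfing_inbreeding(self):
        ped = Pedigree()
        ped.add("A")
        ped.add("S", "A", "A")
        A = additive_relationship(ped)
        assert A.loc("S", "S") == pytest.approx(1.5)

    def test_unknown_parent_is_founder_contribution(self):
        ped = Pedigree()
        ped.add("A")
        ped.add("H", "A", None)
        A = additive_relationship(ped)
        assert A.loc("A", "H") == pytest.approx(0.5)  # half of A_AA, none from the unknown side
        assert A.loc("H", "H") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_semidefinite(self, seed):
        ped = simulate_pedigree(n_founders=8, n_crosses=20, seed=seed)
        A = additive_relationship(ped)
        assert np.min(np.linalg.eigvalsh(A.values)) >= -1e-8
        np.testing.assert_allclose(A.values, A.values.T)
        assert np.all(np.diag(A.values) >= 1.0) and np.all(np.diag(A.values) <= 2.0)

    def test_cycle_rejected(self):
        ped = Pedigree()
        ped.add("A")
        with pytest.raises(ValueError):
            ped.add("B", "C", "A")  # C not defined yet: gap or cycle


def gxe_data(seed, g=20, s2a=16.0, s2ge=0.0, s2e=4.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, np.sqrt(s2a), g)
    rows = []
    for year in ("Y17", "Y18"):
        ge = rng.normal(0, np.sqrt(s2ge), g) if s2ge > 0 else np.zeros(g)
        for rep in (1, 2):
            for i in range(g):
                rows.append(
                    {
                        "genotype": f"G{i:02d}",
                        "year": year,
                        "rep": rep,
                        "ph_cm": 90 + a[i] + ge[i] + rng.normal(0, np.sqrt(s2e)),
                    }
                )
    return pd.DataFrame(rows)


class TestGxE:
    def test_identity_relationship_matches_independent_fit(self):
        from phenouav.genetics import RelationshipMatrix

        df = gxe_data(0)
        genos = sorted(df.genotype.unique())
        eye = RelationshipMatrix(genos, np.eye(len(genos)))
        f_ind = fit_gxe(df, relationship=None)
        f_eye = fit_gxe(df, relationship=eye)
        for k in f_ind.vc.components:
            assert f_eye.vc.components[k] == pytest.approx(f_ind.vc.components[k], abs=1e-6)
        assert f_eye.vc.sigma2_e == pytest.approx(f_ind.vc.sigma2_e, abs=1e-6)

    def test_single_year_rejected(self):
        df = gxe_data(1)
        with pytest.raises(ValueError, match="2 environments"):
            fit_gxe(df[df.year == "Y17"])

    def test_narrow_sense_heritability_formula(self):
        vc = _vc({"genotype": 16.0, "genotype:year": 2.0}, 4.0)
        h2, _ = narrow_sense_heritability(vc, n_env=2, n_rep=2)
        assert h2 == pytest.approx(16 / (16 + 1.0 + 1.0))

    def test_pedigree_signal_recovered(self):
        # full-sib families share additive values; the A-matrix fit should
        # find substantial additive variance
        rng = np.random.default_rng(3)
        ped = Pedigree()
        for i in range(10):
            ped.add(f"F{i}")
        k = 0
        for fam in range(5):
            p1, p2 = f"F{2 * fam}", f"F{2 * fam + 1}"
            for _ in range(4):
                ped.add(f"X{k}", p1, p2)
                k += 1
        A = additive_relationship(ped)
        offspring = [i for i in ped.individuals if i.startswith("X")]
        L = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(A.ids)))
        u = L @ rng.normal(0, 4.0, len(A.ids))
        add = dict(zip(A.ids, u))
        rows = [
            {"genotype": g, "year": yr, "rep": rep,
             "ph_cm": 90 + add[g] + rng.normal(0, 1.0)}
            for g in offspring for yr in ("Y17", "Y18") for rep in (1, 2)
        ]
        fit = fit_gxe(pd.DataFrame(rows), relationship=A.submatrix(offspring))
        assert fit.vc.components["genotype"] > 4.0


class TestSpearman:
    def test_monotone_is_one(self):
        res = spearman_with_test([1, 2, 3, 4, 5], [10, 20, 25, 90, 100])
        assert res["rho"] == pytest.approx(1.0)
        assert res["p_value"] == 0.0

    def test_reverse_is_minus_one(self):
        res = spearman_with_test([1, 2, 3, 4], [9, 7, 5, 1])
        assert res["rho"] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4: rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_with_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res["rho"] == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, 40).astype(float)
        y = x + rng.normal(0, 2, 40)
        res = spearman_with_test(x, y)
        ref = stats.spearmanr(x, y)
        assert res["rho"] == pytest.approx(ref.statistic, abs=1e-12)
        assert res["p_value"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_linear_ci_option(self):
        res = spearman_with_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], ci="linear")
        hw = 1.959963984540054 * (1 - 0.8) / 3
        assert res["ci_high"] - res["rho"] == pytest.approx(hw, rel=1e-6)


class TestFlightAdjustment:
    def test_single_flight_passthrough(self):
        rec = pd.DataFrame(
            {"plot_id": ["p1", "p2"], "flight": [1, 1], "ph_cm": [90.0, 95.0]}
        )
        adj = adjust_for_flights(rec)
        assert adj["p1"] == 90.0 and adj["p2"] == 95.0

    def test_balanced_two_flight_offset(self):
        plots = [f"p{i}" for i in range(6)]
        base = np.array([90.0, 92, 94, 96, 98, 100])
        rec = pd.DataFrame(
            {
                "plot_id": plots * 2,
                "flight": [1] * 6 + [2] * 6,
                "ph_cm": np.concatenate([base, base + 2.0]),
            }
        )
        adj = adjust_for_flights(rec)
        np.testing.assert_allclose(adj[plots], base + 1.0, atol=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(8)] * 3,
                "flight": np.repeat([1, 2, 3], 8),
                "ph_cm": rng.normal(90, 5, 24),
            }
        )
        a = adjust_for_flights(rec)
        b = adjust_for_flights(rec.sample(frac=1, random_state=4))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_plot_missing_everywhere_is_nan(self):
        rec = pd.DataFrame(
            {
                "plot_id": ["p1", "p2", "p1", "p2", "p3"],
                "flight": [1, 1, 2, 2, 1],
                "ph_cm": [90.0, 95.0, 92.0, 97.0, np.nan],
            }
        )
        adj = adjust_for_flights(rec)
        assert np.isnan(adj["p3"])
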