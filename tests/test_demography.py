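"""Folded SFS construction, expected spectra, composite likelihood,
AIC bookkeeping and unit conversion."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from hazelpop.demography import (
    FoldedSFS,
    UnitConstants,
    aic,
    build_folded_sfs,
    composite_loglik,
    constant_size_model,
    convert_units,
    expected_sfs,
    FitResult,
    model_catalog,
    select_model,
    theta_hat,
    two_pop_split_model,
)
from hazelpop.variants import MISSING, PopulationMap

from conftest import make_matrix


def pops_for(vm, sizes):
    labels = []
    for name, n in sizes.items():
        labels += [name] * n
    return PopulationMap({s: l for s, l in zip(vm.sample_ids, labels)})


class TestBuildFoldedSfs:
    def test_singleton_placement(self):
        # 2+2 diploids (dims 4,4); singleton in pop1 only -> cell (1, 0)
        vm = make_matrix([[1], [0], [0], [0]])
        pops = pops_for(vm, {"A": 2, "B": 2})
        sfs = build_folded_sfs(vm, pops, ["A", "B"])
        assert sfs.dims == (4, 4)
        assert sfs.data[1, 0] == 1.0
        assert sfs.n_snps == 1.0

    def test_missing_site_excluded(self):
        vm = make_matrix([[1, 1], [0, MISSING], [0, 0], [0, 0]])
        pops = pops_for(vm, {"A": 2, "B": 2})
        sfs = build_folded_sfs(vm, pops, ["A", "B"])
        assert sfs.n_snps == 1.0

    def test_twelve_site_hand_tally(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(4, 12)).astype(np.int8)
        vm = make_matrix(g)
        pops = pops_for(vm, {"A": 2, "B": 2})
        sfs = build_folded_sfs(vm, pops, ["A", "B"])
        # independent tally: fold by total minor-allele count
        tally = np.zeros((5, 5))
        for j in range(12):
            c1 = int(g[:2, j].sum())
            c2 = int(g[2:, j].sum())
            tot = c1 + c2
            if tot == 0 or tot == 8:
                continue
            if tot > 4:
                c1, c2 = 4 - c1, 4 - c2
            tally[c1, c2] += 1
        live = ~sfs.mask
        np.testing.assert_allclose(sfs.data[live], tally[live])
        assert sfs.n_snps == tally.sum()

    def test_mass_conserved_on_simulated_panel(self, neutral_panel_10):
        vm, pops, _ = neutral_panel_10
        sub = vm.take_sites(np.arange(min(500, vm.n_sites)))
        sfs = build_folded_sfs(sub, pops, ["p1"])
        segregating = ((sub.genotypes.sum(axis=0) % (2 * sub.n_samples)) != 0).sum()
        assert sfs.n_snps == segregating

    def test_fs_file_round_trip(self, tmp_path):
        vm = make_matrix([[1], [0], [0], [0]])
        pops = pops_for(vm, {"A": 2, "B": 2})
        sfs = build_folded_sfs(vm, pops, ["A", "B"])
        sfs.to_file(tmp_path / "obs.fs")
        back = FoldedSFS.from_file(tmp_path / "obs.fs")
        assert back.dims == sfs.dims
        np.testing.assert_allclose(back.data, sfs.data)
        np.testing.assert_array_equal(back.mask, sfs.mask)


class TestExpectedSfs:
    def test_folding_commutes(self):
        m = two_pop_split_model(T=0.5, m=0.5)
        unfolded = expected_sfs(m, (4, 4), n_reps=500, seed=9, fold=False)
        direct = expected_sfs(m, (4, 4), n_reps=500, seed=9)
        refolded = FoldedSFS.from_unfolded(unfolded.data, (4, 4))
        np.testing.assert_allclose(refolded.data, direct.data, rtol=1e-12)

    def test_just_split_collapses_to_shared_population(self):
        """T -> 0 with no migration: summing 2-D cells by total count
        reproduces the single-population folded spectrum for n1+n2."""
        m2 = two_pop_split_model(T=1e-4, m=0.0)
        e2 = expected_sfs(m2, (4, 4), n_reps=20_000, seed=5)
        total = np.add.outer(np.arange(5), np.arange(5))
        diag = np.array([e2.data[total == k].sum() for k in range(1, 5)])
        # fold cell counts 1..4 of an n=8 spectrum: eta_k + eta_{8-k}
        expect = np.array([1 + 1 / 7, 1 / 2 + 1 / 6, 1 / 3 + 1 / 5, 1 / 4])
        np.testing.assert_allclose(diag / diag.sum(), expect / expect.sum(),
                                   rtol=0.06)

    def test_symmetric_island_model_is_exchangeable(self):
        m = two_pop_split_model(T=8.0, m=2.0)
        e = expected_sfs(m, (6, 6), n_reps=20_000, seed=3)
        live = ~e.mask
        sym_live = live & live.T
        np.testing.assert_allclose(e.data[sym_live],
                                   e.data.T[sym_live], rtol=0.15, atol=5e-3)

    def test_deterministic_given_seed(self):
        m = constant_size_model()
        a = expected_sfs(m, (6,), n_reps=300, seed=11)
        b = expected_sfs(m, (6,), n_reps=300, seed=11)
        np.testing.assert_array_equal(a.data, b.data)


class TestCompositeLoglik:
    def test_saturated_case(self):
        obs_counts = np.array([0.0, 8.0, 4.0, 0.0])
        exp = np.array([0.0, 2.0, 1.0, 0.0])
        mask = np.array([True, False, False, True])
        obs = FoldedSFS((3,), obs_counts, mask)
        e = FoldedSFS((3,), exp, mask)
        # theta_hat = 12/3 = 4; lambda = obs exactly
        ll = composite_loglik(obs, e)
        expected = sum(o * math.log(o) - o - math.lgamma(o + 1) for o in (8, 4))
        assert ll == pytest.approx(expected)

    def test_three_cell_hand_example(self):
        obs = FoldedSFS((3,), np.array([0, 2.0, 1.0, 1.0]),
                        np.array([True, False, False, False]))
        e = FoldedSFS((3,), np.array([0, 0.5, 0.25, 0.25]),
                      np.array([True, False, False, False]))
        theta = 4.0
        lam = theta * np.array([0.5, 0.25, 0.25])
        o = np.array([2.0, 1.0, 1.0])
        expected = float(np.sum(o * np.log(lam) - lam - gammaln(o + 1)))
        assert composite_loglik(obs, e, theta=theta) == pytest.approx(expected)

    def test_moving_theta_from_profile_decreases(self):
        obs = FoldedSFS((3,), np.array([0, 6.0, 3.0, 1.0]),
                        np.array([True, False, False, False]))
        e = FoldedSFS((3,), np.array([0, 0.6, 0.3, 0.1]),
                      np.array([True, False, False, False]))
        th = theta_hat(obs, e)
        assert composite_loglik(obs, e, theta=th) > composite_loglik(obs, e, theta=2 * th)
        assert composite_loglik(obs, e, theta=th) > composite_loglik(obs, e, theta=th / 2)

    def test_profile_theta_matches_numeric_optimum(self):
        obs = FoldedSFS((3,), np.array([0, 11.0, 5.0, 2.0]),
                        np.array([True, False, False, False]))
        e = FoldedSFS((3,), np.array([0, 0.55, 0.3, 0.15]),
                      np.array([True, False, False, False]))
        th = theta_hat(obs, e)
        res = minimize_scalar(lambda t: -composite_loglik(obs, e, theta=t),
                              bounds=(1.0, 100.0), method="bounded",
                              options={"xatol": 1e-10})
        assert th == pytest.approx(res.x, rel=1e-6)


class TestAicAndSelection:
    def test_worked_example(self):
        assert aic(-418_444, 8) == 836_904

    def test_simple_values(self):
        assert aic(0.0, 1) == 2.0
        assert aic(-10.5, 3) == 27.0

    def test_recomputation_is_bit_exact(self):
        fit = FitResult(model_id="x", family="f", params_hat={}, theta_hat=1.0,
                        loglik=-1234.5678, k=5, aic=aic(-1234.5678, 5), n_starts=1)
        assert aic(fit.loglik, fit.k) == fit.aic

    def test_ranking_and_tie_break(self):
        def fr(mid, ll, k):
            return FitResult(model_id=mid, family="f", params_hat={},
                             theta_hat=1.0, loglik=ll, k=k, aic=aic(ll, k),
                             n_starts=1)
        a = fr("a", -50.0, 5)   # aic 110
        b = fr("b", -45.0, 5)   # aic 100
        c = fr("c", -46.0, 4)   # aic 100, fewer params -> wins tie
        ranked = select_model([a, b, c])
        assert [f.model_id for f in ranked] == ["c", "b", "a"]
        assert ranked[-1].aic - ranked[0].aic == pytest.approx(10.0)


class TestUnitConversion:
    def test_identity_scaling(self):
        const = UnitConstants(mu=1e-8, gen_time=1.0, L=1.0)
        fit = FitResult("m", "f", {}, theta_hat=4 * 1e-8 * 1.0, loglik=0.0,
                        k=1, aic=2.0, n_starts=1)
        assert convert_units(fit, const)["N_ref"] == pytest.approx(1.0)

    def test_reference_constants(self):
        # 4 * mu * L = 4 * 3.75e-8 * 370.75e6 = 55.6125
        const = UnitConstants()
        assert 4 * const.mu * const.L == pytest.approx(55.6125)
        fit = FitResult("m", "f", {}, theta_hat=55.6125, loglik=0.0, k=1,
                        aic=2.0, n_starts=1)
        assert convert_units(fit, const)["N_ref"] == pytest.approx(1.0)

    def test_size_and_time_conversion(self):
        const = UnitConstants(mu=3.75e-8, gen_time=15.0, L=370.75e6)
        theta = 4 * const.mu * const.L * 10_000  # N_ref = 10 000
        fit = FitResult("m", "f", {"nu1": 2.0, "T": 0.5}, theta_hat=theta,
                        loglik=0.0, k=3, aic=6.0, n_starts=1)
        conv = convert_units(fit, const)
        assert conv["Ne_1"] == pytest.approx(20_000)
        assert conv["T_years"] == pytest.approx(150_000)


class TestModelCatalog:
    def test_seventeen_models_in_five_families(self):
        cat = model_catalog()
        assert len(cat) == 17
        families = {m.family for m in cat.values()}
        assert families == {
            "divergence_with_gene_flow", "ancient_migration",
            "secondary_contact", "simultaneous_split", "hybrid_origin",
        }

    def test_flagship_model_has_k8(self):
        # 7 simplex parameters + profiled theta, the worked-example k
        assert model_catalog()["sc_adjacent_sym"].k_free == 8

    def test_invalid_times_rejected(self):
        m = model_catalog()["sc_adjacent_sym"]
        with pytest.raises(ValueError):
            m.demography({"T2": -0.5})

    def test_all_models_build_msprime_demographies(self):
        import msprime

        for m in model_catalog().values():
            d = m.demography()
            assert isinstance(d, msprime.Demography)
            d.validate()


class TestParametricBootstrap:
    def test_smoke_intervals_bracket_point_estimate(self):
        from hazelpop.demography import parametric_bootstrap

        m = constant_size_model()
        e = expected_sfs(m, (6,), n_reps=3_000, seed=41)
        theta = 800.0
        rng = np.random.default_rng(5)
        obs = FoldedSFS(e.dims, np.where(e.mask, 0.0,
                                         rng.poisson(theta * e.data)), e.mask)
        fit = FitResult(model_id=m.id, family=m.family,
                        params_hat={"nu1": 1.0}, theta_hat=theta,
                        loglik=0.0, k=2, aic=4.0, n_starts=1)
        ci = parametric_bootstrap(
            m, fit, (6,), n_boot=3, seed=9, exp_reps=1_000,
            n_starts=2, maxiter=5, n_reps=200, reselect_reps=0, top_k=1,
            refine_schedule=(), polish=None, final_reps=500,
        )
        lo, hi = ci["nu1"]
        assert lo <= hi


class TestThetaSelfConsistency:
    def test_one_pop_theta_recovered_within_1pct(self):
        m = constant_size_model()
        e = expected_sfs(m, (8,), n_reps=5_000, seed=21)
        theta_true = 500.0
        obs = FoldedSFS(e.dims, np.where(e.mask, 0.0, theta_true * e.data), e.mask)
        e2 = expected_sfs(m, (8,), n_reps=5_000, seed=22)
        assert theta_hat(obs, e2) == pytest.approx(theta_true, rel=0.01)
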