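"""Diversity, differentiation and LD-decay statistics."""

import numpy as np
import pandas as pd
import pytest

from hazelpop.diversity import (
    WindowSpec,
    ld_decay,
    ln_pi_ratio,
    per_site_pi,
    sample_heterozygosity,
    wc_fst,
    wc_fst_components,
    window_pi,
    genome_fst,
    _isotonic_decreasing,
)
from hazelpop.variants import MISSING, PopulationMap

from conftest import make_matrix


def wc_oracle(geno_a, geno_b):
    """Independent literal transcription of the Weir & Cockerham (1984)
    two-population variance components, evaluated with explicit scalar
    arithmetic per site (the brute-force oracle)."""
    out = []
    for site in range(len(geno_a[0])):
        ga = [g[site] for g in geno_a if g[site] != MISSING]
        gb = [g[site] for g in geno_b if g[site] != MISSING]
        n1, n2 = len(ga), len(gb)
        p1 = sum(ga) / (2 * n1)
        p2 = sum(gb) / (2 * n2)
        h1 = sum(1 for g in ga if g == 1) / n1
        h2 = sum(1 for g in gb if g == 1) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - 1 / (nbar - 1)
                           * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c))
    return out


class TestWindowPi:
    def test_monomorphic_panel_zero(self):
        vm = make_matrix([[0, 0], [0, 0]])
        pops = PopulationMap({"s0": "A", "s1": "A"})
        df = window_pi(vm, pops, "A", WindowSpec(size=1000, step=1000),
                       {"chr1": 1000})
        assert df["pi"].iloc[0] == 0.0

    def test_single_snp_half_frequency(self):
        # one SNP with j=2 alt copies among m=4: per-site pi =
        # 2*2*(4-2)/(4*3) = 2/3, i.e. 4 differing pairs out of 6
        vm = make_matrix([[1], [1]], pos=[500])
        pops = PopulationMap({"s0": "A", "s1": "A"})
        df = window_pi(vm, pops, "A", WindowSpec(size=1000, step=1000),
                       {"chr1": 1000})
        assert df["pi"].iloc[0] == pytest.approx((2 / 3) / 1000)

    def test_coalescent_mean_matches_theta(self, neutral_panel_10):
        vm, pops, truth = neutral_panel_10
        site_pi = per_site_pi(vm, pops.sample_rows(vm, "p1"))
        mean_pi = np.nansum(site_pi) / truth["L"]
        assert mean_pi == pytest.approx(1e-3, rel=0.10)

    def test_tiling_windows_combine_by_length(self, neutral_panel_10):
        vm, pops, _ = neutral_panel_10
        lengths = {"chr1": 1_000_000}
        fine = window_pi(vm, pops, "p1", WindowSpec(size=100_000, step=100_000),
                         lengths)
        coarse = window_pi(vm, pops, "p1", WindowSpec(size=1_000_000, step=1_000_000),
                           lengths)
        weights = (fine["end"] - fine["start"]).to_numpy()
        combined = np.nansum(fine["pi"].to_numpy() * weights) / weights.sum()
        assert combined == pytest.approx(coarse["pi"].iloc[0], rel=1e-9)

    def test_small_population_rejected(self):
        vm = make_matrix([[0], [1]])
        pops = PopulationMap({"s0": "A", "s1": "B"})
        with pytest.raises(ValueError):
            window_pi(vm, pops, "A")


class TestHeterozygosity:
    def test_direct_quotient(self):
        vm = make_matrix([[1, 1, 1, 1, 1, 0], [0, 0, 0, 0, 0, 0]])
        het = sample_heterozygosity(vm, 1000)
        assert het["s0"] == 0.005
        assert het["s1"] == 0.0

    def test_hand_counted_fixture(self, neutral_panel_10):
        vm, _, _ = neutral_panel_10
        het = sample_heterozygosity(vm, 1_000_000)
        manual = (vm.genotypes == 1).sum(axis=1) / 1_000_000
        np.testing.assert_allclose(het.to_numpy(), manual)


class TestWcFst:
    def test_matches_literal_oracle(self, two_pop_matrix):
        vm, pops = two_pop_matrix
        a, b, c = wc_fst_components(vm, pops.sample_rows(vm, "A"),
                                    pops.sample_rows(vm, "B"))
        oracle = wc_oracle(vm.genotypes[:4].tolist(), vm.genotypes[4:].tolist())
        for j, (oa, ob, oc) in enumerate(oracle):
            assert a[j] == pytest.approx(oa, abs=1e-10)
            assert b[j] == pytest.approx(ob, abs=1e-10)
            assert c[j] == pytest.approx(oc, abs=1e-10)

    def test_fixed_difference_gives_one(self):
        g = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(np.int8)
        vm = make_matrix(g)
        pops = PopulationMap({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        fst = genome_fst(vm, pops, "A", "B")
        assert fst == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, neutral_panel_10):
        vm, _, _ = neutral_panel_10
        # split one panel arbitrarily into two "populations"
        pops = PopulationMap({s: ("A" if i % 2 == 0 else "B")
                              for i, s in enumerate(vm.sample_ids)})
        assert abs(genome_fst(vm, pops, "A", "B")) < 0.02

    def test_symmetry_exact(self, two_pop_matrix):
        vm, pops = two_pop_matrix
        ws = WindowSpec(size=1000, step=1000)
        ab = wc_fst(vm, pops, "A", "B", ws, {"chr1": 1000})
        ba = wc_fst(vm, pops, "B", "A", ws, {"chr1": 1000})
        np.testing.assert_array_equal(ab["fst"].to_numpy(), ba["fst"].to_numpy())

    def test_permutation_invariance(self, two_pop_matrix):
        vm, pops = two_pop_matrix
        shuffled = vm.take_samples([3, 1, 0, 2, 7, 5, 6, 4])
        f1 = genome_fst(vm, pops, "A", "B")
        f2 = genome_fst(shuffled, pops, "A", "B")
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_island_model_against_frequency_oracle(self):
        """Two-deme equilibrium migration: WC estimate within 20% of a
        Hudson-style frequency-based FST (1 - Hw/Hb) on the same data."""
        from hazelpop.demography import two_pop_split_model
        from hazelpop.simulate import SimConfig, simulate_genotypes

        m = two_pop_split_model(T=5.0, m=2.0)
        cfg = SimConfig(model=m, sample_sizes={"p1": 8, "p2": 8}, L=2e6,
                        mu=2e-4, rho=2e-4, seed=13)
        vm, pops, _ = simulate_genotypes(cfg)
        wc = genome_fst(vm, pops, "p1", "p2")
        # independent oracle: ratio-of-averages Hudson estimator
        rows1 = pops.sample_rows(vm, "p1")
        rows2 = pops.sample_rows(vm, "p2")
        a1, t1 = vm.allele_counts(rows1)
        a2, t2 = vm.allele_counts(rows2)
        p1 = a1 / t1
        p2 = a2 / t2
        hw = (2 * p1 * (1 - p1) * t1 / (t1 - 1)) + (2 * p2 * (1 - p2) * t2 / (t2 - 1))
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        hudson = 1.0 - (hw.sum() / 2.0) / hb.sum()
        assert wc == pytest.approx(hudson, rel=0.20)


class TestLnPiRatio:
    def test_identities(self):
        grid = pd.DataFrame({"chrom": ["c"] * 2, "start": [0, 100],
                             "end": [100, 200]})
        num = grid.assign(pi=[1e-3, np.e * 1e-3])
        den = grid.assign(pi=[1e-3, 1e-3])
        out = ln_pi_ratio(num, den)
        assert out["ln_pi_ratio"].iloc[0] == pytest.approx(0.0)
        assert out["ln_pi_ratio"].iloc[1] == pytest.approx(1.0)

    def test_zero_or_missing_gives_nan(self):
        grid = pd.DataFrame({"chrom": ["c"] * 2, "start": [0, 100],
                             "end": [100, 200]})
        out = ln_pi_ratio(grid.assign(pi=[0.0, np.nan]), grid.assign(pi=[1.0, 1.0]))
        assert out["ln_pi_ratio"].isna().all()

    def test_mismatched_grids_rejected(self):
        a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100], "pi": [1.0]})
        b = pd.DataFrame({"chrom": ["c"], "start": [50], "end": [150], "pi": [1.0]})
        with pytest.raises(ValueError):
            ln_pi_ratio(a, b)


class TestLdDecay:
    def test_duplicated_site_r2_one(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]],
                     dtype=np.int8)
        vm = make_matrix(g, pos=[0, 1000])
        pops = PopulationMap({f"s{i}": "A" for i in range(6)})
        curve = ld_decay(vm, pops, "A", max_dist=10_000)
        b = 1000 // 100
        assert curve.mean_r2[b] == pytest.approx(1.0)

    def test_half_decay_on_constructed_crossing(self):
        # monotone curve with max 0.8 crossing 0.4 at 12 kb
        edges = np.arange(0, 20_001, 100)
        smooth = _isotonic_decreasing(
            np.where(edges[:-1] < 12_000, 0.8, 0.3), np.ones(len(edges) - 1))
        half = 0.8 / 2
        first = np.flatnonzero(smooth <= half)[0]
        assert edges[first] == 12_000

    def test_monotone_smoothing_and_decay(self, neutral_panel_10):
        vm, pops, _ = neutral_panel_10
        sub = vm.take_sites(np.arange(min(400, vm.n_sites)))
        curve = ld_decay(sub, pops, "p1", max_dist=50_000, bin_width=1000)
        filled = curve.n_pairs > 0
        sm = _isotonic_decreasing(curve.mean_r2[filled],
                                  curve.n_pairs[filled].astype(float))
        assert (np.diff(sm) <= 1e-12).all()
        assert np.isfinite(curve.max_r2)
        assert 0 <= curve.max_r2 <= 1

    def test_no_pairs_is_error(self):
        vm = make_matrix([[0], [1], [2], [1]], pos=[0])
        pops = PopulationMap({f"s{i}": "A" for i in range(4)})
        with pytest.raises(ValueError):
            ld_decay(vm, pops, "A", max_dist=100)
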