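"""Sweep scan scores, empirical thresholds and the intersection caller."""

import numpy as np
import pandas as pd
import pytest

from hazelpop.annotate import Gene, GeneAnnotation
from hazelpop.sweeps import (
    SweepRegion,
    SweepScanConfig,
    intersect_sweeps,
    quantile_threshold,
    regions_to_genes,
    xpclr_scan,
    xpclr_to_windows,
)
from hazelpop.variants import PopulationMap

from conftest import make_matrix


class TestQuantileThreshold:
    def test_type7_arithmetic_on_1_to_100(self):
        values = np.arange(1.0, 101.0)
        cutoff, flags = quantile_threshold(values, 0.95)
        assert cutoff == pytest.approx(95.05)
        assert flags.sum() == 5
        assert set(values[flags]) == {96, 97, 98, 99, 100}

    def test_degenerate_distribution_flags_all(self, caplog):
        with caplog.at_level("WARNING"):
            cutoff, flags = quantile_threshold(np.zeros(25), 0.95)
        assert "degenerate" in caplog.text
        assert flags.all()

    def test_outlier_flagged_and_missing_excluded(self):
        values = np.concatenate([np.random.default_rng(1).normal(size=20),
                                 [50.0], [np.nan]])
        cutoff, flags = quantile_threshold(values, 0.95)
        assert flags[20]
        assert not flags[21]  # NaN never flagged

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_threshold(np.arange(10.0), 0.95)


def window_grid(n, size=100):
    return pd.DataFrame({
        "chrom": ["c"] * n,
        "start": np.arange(n) * size,
        "end": (np.arange(n) + 1) * size,
    })


class TestIntersectSweeps:
    def test_disjoint_sets_empty(self):
        w = window_grid(10)
        f1 = np.zeros(10, bool); f1[1] = True
        f2 = np.zeros(10, bool); f2[5] = True
        f3 = np.zeros(10, bool); f3[8] = True
        assert intersect_sweeps(w, f1, f2, f3) == []

    def test_adjacent_windows_merge(self):
        w = window_grid(10)
        joint = np.zeros(10, bool)
        joint[5] = joint[6] = True
        regions = intersect_sweeps(w, joint, joint.copy(), joint.copy())
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (500, 700)

    def test_randomized_flags_match_bruteforce(self):
        rng = np.random.default_rng(12)
        w = window_grid(60)
        for _ in range(20):
            f1, f2, f3 = (rng.random(60) < 0.3 for _ in range(3))
            regions = intersect_sweeps(w, f1, f2, f3)
            # brute-force oracle: joint windows, then interval merge
            joint = sorted(np.flatnonzero(f1 & f2 & f3))
            merged = []
            for i in joint:
                s, e = i * 100, (i + 1) * 100
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            assert [(r.start, r.end) for r in regions] == \
                [tuple(m) for m in merged]
            # subset property
            flagged_windows = {(r["start"], r["end"])
                               for _, r in w[f1 & f2 & f3].iterrows()}
            for s, e in flagged_windows:
                assert any(r.start <= s and e <= r.end for r in regions)


class TestRegionsToGenes:
    def make_annotation(self):
        genes = [Gene(id=f"g{i}", chrom="c", start=i * 1000, end=i * 1000 + 500,
                      strand="+") for i in range(10)]
        return GeneAnnotation(genes=genes)

    def test_empty_and_multi_gene_regions(self):
        ann = self.make_annotation()
        regions = [
            SweepRegion("c", 600, 900),        # gap between genes
            SweepRegion("c", 900, 2200),       # overlaps g1, g2
            SweepRegion("c", 5400, 6100),      # overlaps g5, g6
        ]
        psgs = regions_to_genes(regions, ann)
        assert regions[0].genes == []
        assert regions[1].genes == ["g1", "g2"]
        assert regions[2].genes == ["g5", "g6"]
        assert psgs == ["g1", "g2", "g5", "g6"]

    def test_hand_overlap_table(self):
        ann = self.make_annotation()
        # 1-bp overlap at a gene edge counts; bookended does not
        r_touch = SweepRegion("c", 499, 600)
        r_book = SweepRegion("c", 500, 600)
        regions_to_genes([r_touch, r_book], ann)
        assert r_touch.genes == ["g0"]
        assert r_book.genes == []


class TestXpclrScan:
    def test_identical_populations_score_zero(self, neutral_panel_10):
        vm, _, _ = neutral_panel_10
        # same individuals in both roles -> identical frequencies
        dup = vm.take_samples(list(range(10)) + list(range(10)))
        dup.sample_ids = [f"r{i}" for i in range(10)] + [f"o{i}" for i in range(10)]
        pops2 = PopulationMap({f"r{i}": "ref" for i in range(10)} |
                              {f"o{i}": "obj" for i in range(10)})
        scan = xpclr_scan(dup, pops2, "ref", "obj",
                          SweepScanConfig(grid_step_bp=10_000),
                          {"chr1": 1_000_000})
        finite = scan["xpclr"].dropna()
        assert (finite == 0).all()

    def test_single_snp_window_identical_freqs_zero(self):
        # p_ref = p_obj = 0.5 at the single assayed SNP
        vm = make_matrix(np.array([[0], [1], [2], [1], [0], [1], [2], [1]],
                                  dtype=np.int8), pos=[100])
        pops = PopulationMap({f"s{i}": ("R" if i < 4 else "O")
                              for i in range(8)})
        cfg = SweepScanConfig(grid_step_bp=100, min_snps=1)
        scan = xpclr_scan(vm, pops, "R", "O", cfg, {"chr1": 300})
        vals = scan["xpclr"].dropna()
        assert (vals.abs() < 1e-9).all()

    def test_sparse_windows_missing(self, neutral_panel_10):
        vm, pops, _ = neutral_panel_10
        cfg = SweepScanConfig(grid_step_bp=50_000, min_snps=10 ** 6)
        scan = xpclr_scan(vm, pops, "p1", "p1", cfg, {"chr1": 1_000_000})
        assert scan["xpclr"].isna().all()

    def test_monotone_in_sweep_strength(self):
        """Raising the planted haplotype frequency never lowers the
        score at the sweep center (same seed)."""
        from hazelpop.demography import two_pop_split_model
        from hazelpop.simulate import SimConfig, plant_sweep, simulate_genotypes

        m = two_pop_split_model(T=0.3, m=1.0)
        cfg = SimConfig(model=m, sample_sizes={"p1": 10, "p2": 10}, L=2e6,
                        mu=2e-4, rho=2e-4, seed=51)
        vm, pops, _ = simulate_genotypes(cfg)
        region = ("chr1", 900_000, 1_100_000)
        scfg = SweepScanConfig(grid_step_bp=20_000)
        lengths = {"chr1": 2_000_000}
        scores = []
        for freq in (0.5, 0.7, 0.9, 1.0):
            planted = plant_sweep(vm, pops, "p2", region, final_freq=freq,
                                  seed=99)
            scan = xpclr_scan(planted, pops, "p1", "p2", scfg, lengths)
            center = scan[(scan["pos"] >= 900_000) & (scan["pos"] < 1_100_000)]
            scores.append(np.nanmax(center["xpclr"]))
        assert all(b >= a - 1e-6 for a, b in zip(scores, scores[1:]))

    def test_small_populations_rejected(self, neutral_panel_10):
        vm, pops, _ = neutral_panel_10
        small = PopulationMap({s: ("A" if i < 2 else "B")
                               for i, s in enumerate(vm.sample_ids)})
        with pytest.raises(ValueError):
            xpclr_scan(vm, small, "A", "B")


class TestXpclrToWindows:
    def test_max_within_window(self):
        scan = pd.DataFrame({
            "chrom": ["c"] * 5,
            "pos": [0, 50, 100, 150, 250],
            "n_snps": [5] * 5,
            "xpclr": [1.0, 7.0, 2.0, np.nan, 3.0],
        })
        from hazelpop.diversity import WindowSpec
        out = xpclr_to_windows(scan, WindowSpec(size=100, step=100), {"c": 300})
        assert list(out["xpclr"]) == [7.0, 2.0, 3.0]
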