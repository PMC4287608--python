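import itertools
import math

import numpy as np
import pandas as pd
import pytest

import noiseqtl as nq
from noiseqtl.mapping import (
    LOD_CAP,
    ScanResult,
    cim_scan,
    find_peaks,
    genotype_probabilities,
    percent_effect,
    permutation_threshold,
    select_cofactors,
)


def _haldane(d):
    return (1 - math.exp(-2 * d / 100)) / 2


def _ril_R(d):
    r = _haldane(d)
    return 2 * r / (1 + 2 * r)


class TestGenotypeProbabilities:
    def test_observed_marker_probability_is_exact(self, gmap5, geno316, grid316):
        markers = grid316.marker_columns()
        signed = geno316.signed()
        for _, row in markers.iloc[:10].iterrows():
            col = grid316.probs[:, row.name]
            expected = (signed[row["marker"]].to_numpy() + 1) / 2
            assert np.array_equal(col, expected)

    def test_midpoint_concordant_flanks_matches_enumeration(self):
        # flanks 20 cM apart, both allele A, query at the midpoint: enumerate
        # the two possible paths (A-A-A vs A-B-A) with R at 10 cM
        gmap = nq.GeneticMap(
            pd.DataFrame({"chromosome": ["c"] * 2, "marker": ["l", "r"],
                          "cm": [0.0, 20.0]})
        )
        lines = [f"L{i}" for i in range(4)]
        alleles = pd.DataFrame(
            {"l": ["A", "A", "B", "A"], "r": ["A", "B", "B", "A"]}, index=lines
        )
        cyto = pd.Series(["A_CYT", "A_CYT", "B_CYT", "B_CYT"], index=lines)
        geno = nq.RILGenotypes(alleles=alleles, cytoplasm=cyto)
        grid = genotype_probabilities(gmap, geno, step=10.0)
        mid = grid.positions[(grid.positions["cm"] == 10.0)].index[0]
        R = _ril_R(10.0)
        p_concordant = (1 - R) ** 2 / ((1 - R) ** 2 + R**2)
        assert grid.probs[0, mid] == pytest.approx(p_concordant, abs=1e-12)
        assert grid.probs[3, mid] == pytest.approx(p_concordant, abs=1e-12)
        # discordant flanks: symmetry forces 1/2
        assert grid.probs[1, mid] == pytest.approx(0.5, abs=1e-12)
        # both flanks B: complement
        assert grid.probs[2, mid] == pytest.approx(1 - p_concordant, abs=1e-12)

    def test_missing_flank_uses_nearest_informative(self):
        gmap = nq.GeneticMap(
            pd.DataFrame({"chromosome": ["c"] * 3, "marker": ["a", "b", "c"],
                          "cm": [0.0, 10.0, 20.0]})
        )
        alleles = pd.DataFrame({"a": ["A"], "b": [np.nan], "c": ["A"]}, index=["L1"])
        geno = nq.RILGenotypes(alleles=alleles,
                               cytoplasm=pd.Series(["A_CYT"], index=["L1"]))
        grid = genotype_probabilities(gmap, geno, step=10.0)
        at_b = grid.positions[grid.positions["cm"] == 10.0].index[0]
        R = _ril_R(10.0)
        expected = (1 - R) ** 2 / ((1 - R) ** 2 + R**2)
        assert grid.probs[0, at_b] == pytest.approx(expected, abs=1e-12)

    def test_invalid_step_rejected(self, gmap5, geno316):
        with pytest.raises(ValueError):
            genotype_probabilities(gmap5, geno316, step=0.0)


class TestSelectCofactors:
    def test_zero_cofactors(self, grid316):
        assert select_cofactors(grid316, np.zeros(316) + np.arange(316), 0) == []

    def test_noiseless_single_marker_selected_first(self, grid316, geno316):
        y = geno316.signed()["mIV_05"].to_numpy() * 2.0
        chosen = select_cofactors(grid316, y, 3)
        assert chosen[0] == "mIV_05"

    def test_greedy_selection_matches_exhaustive_oracle(self):
        # tiny population, 3 markers: replay greedy forward selection by
        # brute-force RSS over all candidate orderings
        rng = np.random.default_rng(0)
        gmap = nq.GeneticMap(
            pd.DataFrame({"chromosome": ["c"] * 3, "marker": ["a", "b", "c"],
                          "cm": [0.0, 30.0, 60.0]})
        )
        geno = nq.simulate_ril_genotypes(gmap, nq.DesignSpec(n_lines=50, seed=4))
        grid = genotype_probabilities(gmap, geno, step=5.0)
        X = geno.signed().to_numpy()
        y = X[:, 0] * 0.5 + X[:, 2] * 0.3 + rng.normal(0, 0.5, 50)

        def rss(cols):
            A = np.column_stack([np.ones(50)] + [X[:, j] for j in cols])
            res = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            return res @ res

        names = ["a", "b", "c"]
        oracle = []
        remaining = [0, 1, 2]
        for _ in range(2):
            best = min(remaining, key=lambda j: (rss(oracle + [j]), j))
            oracle.append(best)
            remaining.remove(best)
        assert select_cofactors(grid, y, 2) == [names[j] for j in oracle]


class TestCIMScan:
    def test_marker_lod_equals_single_marker_regression(self, grid316, geno316):
        # zero-cofactor scan at genotyped markers == brute-force OLS LOD
        rng = np.random.default_rng(1)
        x = geno316.signed()["mII_10"].to_numpy()
        y = 0.4 * x + rng.normal(0, 1, 316)
        scan = cim_scan(grid316, y, cofactors=(), window=10.0)
        markers = grid316.marker_columns()
        signed = geno316.signed()
        n = 316
        for _, row in markers.sample(12, random_state=0).iterrows():
            xm = signed[row["marker"]].to_numpy()
            A = np.column_stack([np.ones(n), xm])
            res = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            rss1 = res @ res
            rss0 = ((y - y.mean()) ** 2).sum()
            lod = (n / 2) * math.log10(rss0 / rss1)
            got = scan.table.loc[row.name, "lod"]
            assert got == pytest.approx(lod, abs=1e-8)

    def test_additive_effect_is_half_class_difference(self, grid316, geno316):
        x = geno316.signed()["mIII_10"].to_numpy()
        y = 1.5 * x + 10.0
        scan = cim_scan(grid316, y, cofactors=(), window=10.0)
        idx = grid316.positions[grid316.positions["marker"] == "mIII_10"].index[0]
        assert scan.table.loc[idx, "effect"] == pytest.approx(1.5, abs=1e-9)
        assert scan.table.loc[idx, "capped"]  # perfect fit hits the LOD cap
        assert scan.table.loc[idx, "lod"] == LOD_CAP

    def test_infinite_window_drops_all_cofactors_on_own_chromosome(self, grid316, geno316):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 316)
        cofs = ["mI_05", "mI_10", "mI_15"]
        wide = cim_scan(grid316, y, cofactors=cofs, window=np.inf)
        plain = cim_scan(grid316, y, cofactors=(), window=10.0)
        chr1 = wide.table["chromosome"] == "I"
        np.testing.assert_allclose(
            wide.table.loc[chr1, "lod"], plain.table.loc[chr1, "lod"], atol=1e-10
        )

    def test_affine_phenotype_invariance(self, grid316):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 316)
        s1 = cim_scan(grid316, y, cofactors=("mV_03",), window=10.0)
        s2 = cim_scan(grid316, 5.0 * y + 2.0, cofactors=("mV_03",), window=10.0)
        np.testing.assert_allclose(s1.table["lod"], s2.table["lod"], atol=1e-8)
        np.testing.assert_allclose(
            5.0 * s1.table["effect"], s2.table["effect"], atol=1e-8
        )

    def test_lod_nonnegative_everywhere(self, grid316):
        rng = np.random.default_rng(4)
        scan = cim_scan(grid316, rng.normal(0, 1, 316), cofactors=("mII_05",))
        assert (scan.table["lod"] >= 0).all()

    def test_too_few_lines_rejected(self, grid316):
        y = pd.Series(np.nan, index=list(grid316.lines))
        y.iloc[:5] = 1.0
        with pytest.raises(ValueError):
            cim_scan(grid316, y)


class TestPermutationThreshold:
    def test_seed_reproducible_and_alpha_monotone(self, grid316):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 316)
        t1 = permutation_threshold(grid316, y, n_perm=50, alpha=0.05, seed=9)
        t2 = permutation_threshold(grid316, y, n_perm=50, alpha=0.05, seed=9)
        t3 = permutation_threshold(grid316, y, n_perm=50, alpha=0.20, seed=9)
        assert t1 == t2
        assert t3 <= t1

    def test_constant_phenotype_rejected(self, grid316):
        with pytest.raises(ValueError, match="degenerate"):
            permutation_threshold(grid316, np.ones(316), n_perm=10)

    def test_threshold_is_order_statistic(self, grid316, monkeypatch):
        # with alpha = 0.05 and n_perm = 20 the threshold must equal the
        # 19th order statistic of the permutation maxima
        import noiseqtl.mapping as mapping_mod

        recorded = []
        orig = mapping_mod._scan_arrays

        def spy(*args, **kwargs):
            out = orig(*args, **kwargs)
            recorded.append(out[0].max())
            return out

        monkeypatch.setattr(mapping_mod, "_scan_arrays", spy)
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 316)
        thr = permutation_threshold(grid316, y, n_perm=20, alpha=0.05, seed=1,
                                    reselect_cofactors=False)
        assert thr == sorted(recorded)[int(np.ceil(0.95 * 20)) - 1]


class TestFindPeaks:
    @staticmethod
    def _scan_from_lods(lods, chrom="I"):
        table = pd.DataFrame(
            {"chromosome": chrom, "cm": np.arange(len(lods), dtype=float),
             "lod": lods, "effect": 0.1, "capped": False}
        )
        return ScanResult(table=table)

    def test_flat_scan_no_peaks(self):
        assert find_peaks(self._scan_from_lods([0.0] * 10), 2.0) == []

    def test_dip_rule_separates_two_peaks(self):
        # hand-built curve: maxima 3 and 2.5 with a dip to 0.5 between
        peaks = find_peaks(self._scan_from_lods([0, 1, 3, 1, 0.5, 2.5, 1, 0]), 2.0)
        assert [(p.peak_cm, p.lod) for p in peaks] == [(2.0, 3.0), (5.0, 2.5)]

    def test_shallow_dip_merges_maxima(self):
        # dip of only 0.6 below the smaller maximum: one peak
        peaks = find_peaks(self._scan_from_lods([0, 1, 3, 2.4, 2.9, 1, 0]), 2.0)
        assert len(peaks) == 1
        assert peaks[0].peak_cm == 2.0

    def test_one_lod_interval_contains_peak_and_clips(self):
        peaks = find_peaks(self._scan_from_lods([2.5, 3.0, 2.4, 1.5, 1.0]), 2.0)
        (p,) = peaks
        assert p.interval == (0.0, 2.0)
        assert p.interval[0] <= p.peak_cm <= p.interval[1]

    def test_empty_scan(self):
        scan = ScanResult(table=pd.DataFrame(
            columns=["chromosome", "cm", "lod", "effect", "capped"]))
        assert find_peaks(scan, 2.0) == []

    def test_invalid_lod_min(self):
        with pytest.raises(ValueError):
            find_peaks(self._scan_from_lods([1.0]), 0.0)


class TestPercentEffect:
    @pytest.mark.parametrize(
        "a, mean, expected", [(0.0, 1.0, 0.0), (0.1, 1.0, 20.0), (-0.25, 2.5, 20.0)]
    )
    def test_values(self, a, mean, expected):
        assert percent_effect(a, mean) == pytest.approx(expected)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_effect(0.1, 0.0)
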