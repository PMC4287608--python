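import numpy as np
import pandas as pd
import pytest

import noiseqtl as nq
from noiseqtl.marker_models import (
    additive_anova,
    build_network,
    interactions_per_locus,
    network_to_sif,
    pairwise_epistasis_anova,
)
from statsmodels.stats.multitest import multipletests


def _balanced_markers(n_reps=4):
    """Fully crossed 2x2x2 design: 8 cells x n_reps lines, orthogonal codes."""
    rows = []
    for a in (-1.0, 1.0):
        for b in (-1.0, 1.0):
            for c in (-1.0, 1.0):
                for _ in range(n_reps):
                    rows.append((a, b, c))
    idx = [f"L{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=["mA", "mB", "CYTOPLASM"], index=idx)


class TestAdditiveAnova:
    def test_constant_phenotype_zero_everything(self):
        M = _balanced_markers()
        y = pd.Series(3.0, index=M.index)
        res = additive_anova(y, M, "t")
        assert np.allclose(res.table["ss"], 0.0)
        assert np.allclose(res.table["effect"], 0.0)

    def test_type3_equals_type1_in_orthogonal_design(self):
        rng = np.random.default_rng(0)
        M = _balanced_markers()
        y = pd.Series(0.5 * M["mA"] + 0.2 * M["mB"] + rng.normal(0, 1, len(M)),
                      index=M.index)
        res = additive_anova(y, M, "t")
        # sequential (Type I) SS computed by adding terms in order
        yv = y.to_numpy()
        X = np.ones((len(M), 1))
        prev_rss = ((yv - yv.mean()) ** 2).sum()
        for term in ["mA", "mB", "CYTOPLASM"]:
            X = np.column_stack([X, M[term].to_numpy()])
            res_v = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
            rss = res_v @ res_v
            ss1 = prev_rss - rss
            prev_rss = rss
            ss3 = res.table.set_index("term").loc[term, "ss"]
            assert ss3 == pytest.approx(ss1, abs=1e-10)

    def test_f_and_p_match_statsmodels_ols(self):
        # independent route: statsmodels OLS + Type III anova on 8 lines x 2
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        M = _balanced_markers(n_reps=2)[["mA", "mB"]]
        y = pd.Series(0.8 * M["mA"] + rng.normal(0, 1, len(M)), index=M.index)
        res = additive_anova(y, M, "t")
        df = M.assign(y=y)
        fit = smf.ols("y ~ mA + mB", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=3)
        for term in ("mA", "mB"):
            mine = res.table.set_index("term").loc[term]
            assert mine["F"] == pytest.approx(tab.loc[term, "F"], rel=1e-8)
            assert mine["p"] == pytest.approx(tab.loc[term, "PR(>F)"], abs=1e-10)

    def test_effect_is_allelic_substitution(self):
        M = _balanced_markers()
        y = pd.Series(np.where(M["mA"] > 0, 10.0, 6.0), index=M.index)
        res = additive_anova(y, M, "t")
        assert res.table.set_index("term").loc["mA", "effect"] == pytest.approx(4.0)

    def test_confounded_marker_dropped_with_warning(self):
        M = _balanced_markers()
        M["dup"] = M["mA"]
        y = pd.Series(np.arange(len(M), dtype=float), index=M.index)
        with pytest.warns(UserWarning, match="confounded"):
            res = additive_anova(y, M, "t")
        assert "dup" in res.dropped

    def test_class_with_single_line_rejected(self):
        M = _balanced_markers(n_reps=2)
        M.iloc[1:, 0] = 1.0  # leaves one line at -1
        y = pd.Series(np.arange(len(M), dtype=float), index=M.index)
        with pytest.raises(ValueError, match="genotype class"):
            additive_anova(y, M, "t")


class TestPairwiseEpistasis:
    def test_pure_interaction_has_zero_main_effects(self):
        M = _balanced_markers()
        y = pd.Series(M["mA"] * M["mB"] * 2.0, index=M.index)
        res = pairwise_epistasis_anova(y, M, "t")
        t = res.table.set_index("term")
        assert t.loc["mA", "ss"] == pytest.approx(0.0, abs=1e-18)
        assert t.loc["mB", "ss"] == pytest.approx(0.0, abs=1e-18)
        assert t.loc["mA:mB", "ss"] > 1.0

    def test_model_has_no_three_way_terms(self):
        rng = np.random.default_rng(2)
        M = _balanced_markers()
        y = pd.Series(rng.normal(0, 1, len(M)), index=M.index)
        res = pairwise_epistasis_anova(y, M, "t")
        for term in res.table["term"]:
            assert term.count(":") <= 1

    def test_bh_adjustment_matches_hand_computation(self):
        # p = {0.01..0.05}, m = 5: step-up BH gives q = 0.05 for all
        pvals = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        q = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, 0.05)
        # and q-values are monotone nondecreasing in p on model output
        rng = np.random.default_rng(3)
        M = _balanced_markers()
        y = pd.Series(rng.normal(0, 1, len(M)), index=M.index)
        res = pairwise_epistasis_anova(y, M, "t")
        t = res.table.sort_values("p")
        assert (np.diff(t["q"]) >= -1e-12).all()

    def test_empty_cell_pair_skipped(self):
        # the (+1, +1) cell of (mA, mB) never occurs
        M = pd.DataFrame(
            {"mA": [-1.0] * 4 + [1.0] * 4,
             "mB": [1.0, 1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0],
             "mC": [1.0, -1.0] * 4},
            index=[f"L{i}" for i in range(8)],
        )
        y = pd.Series(np.random.default_rng(4).normal(0, 1, len(M)), index=M.index)
        res = pairwise_epistasis_anova(y, M, "t")
        assert ("mA", "mB") in {tuple(sorted(p)) for p in res.skipped_pairs}
        assert "mA:mB" not in res.table["term"].tolist()


class TestNetwork:
    @staticmethod
    def _result(phenotype, sig_pairs=(), sig_mains=(), loci=("a", "b", "c")):
        from itertools import combinations
        rows = []
        for l in loci:
            rows.append({"term": l, "kind": "main", "ss": 1.0, "df": 1, "F": 1.0,
                         "p": 0.001 if l in sig_mains else 0.9,
                         "q": 0.001 if l in sig_mains else 0.9,
                         "effect": 0.1, "testable": True})
        for a, b in combinations(loci, 2):
            sig = (a, b) in sig_pairs or (b, a) in sig_pairs
            rows.append({"term": f"{a}:{b}", "kind": "interaction", "ss": 1.0,
                         "df": 1, "F": 1.0, "p": 0.001 if sig else 0.9,
                         "q": 0.001 if sig else 0.9, "effect": 0.1,
                         "testable": True})
        from noiseqtl.marker_models import MarkerModelResult
        return MarkerModelResult(phenotype=phenotype, table=pd.DataFrame(rows),
                                 rss=1.0, df_resid=10)

    def test_no_significant_interactions_gives_edgeless_network(self):
        res = [self._result(f"p{i}") for i in range(5)]
        net = build_network(res, edge_min=0.1)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 3

    def test_breadth_counts_fraction_of_phenotypes(self):
        res = [self._result(f"p{i}", sig_pairs=(("a", "b"),) if i < 3 else ())
               for i in range(10)]
        net = build_network(res, edge_min=0.1)
        assert net.edges[("a", "b")]["breadth"] == pytest.approx(0.3)

    def test_edge_exactly_at_boundary_retained(self):
        res = [self._result(f"p{i}", sig_pairs=(("a", "c"),) if i == 0 else ())
               for i in range(10)]
        net = build_network(res, edge_min=0.10)
        assert ("a", "c") in net.edges
        net2 = build_network(res, edge_min=0.11)
        assert ("a", "c") not in net2.edges

    def test_result_order_invariance(self):
        res = [self._result(f"p{i}", sig_pairs=(("b", "c"),) if i % 2 else ())
               for i in range(6)]
        g1 = build_network(res, edge_min=0.1)
        g2 = build_network(res[::-1], edge_min=0.1)
        assert set(g1.edges) == set(g2.edges)
        assert {n: d["breadth"] for n, d in g1.nodes(data=True)} == \
               {n: d["breadth"] for n, d in g2.nodes(data=True)}

    def test_interactions_per_locus_star(self):
        import networkx as nx
        g = nx.star_graph(["hub", "s1", "s2", "s3", "s4"])
        out = interactions_per_locus(g)
        assert out.set_index("locus").loc["hub", "interactions"] == 4
        assert out["median_interactions"].iloc[0] == 1

    def test_edgeless_median_zero(self):
        import networkx as nx
        g = nx.empty_graph(["a", "b"])
        out = interactions_per_locus(g)
        assert (out["interactions"] == 0).all()
        assert out["median_interactions"].iloc[0] == 0

    def test_sif_round_trip(self, tmp_path):
        res = [self._result(f"p{i}", sig_pairs=(("a", "b"),)) for i in range(4)]
        net = build_network(res, edge_min=0.1)
        path = tmp_path / "net.sif"
        network_to_sif(net, path)
        lines = path.read_text().splitlines()
        assert "a\tepistasis\tb" in lines


class TestCytoplasmInteractionRecovery:
    def test_planted_cyto_nuclear_interaction_breadth(self, gmap5, geno316, design316):
        # cytoplasm x nuclear epistasis planted in 30% of traits shows up as
        # a CYTOPLASM-locus edge with breadth near 0.3
        traits = tuple(f"t{i}" for i in range(30))
        arch = nq.TrueArchitecture(
            traits=traits,
            epistatic_pairs=(
                nq.EpistaticPair(("CYTOPLASM", 0), ("II", 30.0), 0.8, traits[:9]),
            ),
        )
        obs = nq.simulate_phenotypes(geno316, arch, design316, gmap5)
        table = nq.compute_line_cv(obs)
        values = table.line_values("grand_mean")
        markers = pd.DataFrame({
            "mII_07": geno316.signed()["mII_07"],
            "mIV_10": geno316.signed()["mIV_10"],
            "CYTOPLASM": geno316.cytoplasm_signed(),
        })
        results = [pairwise_epistasis_anova(values[t], markers, t) for t in traits]
        net = build_network(results, edge_min=0.1)
        assert ("CYTOPLASM", "mII_07") in net.edges
        assert net.edges[("CYTOPLASM", "mII_07")]["breadth"] == pytest.approx(0.3, abs=0.1)
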