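"""Edge candidates, sign-consistency meta-filter, Fisher combination, PUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicnet import (AnalysisConfig, build_edge_candidates, causality_filter,
                     fisher_combine, meta_filter_edges, select_network_features,
                     spearman_edge)
from omicnet.simulate import Module, SimDesign, simulate_multiomic_study


class TestSpearmanEdge:
    def test_monotone_identity(self):
        rho, p, n = spearman_edge([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0) and p <= 1e-12 and n == 5

    def test_antitone(self):
        rho, _, _ = spearman_edge([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_worked_example(self):
        # d = (0,-1,1,-1,1), sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, p, n = spearman_edge([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)
        ref = stats.spearmanr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_agrees_with_rank_then_pearson_on_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = rng.integers(5, 25)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _, _ = spearman_edge(x, y)
            ref = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(ref, abs=1e-12)

    def test_pairwise_complete_and_floor(self):
        rho, p, n = spearman_edge([1, 2, np.nan, 4, 5, 6], [2, 3, 9, 5, 6, 7])
        assert n == 5 and rho == pytest.approx(1.0) and p > 0

    def test_constant_vector_skipped(self):
        rho, p, n = spearman_edge([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_below_floor_n(self):
        rho, p, n = spearman_edge([1, 2], [1, 2])
        assert np.isnan(rho) and n == 2

    def test_exact_permutation_small_n(self):
        rho, p, _ = spearman_edge([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], pvalue="exact")
        # exhaustive two-sided permutation p over 5! rank assignments
        rx = np.arange(1, 6)
        import itertools
        count = sum(abs(np.corrcoef(rx, pm)[0, 1]) >= abs(rho) - 1e-12
                    for pm in itertools.permutations(rx))
        assert p == pytest.approx(count / 120)


class TestFisherCombine:
    def test_all_ones_identity(self):
        stat, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and p == 1.0

    def test_single_p_passthrough(self):
        _, p = fisher_combine([0.2])
        assert p == pytest.approx(0.2, rel=1e-12)

    def test_worked_chi_square_value(self):
        stat, p = fisher_combine([0.05, 0.05, 0.05])
        assert stat == pytest.approx(-6 * np.log(0.05), rel=1e-12)
        assert stat == pytest.approx(17.974, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(stat, 6), rel=1e-12)
        assert p == pytest.approx(6.3e-3, abs=5e-4)

    def test_zero_clipped_with_floor(self):
        stat, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(stat) and 0 < p < 1


class TestSelectNetworkFeatures:
    def test_threshold_application(self, cfg):
        d = pd.DataFrame({"q": [0.05, 0.2, 0.09]}, index=["a", "b", "c"])
        assert select_network_features(d, cfg) == ["a", "c"]

    def test_all_above_threshold_empty(self, cfg):
        d = pd.DataFrame({"q": [0.5, 0.9]}, index=["a", "b"])
        assert select_network_features(d, cfg) == []


class TestBuildCandidates:
    def test_pair_count(self, tiny_study):
        cand = build_edge_candidates(tiny_study, tiny_study.features_of_class("gene"),
                                     ["disease", "treatA", "treatB"],
                                     block_pairs=[("gene", "gene")])
        assert len(cand) == 45  # 10 choose 2

    def test_constant_feature_candidates_dropped(self, tiny_study):
        tiny_study.values.loc["gen_0", tiny_study.samples_in_group("disease")] = 1.0
        cand = build_edge_candidates(tiny_study, tiny_study.features_of_class("gene"),
                                     ["disease", "treatA", "treatB"])
        assert not ((cand["node_u"] == "gen_0") | (cand["node_v"] == "gen_0")).any()
        assert len(cand) == 36  # 9 choose 2

    def test_block_pairs_labelled(self, tiny_study):
        cand = build_edge_candidates(tiny_study, list(tiny_study.values.index),
                                     ["disease", "treatA"])
        assert set(cand["block_pair"]) == {"gene-gene", "gene-lipid", "lipid-lipid"}
        assert (cand["block_pair"] == "gene-lipid").sum() == 50

    def test_chunked_equals_unchunked(self, tiny_study):
        feats = list(tiny_study.values.index)
        a = build_edge_candidates(tiny_study, feats, ["disease", "treatA"], chunk=4)
        b = build_edge_candidates(tiny_study, feats, ["disease", "treatA"], chunk=10000)
        pd.testing.assert_frame_equal(a, b)

    def test_matrix_path_matches_per_edge_function(self, tiny_study):
        cand = build_edge_candidates(tiny_study, ["gen_0", "gen_1", "gen_2"],
                                     ["disease", "treatA"])
        for row in cand.itertuples():
            x = tiny_study.values.loc[row.node_u, tiny_study.samples_in_group("disease")]
            y = tiny_study.values.loc[row.node_v, tiny_study.samples_in_group("disease")]
            rho, p, _ = spearman_edge(x, y)
            assert row.rho_disease == pytest.approx(rho, abs=1e-12)
            assert row.p_disease == pytest.approx(p, rel=1e-9)

    def test_too_small_group_rejected(self, tiny_study):
        small = tiny_study.sample_meta.copy()
        small.loc[small.index[-7:], "group"] = "disease"
        tiny_study.sample_meta = small
        with pytest.raises(ValueError):
            build_edge_candidates(tiny_study, ["gen_0", "gen_1"], ["treatB", "disease"])


def _cand(rows):
    base = {"node_u": "u", "node_v": "v", "block_pair": "gene-gene"}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec.update(node_u=f"u{i}", node_v=f"v{i}")
        rec.update(r)
        signs = np.sign([rec["rho_g1"], rec["rho_g2"], rec["rho_g3"]])
        rec["sign"] = int(signs[0]) if (signs == signs[0]).all() and signs[0] != 0 else 0
        stat = -2 * sum(np.log([rec["p_g1"], rec["p_g2"], rec["p_g3"]]))
        rec["fisher_stat"] = stat
        rec["fisher_p"] = stats.chi2.sf(stat, 6)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestMetaFilter:
    def test_sign_inconsistency_rejected(self, cfg):
        cand = _cand([{"rho_g1": 0.8, "rho_g2": 0.7, "rho_g3": -0.6,
                       "p_g1": 0.01, "p_g2": 0.01, "p_g3": 0.01}])
        assert len(meta_filter_edges(cand, cfg)) == 0

    def test_consistent_strong_edge_passes(self, cfg):
        cand = _cand([{"rho_g1": 0.9, "rho_g2": 0.8, "rho_g3": 0.85,
                       "p_g1": 0.001, "p_g2": 0.002, "p_g3": 0.001}])
        kept = meta_filter_edges(cand, cfg)
        assert len(kept) == 1 and kept["sign"].iloc[0] == 1

    def test_group_p_threshold(self, cfg):
        cand = _cand([{"rho_g1": 0.8, "rho_g2": 0.7, "rho_g3": 0.6,
                       "p_g1": 0.1, "p_g2": 0.25, "p_g3": 0.01}])
        assert len(meta_filter_edges(cand, cfg)) == 0

    def test_fisher_worked_value_passes_step_iii(self, cfg):
        cand = _cand([{"rho_g1": 0.5, "rho_g2": 0.4, "rho_g3": 0.8,
                       "p_g1": 0.1, "p_g2": 0.15, "p_g3": 0.01}])
        assert cand["fisher_stat"].iloc[0] == pytest.approx(17.61, abs=0.01)
        assert cand["fisher_p"].iloc[0] == pytest.approx(7.3e-3, abs=2e-4)
        assert len(meta_filter_edges(cand, cfg)) == 1

    def test_monotone_in_every_threshold(self):
        rng = np.random.default_rng(5)
        rows = [{"rho_g1": rng.uniform(-1, 1), "rho_g2": rng.uniform(-1, 1),
                 "rho_g3": rng.uniform(-1, 1), "p_g1": rng.uniform(0.001, 1),
                 "p_g2": rng.uniform(0.001, 1), "p_g3": rng.uniform(0.001, 1)}
                for _ in range(400)]
        cand = _cand(rows)
        loose = AnalysisConfig(edge_group_p=0.5, edge_fisher_p=0.2, edge_fdr=0.3)
        kept_loose = meta_filter_edges(cand, loose)
        for kw in ({"edge_group_p": 0.2}, {"edge_fisher_p": 0.05}, {"edge_fdr": 0.1}):
            tight = AnalysisConfig(**{**{"edge_group_p": 0.5, "edge_fisher_p": 0.2,
                                         "edge_fdr": 0.3}, **kw})
            kept_tight = meta_filter_edges(cand, tight)
            assert set(kept_tight["node_u"]) <= set(kept_loose["node_u"])


class TestCausalityFilter:
    def _edges(self):
        return pd.DataFrame({
            "node_u": ["a", "a", "b", "c"],
            "node_v": ["b", "c", "c", "d"],
            "sign": [-1, -1, 1, 1],
            "block_pair": ["gene-gene"] * 4,
        })

    def test_sign_rule_and_puc_ratio(self):
        # fc: a,b,c up, d down
        fc = pd.DataFrame({"log2FC": [1.0, 2.0, 0.5, -1.0]},
                          index=["a", "b", "c", "d"])
        net, rep = causality_filter(self._edges(), fc)
        # a-b: both up, rho<0 -> unexpected (removed); a-c same -> unexpected;
        # b-c: both up, rho>0 -> expected; c-d: opposite fc, rho>0 -> unexpected
        assert rep.n_candidates == 4 and rep.n_unexpected == 3
        assert rep.puc == pytest.approx(0.75)
        assert set(net.edges()) == {("b", "c")}

    def test_expected_negative_edge_kept(self):
        edges = pd.DataFrame({"node_u": ["a"], "node_v": ["d"], "sign": [-1],
                              "block_pair": ["gene-gene"]})
        fc = pd.DataFrame({"log2FC": [1.0, -1.0]}, index=["a", "d"])
        net, rep = causality_filter(edges, fc)
        assert rep.n_unexpected == 0 and net.has_edge("a", "d")

    def test_missing_fc_dropped_and_counted(self):
        fc = pd.DataFrame({"log2FC": [1.0, 2.0, 0.5]}, index=["a", "b", "c"])
        _, rep = causality_filter(self._edges(), fc)
        assert rep.n_missing_fc == 1 and rep.n_candidates == 3

    def test_node_attributes_attached(self, cfg):
        edges = pd.DataFrame({"node_u": ["a"], "node_v": ["b"], "sign": [1],
                              "block_pair": ["gene-gene"]})
        fc = pd.DataFrame({"log2FC": [1.0, 2.0]}, index=["a", "b"])
        meta = pd.DataFrame({"omic_class": ["gene", "gene"]}, index=["a", "b"])
        cats = pd.DataFrame({"category": ["A_only", None]}, index=["a", "b"])
        net, _ = causality_filter(edges, fc, feature_meta=meta, categories=cats)
        assert net.nodes["a"]["omic_class"] == "gene"
        assert net.nodes["a"]["category"] == "A_only"
        assert net.nodes["b"]["log2FC_disease"] == 2.0


class TestPlantedModuleRecovery:
    def test_null_retains_almost_nothing_and_planted_recovered(self):
        """No planted correlation -> near-empty edge set; rho=0.8 module -> recovered."""
        design = SimDesign(n_per_group=50,
                           n_features={"gene": 60, "lipid": 0, "metabolite": 0,
                                       "biochemical": 0, "anthropometric": 0},
                           n_affected={}, modules=(Module("gene", 20, 0.8),),
                           rng_seed=123)
        study, truth = simulate_multiomic_study(design)
        cand = build_edge_candidates(study, list(study.values.index),
                                     ["disease", "treatA", "treatB"])
        kept = meta_filter_edges(cand, AnalysisConfig())
        kept_pairs = {frozenset((u, v)) for u, v in zip(kept["node_u"], kept["node_v"])}
        true_pairs = {frozenset((u, v)) for u, v, _ in truth.true_edges}
        recall = len(kept_pairs & true_pairs) / len(true_pairs)
        fdr = len(kept_pairs - true_pairs) / max(len(kept_pairs), 1)
        assert recall >= 0.8
        assert fdr <= 0.15
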