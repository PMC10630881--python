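"""QC filtering, cluster marker statistics, cell-type assignment, LR overlay."""

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicnet import (AnalysisConfig, assign_genes_to_celltypes,
                     cluster_interaction_summary, cluster_marker_stats,
                     overlay_ligand_receptor, qc_filter_cells)
from omicnet.simulate import simulate_single_cell
from omicnet.singlecell import NOT_ASSIGNED


def _constructed_counts():
    """6 cells x 5 genes with known QC violations."""
    genes = ["mt-a", "g1", "g2", "g3", "g4"]
    x = np.array([
        [100, 2000, 2000, 900, 0],      # library 5000 (boundary), mito 2% -> kept
        [100, 2000, 1000, 900, 0],      # library 4000 -> removed (small library)
        [900, 2100, 2000, 1000, 0],     # library 6000, mito 15% -> removed
        [100, 3000, 2000, 900, 0],      # kept
        [100, 3000, 2000, 900, 5],      # kept
        [100, 3000, 2000, 895, 5],      # kept
    ])
    obs = pd.DataFrame({"cluster": ["A", "A", "B", "B", "A", "B"]},
                       index=[f"c{i}" for i in range(6)])
    return ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=genes))


class TestQcFilter:
    def test_exact_rule_application(self):
        adata, report = qc_filter_cells(_constructed_counts())
        assert report["removed_small_library"] == 1
        assert report["removed_high_mito"] == 1
        assert report["n_cells_out"] == 4
        # g4 detected in 0 remaining cells -> removed by the <3-cells rule
        assert "g4" not in adata.var_names
        assert report["removed_genes_low_detection"] == 1
        assert report["n_cells_out"] + report["removed_cells_total"] == report["n_cells_in"]
        assert report["n_genes_out"] + report["removed_genes_low_detection"] \
            == report["n_genes_in"]

    def test_library_boundary_is_strict_less_than(self):
        adata = _constructed_counts()
        out, report = qc_filter_cells(adata)
        assert "c0" in out.obs_names  # library exactly 5000 is kept

    def test_gene_detected_in_two_cells_removed(self):
        x = np.full((5, 4), 2000)
        x[:, 3] = 0
        x[0, 3] = x[1, 3] = 5  # detected in 2 cells only
        adata = ad.AnnData(X=x, obs=pd.DataFrame(index=[f"c{i}" for i in range(5)]),
                           var=pd.DataFrame(index=["g1", "g2", "g3", "g4"]))
        out, _ = qc_filter_cells(adata)
        assert "g4" not in out.var_names

    def test_non_integer_counts_rejected(self):
        adata = _constructed_counts()
        adata.X = adata.X.astype(float) + 0.5
        with pytest.raises(ValueError):
            qc_filter_cells(adata)

    def test_everything_removed_raises(self):
        adata = _constructed_counts()
        with pytest.raises(ValueError, match="empty"):
            qc_filter_cells(adata, library_min=10 ** 9)


class TestClusterMarkerStats:
    def _adata(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(10, size=(60, 6)).astype(int)
        x[:30, 0] += 60       # g0 elevated in cluster A only
        obs = pd.DataFrame({"cluster": ["A"] * 30 + ["B"] * 30},
                           index=[f"c{i}" for i in range(60)])
        return ad.AnnData(X=x, obs=obs,
                          var=pd.DataFrame(index=[f"g{i}" for i in range(6)]))

    def test_exclusive_gene_maximal_in_own_cluster(self):
        stats = cluster_marker_stats(self._adata())
        g0 = stats[stats["gene"] == "g0"].set_index("cluster")
        assert g0.loc["A", "log2fc"] > 0
        assert g0.loc["A", "mean_norm"] > g0.loc["B", "mean_norm"]

    def test_constant_gene_degenerate(self):
        # equal library sizes, one gene flat across cells: p = 1, log2FC = 0
        x = np.array([[10, 4, 6], [10, 4, 6], [10, 4, 6],
                      [4, 10, 6], [4, 10, 6], [4, 10, 6]])
        adata = ad.AnnData(X=x,
                           obs=pd.DataFrame({"cluster": ["A"] * 3 + ["B"] * 3},
                                            index=[f"c{i}" for i in range(6)]),
                           var=pd.DataFrame(index=["g0", "g1", "gflat"]))
        stats = cluster_marker_stats(adata)
        flat = stats[stats["gene"] == "gflat"]
        assert (flat["p"] == 1.0).all()
        assert flat["log2fc"].abs().max() == 0.0

    def test_one_row_per_gene_cluster(self):
        stats = cluster_marker_stats(self._adata())
        assert len(stats) == 6 * 2
        assert not stats.duplicated(subset=["gene", "cluster"]).any()

    def test_single_cluster_rejected(self):
        adata = self._adata()
        adata.obs["cluster"] = "A"
        with pytest.raises(ValueError):
            cluster_marker_stats(adata)


class TestAssignment:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cluster", "mean_norm",
                                           "log2fc", "p"])

    def test_single_passing_cluster_assigned(self, cfg):
        stats = self._stats([("btc", "cholangiocyte", 5.0, 2.0, 0.001),
                             ("btc", "hepatocyte", 0.5, -1.0, 0.5)])
        out = assign_genes_to_celltypes(stats, cfg)
        assert out["btc"] == "cholangiocyte"

    def test_two_passing_clusters_highest_mean_wins(self, cfg):
        stats = self._stats([("g", "A", 5.0, 1.0, 0.001),
                             ("g", "B", 9.0, 1.0, 0.001)])
        assert assign_genes_to_celltypes(stats, cfg)["g"] == "B"

    def test_uniform_gene_not_assigned(self, cfg):
        stats = self._stats([("g", "A", 5.0, 0.0, 0.9),
                             ("g", "B", 5.0, 0.0, 0.9)])
        assert assign_genes_to_celltypes(stats, cfg)["g"] == NOT_ASSIGNED

    def test_exact_tie_breaks_lexicographically(self, cfg):
        stats = self._stats([("g", "B", 5.0, 1.0, 0.001),
                             ("g", "A", 5.0, 1.0, 0.001)])
        assert assign_genes_to_celltypes(stats, cfg)["g"] == "A"

    def test_every_assignment_satisfies_thresholds(self, cfg):
        adata, truth = simulate_single_cell(n_clusters=6, n_genes=150, n_cells=900,
                                            seed=3)
        filtered, _ = qc_filter_cells(adata)
        stats = cluster_marker_stats(filtered)
        out = assign_genes_to_celltypes(stats, cfg)
        assigned = out[out != NOT_ASSIGNED]
        merged = stats.set_index(["gene", "cluster"])
        for gene, cluster in assigned.items():
            row = merged.loc[(gene, cluster)]
            assert row["mean_norm"] > cfg.sc_umi_min
            assert row["log2fc"] > cfg.sc_log2fc_min
            assert row["p"] < cfg.sc_p_max

    def test_planted_marker_recovery(self, cfg):
        adata, truth = simulate_single_cell(n_clusters=8, n_genes=200, n_cells=1200,
                                            seed=11)
        filtered, _ = qc_filter_cells(adata)
        stats = cluster_marker_stats(filtered)
        out = assign_genes_to_celltypes(stats, cfg)
        markers = {g: c for g, c in truth.marker_map.items() if g in out.index}
        correct = sum(out[g] == c for g, c in markers.items())
        assert correct / len(markers) >= 0.95


class TestLigandReceptorOverlay:
    def _net(self):
        g = nx.Graph()
        g.add_edge("Btc", "Egfr", sign=1)
        g.add_edge("Egfr", "Tgfb2", sign=1)
        return g

    def test_known_pair_flagged(self):
        lr = pd.DataFrame({"ligand": ["Btc"], "receptor": ["Egfr"]})
        g = overlay_ligand_receptor(self._net(), lr,
                                    {"Btc": "cholangiocyte", "Egfr": "hepatocyte"})
        assert g.edges["Btc", "Egfr"]["lr_supported"]
        assert not g.edges["Egfr", "Tgfb2"]["lr_supported"]
        assert g.nodes["Btc"]["lr_role"] == "ligand"
        assert g.nodes["Egfr"]["lr_role"] == "receptor"
        assert g.edges["Btc", "Egfr"]["cell_type_u"] in ("cholangiocyte", "hepatocyte")

    def test_ligand_without_network_receptor(self):
        lr = pd.DataFrame({"ligand": ["Btc"], "receptor": ["Notaround"]})
        g = overlay_ligand_receptor(self._net(), lr)
        assert g.nodes["Btc"]["lr_role"] == "ligand"
        assert not any(d["lr_supported"] for _, _, d in g.edges(data=True))

    def test_empty_table_all_none(self):
        lr = pd.DataFrame({"ligand": [], "receptor": []})
        g = overlay_ligand_receptor(self._net(), lr)
        assert all(d["lr_role"] == "none" for _, d in g.nodes(data=True))


class TestClusterInteractionSummary:
    def test_edge_counting(self):
        g = nx.Graph([("a1", "b1"), ("a2", "b1"), ("a1", "b2"), ("a1", "a2")])
        assign = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = cluster_interaction_summary(g, assign)
        assert out.loc["A", "B"] == 3 and out.loc["B", "A"] == 3
        assert out.attrs["cluster_sizes"] == {"A": 2, "B": 2}

    def test_no_intercluster_edges(self):
        g = nx.Graph([("a1", "a2"), ("b1", "b2")])
        out = cluster_interaction_summary(g, {"a1": "A", "a2": "A",
                                              "b1": "B", "b2": "B"})
        assert out.loc["A", "B"] == 0

    def test_symmetry_on_random_graphs(self):
        rng = np.random.default_rng(13)
        g = nx.gnm_random_graph(30, 80, seed=13)
        assign = {n: f"C{rng.integers(4)}" for n in g.nodes()}
        out = cluster_interaction_summary(g, assign)
        assert (out.to_numpy() == out.to_numpy().T).all()


def test_mtx_round_trip(tmp_path):
    from omicnet import read_mtx_dir, write_mtx_dir
    adata, _ = simulate_single_cell(n_clusters=3, n_genes=40, n_cells=60, seed=5)
    write_mtx_dir(adata, tmp_path)
    back = read_mtx_dir(tmp_path)
    assert back.shape == adata.shape
    assert list(back.var_names) == list(adata.var_names)
    assert (back.obs["cluster"] == adata.obs["cluster"]).all()
    x0 = np.asarray(adata.X)
    x1 = np.asarray(back.X.todense())
    assert (x0 == x1).all()
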