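"""Cell-type overlay: QC filtering of single-cell counts, per-cluster
marker statistics, gene-to-cell-type assignment, and ligand-receptor
annotation of the reconstructed network.

Cluster labels are consumed as input (``obs["cluster"]``); no clustering,
dimensionality reduction or doublet detection happens here.  Assignment
follows the marker rules used for overlaying cell types onto network
genes: a cluster is a candidate for a gene when the gene's mean normalized
expression there exceeds ``sc_umi_min`` with log2 fold change over all
other cells above ``sc_log2fc_min`` at rank-sum p below ``sc_p_max``; the
candidate with the highest mean wins, otherwise the gene is
"Not assigned".
"""

from __future__ import annotations

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .data import AnalysisConfig, logger

NOT_ASSIGNED = "Not assigned"
LIBRARY_MIN = 5000        # cells below this total UMI count are removed
MITO_FRAC_MAX = 0.12      # cells above this mitochondrial fraction are removed
MIN_CELLS_PER_GENE = 3    # genes detected in fewer remaining cells are removed


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def read_mtx_dir(directory, matrix="matrix.mtx", features="features.tsv",
                 barcodes="barcodes.tsv", clusters="clusters.tsv") -> ad.AnnData:
    """Read a cells x genes count matrix from MatrixMarket + sidecar lists.

    ``features``/``barcodes`` are one-id-per-line text files matching the
    matrix dimensions (genes x cells on disk, the common convention;
    transposed on load).  A ``clusters`` file (barcode <tab> label, or one
    label per line) populates ``obs["cluster"]`` when present.
    """
    from pathlib import Path
    from scipy.io import mmread

    directory = Path(directory)
    x = sparse.csr_matrix(mmread(directory / matrix)).T  # cells x genes
    var_names = (directory / features).read_text().split()
    obs_names = (directory / barcodes).read_text().split()
    adata = ad.AnnData(X=x, obs=pd.DataFrame(index=obs_names),
                       var=pd.DataFrame(index=var_names))
    cpath = directory / clusters
    if cpath.exists():
        lines = [ln.split("\t") for ln in cpath.read_text().splitlines() if ln]
        if all(len(ln) >= 2 for ln in lines):
            mapping = {a: b for a, b, *_ in lines}
            adata.obs["cluster"] = [mapping[b] for b in obs_names]
        else:
            adata.obs["cluster"] = [ln[0] for ln in lines]
    return adata


def write_mtx_dir(adata: ad.AnnData, directory) -> None:
    """Write counts as MatrixMarket (genes x cells) + features/barcodes/clusters."""
    from pathlib import Path
    from scipy.io import mmwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(_dense(adata.X).T))
    (directory / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    if "cluster" in adata.obs:
        lines = [f"{b}\t{c}" for b, c in adata.obs["cluster"].items()]
        (directory / "clusters.tsv").write_text("\n".join(lines) + "\n")


def qc_filter_cells(adata: ad.AnnData, mito_genes=None,
                    library_min: float = LIBRARY_MIN,
                    mito_frac_max: float = MITO_FRAC_MAX,
                    min_cells: int = MIN_CELLS_PER_GENE):
    """Standard single-cell QC: small libraries and high-mito cells out, then rare genes.

    ``mito_genes`` defaults to genes whose name starts with ``mt-``
    (case-insensitive).  Returns ``(filtered AnnData, report dict)`` with
    per-rule removal counts; raises if nothing survives.
    """
    x = _dense(adata.X).astype(float)
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    if mito_genes is None:
        mito_mask = adata.var_names.str.lower().str.startswith("mt-")
    else:
        mito_mask = adata.var_names.isin(list(mito_genes))

    library = x.sum(axis=1)
    mito_frac = np.divide(x[:, mito_mask].sum(axis=1), library,
                          out=np.zeros_like(library), where=library > 0)
    small = library < library_min
    high_mito = mito_frac > mito_frac_max
    keep_cells = ~(small | high_mito)

    detected = (x[keep_cells] > 0).sum(axis=0)
    keep_genes = detected >= min_cells

    report = {
        "n_cells_in": adata.n_obs,
        "n_genes_in": adata.n_vars,
        "removed_small_library": int(small.sum()),
        "removed_high_mito": int((high_mito & ~small).sum()),
        "removed_cells_total": int((~keep_cells).sum()),
        "removed_genes_low_detection": int((~keep_genes).sum()),
        "n_cells_out": int(keep_cells.sum()),
        "n_genes_out": int(keep_genes.sum()),
    }
    if report["n_cells_out"] == 0 or report["n_genes_out"] == 0:
        raise ValueError(f"empty matrix after QC filtering: {report}")
    out = adata[keep_cells, keep_genes].copy()
    logger.info("QC: %d->%d cells (%d small library, %d high mito), %d->%d genes",
                report["n_cells_in"], report["n_cells_out"],
                report["removed_small_library"], report["removed_high_mito"],
                report["n_genes_in"], report["n_genes_out"])
    return out, report


def normalize_counts(adata: ad.AnnData, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` library-size normalization (linear scale)."""
    x = _dense(adata.X).astype(float)
    lib = x.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return x / lib * scale


def cluster_marker_stats(adata: ad.AnnData, cluster_key: str = "cluster",
                         scale: float = 1e4) -> pd.DataFrame:
    """Per gene x cluster expression statistics against all other cells pooled.

    Normalization is counts-per-10k; means and the pseudocount-1 log2 fold
    change are computed on the normalized linear scale, the two-sided
    Wilcoxon rank-sum p on the log1p-normalized values.  Clusters with
    fewer than three cells are flagged.
    """
    labels = adata.obs[cluster_key].astype(str)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    norm = normalize_counts(adata, scale)
    logn = np.log1p(norm)
    rows = []
    for c in clusters:
        mask = (labels == c).to_numpy()
        if mask.sum() < 3:
            logger.warning("cluster %s has %d cells (<3); stats flagged", c, mask.sum())
        mean_in = norm[mask].mean(axis=0)
        mean_out = norm[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        res = stats.mannwhitneyu(logn[mask], logn[~mask], axis=0,
                                 alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        const = np.ptp(logn, axis=0) == 0
        p[const] = 1.0
        frac = (norm[mask] > 0).mean(axis=0)
        rows.append(pd.DataFrame({
            "gene": adata.var_names, "cluster": c, "mean_norm": mean_in,
            "log2fc": log2fc, "p": p, "frac_detected": frac,
            "n_cells": int(mask.sum()), "flagged": mask.sum() < 3,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out


def assign_genes_to_celltypes(cluster_stats: pd.DataFrame,
                              cfg: AnalysisConfig | None = None) -> pd.Series:
    """Assign each gene to at most one cell type by the marker thresholds.

    Candidate clusters satisfy mean normalized expression > ``sc_umi_min``,
    log2FC > ``sc_log2fc_min`` and p < ``sc_p_max``; the candidate with the
    highest mean expression wins (exact mean ties break lexicographically
    by cluster name, logged).  Genes with no candidate are "Not assigned".
    """
    cfg = cfg or AnalysisConfig()
    s = cluster_stats
    ok = (s["mean_norm"] > cfg.sc_umi_min) & (s["log2fc"] > cfg.sc_log2fc_min) \
        & (s["p"] < cfg.sc_p_max)
    cand = s.loc[ok].sort_values(["gene", "mean_norm", "cluster"],
                                 ascending=[True, False, True])
    tied = cand.duplicated(subset=["gene", "mean_norm"], keep=False)
    if tied.any():
        logger.info("%d exact mean tie(s) broken lexicographically by cluster name",
                    int(cand.loc[tied, "gene"].nunique()))
    best = cand.drop_duplicates(subset="gene", keep="first").set_index("gene")["cluster"]
    genes = pd.Index(s["gene"].unique(), name="gene")
    out = pd.Series(NOT_ASSIGNED, index=genes, dtype=object, name="cell_type")
    out.loc[best.index] = best
    logger.info("assigned %d/%d genes to a cell type", int((out != NOT_ASSIGNED).sum()),
                len(out))
    return out


def overlay_ligand_receptor(network: nx.Graph, lr_table: pd.DataFrame,
                            assignment: pd.Series | dict | None = None) -> nx.Graph:
    """Tag network nodes as ligand / receptor / both and flag supported edges.

    An edge is ``lr_supported`` when its endpoints form a known
    ligand-receptor pair (either orientation).  Each tag carries the cell
    types of both endpoints when an assignment is supplied.  Unmatched
    table rows are logged; the graph is annotated in place and returned.
    """
    ligands = set(lr_table["ligand"])
    receptors = set(lr_table["receptor"])
    pairs = {frozenset((l, r)) for l, r in zip(lr_table["ligand"], lr_table["receptor"])}
    unmatched = sum(1 for l, r in zip(lr_table["ligand"], lr_table["receptor"])
                    if l not in network or r not in network)
    if unmatched:
        logger.info("%d LR pair(s) with an endpoint absent from the network", unmatched)
    assign = dict(assignment) if assignment is not None else {}
    for n in network.nodes():
        role = "none"
        if n in ligands and n in receptors:
            role = "both"
        elif n in ligands:
            role = "ligand"
        elif n in receptors:
            role = "receptor"
        network.nodes[n]["lr_role"] = role
        if n in assign:
            network.nodes[n]["cell_type"] = assign[n]
    for u, v, d in network.edges(data=True):
        d["lr_supported"] = frozenset((u, v)) in pairs
        if d["lr_supported"]:
            d["cell_type_u"] = assign.get(u, NOT_ASSIGNED)
            d["cell_type_v"] = assign.get(v, NOT_ASSIGNED)
    return network


def cluster_interaction_summary(network: nx.Graph, assignment,
                                weight_attr: str | None = None) -> pd.DataFrame:
    """Symmetric cluster x cluster table of inter-cluster network edges.

    Entries count edges with one endpoint assigned to each cluster; with
    ``weight_attr`` (e.g. a per-group rho column) the mean absolute weight
    is reported in a companion ``<pair>_weight`` structure via ``attrs``.
    """
    assign = dict(assignment)
    clusters = sorted({c for c in assign.values() if c != NOT_ASSIGNED})
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    counts = pd.DataFrame(0, index=clusters, columns=clusters)
    weights: dict[tuple, list] = {}
    for u, v, d in network.edges(data=True):
        cu, cv = assign.get(u, NOT_ASSIGNED), assign.get(v, NOT_ASSIGNED)
        if cu == NOT_ASSIGNED or cv == NOT_ASSIGNED or cu == cv:
            continue
        counts.loc[cu, cv] += 1
        counts.loc[cv, cu] += 1
        if weight_attr and weight_attr in d:
            weights.setdefault(tuple(sorted((cu, cv))), []).append(abs(d[weight_attr]))
    if weight_attr:
        counts.attrs["mean_abs_weight"] = {k: float(np.mean(v))
                                           for k, v in weights.items()}
    comp = pd.Series({c: sum(1 for g, cc in assign.items() if cc == c)
                      for c in clusters}, name="n_genes")
    counts.attrs["cluster_sizes"] = comp.to_dict()
    return counts
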