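"""Multi-omic co-variation network reconstruction.

Edges are candidate Spearman correlations computed separately within each
non-reference experimental group (the disease-diet arms; the reference group
is excluded), then meta-filtered: the correlation must keep one strict sign
in every group, every per-group p must clear ``edge_group_p``, the Fisher
combined p must clear ``edge_fisher_p``, and the BH q within the edge's
omic-class block family must clear ``edge_fdr``.  Finally the fold-change
causality filter removes "unexpected" edges whose correlation sign
contradicts the product of the two endpoints' disease fold-change signs;
the fraction removed is reported as the PUC (proportion of unexpected
correlations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import AnalysisConfig, OmicsStudy, logger
from .differential import bh_fdr

P_FLOOR = 1e-300  # floor for zero p-values entering log


def select_network_features(disease: pd.DataFrame, cfg: AnalysisConfig | None = None):
    """Features passing the node gate for network construction (disease q < node_fdr)."""
    cfg = cfg or AnalysisConfig()
    sel = disease.index[(disease["q"] < cfg.node_fdr).fillna(False)]
    if len(sel) == 0:
        logger.warning("no features pass the node gate (q < %.3g); network will be empty",
                       cfg.node_fdr)
    return list(sel)


def spearman_edge(x, y, min_n: int = 4, pvalue: str = "t"):
    """Spearman rank correlation for one candidate edge.

    Pairwise-complete observations; average ranks for ties; two-sided p from
    the t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 df, or
    by exhaustive permutation (``pvalue="exact"``, n <= 8).  Returns
    ``(rho, p, n)``; NaN rho for constant input (edge to be skipped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_n:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant vector in spearman_edge; edge skipped")
        return np.nan, np.nan, n
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    if pvalue == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total, n
    if abs(rho) >= 1.0:
        logger.warning("|rho| = 1 at n=%d; p set to machine floor", n)
        return float(np.sign(rho)), P_FLOOR, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(rho), float(p), n


def fisher_combine(p, floor: float = P_FLOOR):
    """Fisher's method: ``stat = -2 * sum(ln p_i)``, chi-square upper tail on 2k df."""
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        logger.warning("p-value(s) <= 0 clipped to %.3g in fisher_combine", floor)
        p = np.clip(p, floor, None)
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(stat), float(stats.chi2.sf(stat, 2 * len(p)))


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 (rows), NaN-free input."""
    return stats.rankdata(a, axis=1)


def _group_corr(values: np.ndarray):
    """Spearman rho and t-approximation p matrices for a complete F x n block."""
    n = values.shape[1]
    ranks = _rank_rows(values)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    denom = 1.0 - rho * rho
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = P_FLOOR
    const = sd == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    return rho, p, const


def build_edge_candidates(study: OmicsStudy, features, groups,
                          block_pairs=None, min_samples: int = 4,
                          chunk: int = 512) -> pd.DataFrame:
    """All unordered feature-pair candidates with per-group Spearman statistics.

    ``groups`` are the experimental arms pooled per-group for correlation
    (by convention the disease-diet arms, excluding the reference group).
    ``block_pairs`` optionally restricts to specific omic-class pairs, e.g.
    ``[("gene", "gene"), ("gene", "lipid")]``; by default every class pair
    among the selected features is produced.  Candidate rows carry
    per-group rho/p/n, the shared sign (if consistent), the Fisher combined
    statistic/p, and the block label.  Pair assembly walks the feature list
    in chunks so the full pair set is never materialized at once beyond the
    output table itself.
    """
    features = list(features)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for the per-group correlation meta-analysis")
    idx = {f: i for i, f in enumerate(features)}
    sub = study.values.loc[features]
    classes = study.feature_meta.loc[features, "omic_class"].to_numpy()

    per_group = {}
    dropped_const: set[int] = set()
    for g in groups:
        vals = sub[study.samples_in_group(g)].to_numpy(dtype=float)
        if vals.shape[1] < min_samples:
            raise ValueError(f"group {g!r} has {vals.shape[1]} samples; need >= {min_samples}")
        if np.isnan(vals).any():
            rho, p = _pairwise_complete_corr(vals, min_samples)
            const = np.zeros(len(features), dtype=bool)
        else:
            rho, p, const = _group_corr(vals)
        per_group[g] = (rho, p, vals.shape[1])
        dropped_const |= set(np.where(const)[0])
    if dropped_const:
        logger.info("%d feature(s) constant within a group; their candidates dropped",
                    len(dropped_const))

    wanted = None
    if block_pairs is not None:
        wanted = {tuple(sorted(bp)) for bp in block_pairs}

    frames = []
    nf = len(features)
    for start in range(0, nf, chunk):
        stop = min(start + chunk, nf)
        iu, ju = np.triu_indices(nf, k=1)
        keep = (iu >= start) & (iu < stop)
        iu, ju = iu[keep], ju[keep]
        if len(iu) == 0:
            continue
        block = np.array([
            "-".join(sorted((a, b))) for a, b in zip(classes[iu], classes[ju])
        ])
        if wanted is not None:
            bmask = np.array([tuple(sorted((a, b))) in wanted
                              for a, b in zip(classes[iu], classes[ju])])
            iu, ju, block = iu[bmask], ju[bmask], block[bmask]
            if len(iu) == 0:
                continue
        data = {
            "node_u": np.asarray(features, dtype=object)[iu],
            "node_v": np.asarray(features, dtype=object)[ju],
            "block_pair": block,
        }
        signs = []
        logp = np.zeros(len(iu))
        valid = np.ones(len(iu), dtype=bool)
        k = 0
        for g in groups:
            rho, p, ng = per_group[g]
            rg, pg = rho[iu, ju], p[iu, ju]
            data[f"rho_{g}"] = rg
            data[f"p_{g}"] = pg
            data[f"n_{g}"] = ng
            signs.append(np.sign(rg))
            valid &= ~np.isnan(rg)
            logp += np.log(np.clip(pg, P_FLOOR, None))
            k += 1
        signs = np.vstack(signs)
        consistent = valid & np.all(signs == signs[0], axis=0) & (signs[0] != 0)
        data["sign"] = np.where(consistent, signs[0], 0).astype(int)
        stat = -2.0 * logp
        data["fisher_stat"] = np.where(valid, stat, np.nan)
        data["fisher_p"] = np.where(valid, stats.chi2.sf(stat, 2 * k), np.nan)
        frame = pd.DataFrame(data)
        frames.append(frame[valid | True].loc[valid])  # drop constant-feature pairs
    if not frames:
        return pd.DataFrame(columns=["node_u", "node_v", "block_pair", "sign",
                                     "fisher_stat", "fisher_p"])
    out = pd.concat(frames, ignore_index=True)
    logger.info("built %d edge candidates over %d features, %d groups",
                len(out), nf, len(groups))
    return out


def _pairwise_complete_corr(vals: np.ndarray, min_n: int):
    """Slow pairwise-complete Spearman for matrices with missing values."""
    f = vals.shape[0]
    rho = np.full((f, f), np.nan)
    p = np.full((f, f), np.nan)
    for i in range(f):
        for j in range(i + 1, f):
            r, pv, n = spearman_edge(vals[i], vals[j], min_n=min_n)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return rho, p


def meta_filter_edges(candidates: pd.DataFrame, cfg: AnalysisConfig | None = None,
                      groups=None, global_bh: bool = False) -> pd.DataFrame:
    """Retain candidates passing the four-step meta-filter.

    (i) strict shared correlation sign across all groups; (ii) every
    per-group p < ``edge_group_p``; (iii) Fisher combined p <
    ``edge_fisher_p``; (iv) BH q < ``edge_fdr``, with BH applied to the
    Fisher p of all candidates separately within each block-pair family
    (or globally with ``global_bh``).  Computing q over the full candidate
    family keeps the cascade monotone in every threshold.
    """
    cfg = cfg or AnalysisConfig()
    if candidates.empty:
        return candidates.assign(q_edge=pd.Series(dtype=float))
    pcols = [c for c in candidates.columns if c.startswith("p_")]
    if groups is not None:
        pcols = [f"p_{g}" for g in groups]

    cand = candidates.copy()
    if global_bh:
        cand["q_edge"] = bh_fdr(cand["fisher_p"])
    else:
        cand["q_edge"] = np.nan
        for _, sub in cand.groupby("block_pair"):
            cand.loc[sub.index, "q_edge"] = bh_fdr(sub["fisher_p"])

    sign_ok = cand["sign"] != 0
    group_ok = np.ones(len(cand), dtype=bool)
    for c in pcols:
        group_ok &= (cand[c] < cfg.edge_group_p).to_numpy()
    fisher_ok = (cand["fisher_p"] < cfg.edge_fisher_p).to_numpy()
    q_ok = (cand["q_edge"] < cfg.edge_fdr).to_numpy()
    retained = cand.loc[sign_ok & group_ok & fisher_ok & q_ok].reset_index(drop=True)
    logger.info("meta-filter: %d candidates -> %d retained (sign %d, group-p %d, "
                "fisher %d, fdr %d)", len(cand), len(retained), int(sign_ok.sum()),
                int((sign_ok & group_ok).sum()), int((sign_ok & group_ok & fisher_ok).sum()),
                len(retained))
    return retained


@dataclass
class PUCReport:
    """Outcome of the fold-change causality filter."""

    n_candidates: int
    n_unexpected: int
    n_missing_fc: int = 0
    per_block: dict = field(default_factory=dict)

    @property
    def puc(self) -> float:
        """Proportion of unexpected correlations among evaluable candidates."""
        if self.n_candidates == 0:
            return 0.0
        return self.n_unexpected / self.n_candidates


def causality_filter(edges: pd.DataFrame, disease: pd.DataFrame,
                     feature_meta: pd.DataFrame | None = None,
                     categories: pd.DataFrame | None = None,
                     sign_col: str = "sign"):
    """Remove edges whose correlation sign contradicts the disease fold changes.

    An edge is *expected* iff ``sign(rho) == sign(log2FC_u) * sign(log2FC_v)``
    in the disease contrast; unexpected edges are removed and their fraction
    reported as the PUC.  Edges with an endpoint missing a fold change are
    dropped and counted separately.  Returns ``(network, report)`` where
    ``network`` is a simple undirected graph whose nodes carry omic class,
    treatment category and disease log2FC attributes.
    """
    fc = disease["log2FC"]
    known = edges["node_u"].isin(fc.index) & edges["node_v"].isin(fc.index)
    n_missing = int((~known).sum())
    if n_missing:
        logger.warning("%d edge(s) dropped: endpoint missing disease log2FC", n_missing)
    ed = edges.loc[known].copy()
    su = np.sign(fc.reindex(ed["node_u"]).to_numpy(dtype=float))
    sv = np.sign(fc.reindex(ed["node_v"]).to_numpy(dtype=float))
    expected = ed[sign_col].to_numpy() == su * sv
    ed["expected"] = expected

    per_block = {}
    if "block_pair" in ed.columns:
        for b, sub in ed.groupby("block_pair"):
            per_block[b] = {"n_candidates": len(sub),
                            "n_unexpected": int((~sub["expected"]).sum())}
    report = PUCReport(n_candidates=len(ed), n_unexpected=int((~expected).sum()),
                       n_missing_fc=n_missing, per_block=per_block)

    kept = ed.loc[expected]
    g = nx.Graph()
    nodes = pd.unique(pd.concat([kept["node_u"], kept["node_v"]]))
    for n in nodes:
        attrs = {"log2FC_disease": float(fc.loc[n])}
        if feature_meta is not None and n in feature_meta.index:
            attrs["omic_class"] = feature_meta.loc[n, "omic_class"]
        if categories is not None and n in categories.index:
            cat = categories.loc[n, "category"]
            if pd.notna(cat):
                attrs["category"] = cat
        g.add_node(n, **attrs)
    edge_cols = [c for c in kept.columns if c not in ("node_u", "node_v")]
    for row in kept.itertuples(index=False):
        d = row._asdict()
        u, v = d.pop("node_u"), d.pop("node_v")
        if u == v:
            continue
        g.add_edge(u, v, **{k: d[k] for k in edge_cols if k in d})
    logger.info("causality filter: %d candidates, %d unexpected removed (PUC=%.4f), "
                "graph has %d nodes / %d edges", report.n_candidates,
                report.n_unexpected, report.puc, g.number_of_nodes(), g.number_of_edges())
    return g, report


def reconstruct_network(study: OmicsStudy, disease: pd.DataFrame, groups,
                        cfg: AnalysisConfig | None = None,
                        categories: pd.DataFrame | None = None,
                        block_pairs=None):
    """Full cascade: node gate -> candidates -> meta-filter -> causality filter.

    Returns ``(network, puc_report, retained_edges)``.
    """
    cfg = cfg or AnalysisConfig()
    feats = select_network_features(disease, cfg)
    if not feats:
        return nx.Graph(), PUCReport(0, 0), pd.DataFrame()
    cand = build_edge_candidates(study, feats, groups, block_pairs=block_pairs)
    retained = meta_filter_edges(cand, cfg, groups=groups)
    net, report = causality_filter(retained, disease,
                                   feature_meta=study.feature_meta,
                                   categories=categories)
    return net, report, retained
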