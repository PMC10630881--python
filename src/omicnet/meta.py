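"""Cross-study meta-analysis: rank product, Fisher combination, and
extraction of direction-concordant signatures against a reference contrast.

The rank product of a gene over k studies is the geometric mean of its
per-study evidence ranks, ``RP_g = (prod_i r_gi)^(1/k)``, with rank 1 the
most extreme gene in the requested direction; consistently extreme genes
get RP near 1.  Significance comes from permuting ranks independently
within each study (restricted, per gene, to the studies where the gene is
present), or by exhaustive enumeration of the per-study rank grid when it
is small.  The two one-sided runs (up, down) are combined by reporting the
better direction with its p doubled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnalysisConfig, logger
from .differential import bh_fdr
from .network import fisher_combine, P_FLOOR

EXHAUSTIVE_LIMIT = 10 ** 5


def _ranks(tables: list[pd.DataFrame], genes: pd.Index, direction: str) -> np.ndarray:
    """Per-study evidence ranks (1 = most extreme in ``direction``), NaN where absent."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    r = np.full((len(genes), len(tables)), np.nan)
    for j, t in enumerate(tables):
        score = -t["log2FC"] if direction == "up" else t["log2FC"]
        rk = stats.rankdata(score)  # average ranks for ties; rank 1 = most extreme
        r[genes.get_indexer(t.index), j] = rk
    return r


def rank_product(tables: list[pd.DataFrame], direction: str = "up",
                 n_perm: int = 1000, seed: int = 0,
                 exhaustive: bool | None = None) -> pd.DataFrame:
    """Rank-product statistic and permutation p per gene over >= 1 studies.

    Genes are matched by table index; a gene missing from a study is ranked
    over its present studies only, against a null drawn from that same
    study subset.  ``exhaustive=None`` (default) enumerates the full rank
    grid whenever its size is at most 10^5 (exact p, no correction);
    otherwise Monte-Carlo permutation with the add-one correction
    ``p = (#{null <= obs} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = pd.Index(sorted(set().union(*[set(t.index) for t in tables])))
    ranks = _ranks(tables, genes, direction)
    present = ~np.isnan(ranks)
    k = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        logs = np.where(present, np.log(ranks, where=present, out=np.zeros_like(ranks)), 0.0)
    rp = np.exp(logs.sum(axis=1) / np.maximum(k, 1))
    rp[k == 0] = np.nan

    sizes = np.array([len(t) for t in tables])
    if exhaustive is None:
        exhaustive = bool(np.prod(sizes.astype(float)) <= EXHAUSTIVE_LIMIT) \
            and bool(present.all())

    p = np.full(len(genes), np.nan)
    if exhaustive:
        grids = np.meshgrid(*[np.arange(1, n + 1) for n in sizes], indexing="ij")
        null_rp = np.exp(sum(np.log(g) for g in grids) / len(sizes)).ravel()
        for i in range(len(genes)):
            if k[i] == 0:
                continue
            p[i] = float((null_rp <= rp[i] + 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(genes))
        for _ in range(n_perm):
            null_logs = np.zeros_like(logs)
            for j, n_j in enumerate(sizes):
                pj = present[:, j]
                perm = rng.permutation(n_j)[:pj.sum()] + 1.0
                null_logs[pj, j] = np.log(perm)
            null_rp = np.exp(null_logs.sum(axis=1) / np.maximum(k, 1))
            count += null_rp <= rp + 1e-12
        p = (count + 1.0) / (n_perm + 1.0)
        p[k == 0] = np.nan

    out = pd.DataFrame({"RP": rp, "rp_p": p, "n_studies_present": k},
                       index=genes)
    out.index.name = "gene_id"
    return out


def fisher_meta(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-gene Fisher combination of two-sided per-study p-values.

    A gene present in one study only gets that study's p back, flagged via
    ``n_studies_present``.  Also reports the per-gene majority fold-change
    direction and the fraction of studies agreeing with it.
    """
    genes = pd.Index(sorted(set().union(*[set(t.index) for t in tables])))
    pmat = np.full((len(genes), len(tables)), np.nan)
    signs = np.full((len(genes), len(tables)), np.nan)
    for j, t in enumerate(tables):
        loc = genes.get_indexer(t.index)
        pmat[loc, j] = t["p"].to_numpy()
        signs[loc, j] = np.sign(t["log2FC"].to_numpy())
    present = ~np.isnan(pmat)
    k = present.sum(axis=1)
    logs = np.where(present, np.log(np.clip(pmat, P_FLOOR, 1.0),
                                    where=present, out=np.zeros_like(pmat)), 0.0)
    stat = -2.0 * logs.sum(axis=1)
    fisher_p = stats.chi2.sf(stat, 2 * k)
    net_sign = np.nansum(signs, axis=1)
    majority = np.sign(net_sign)
    with np.errstate(invalid="ignore"):
        concord = np.where(k > 0,
                           np.nansum(signs == majority[:, None], axis=1) / np.maximum(k, 1),
                           np.nan)
    out = pd.DataFrame({"fisher_stat": stat, "fisher_p": fisher_p,
                        "n_studies_present": k, "majority_sign": majority,
                        "direction_concordance": concord}, index=genes)
    out.index.name = "gene_id"
    return out


def meta_analysis(tables: list[pd.DataFrame], n_perm: int = 1000,
                  seed: int = 0) -> pd.DataFrame:
    """Full MetaResult: two-directional rank product + Fisher per gene.

    The reported ``rp_p`` is twice the better one-sided direction's p
    (capped at 1); ``q`` is its BH adjustment over all genes.
    """
    up = rank_product(tables, "up", n_perm=n_perm, seed=seed)
    down = rank_product(tables, "down", n_perm=n_perm, seed=seed + 1)
    fish = fisher_meta(tables)
    better_up = up["rp_p"] <= down["rp_p"]
    res = fish.copy()
    res["RP"] = np.where(better_up, up["RP"], down["RP"])
    res["rp_direction"] = np.where(better_up, 1.0, -1.0)
    res["rp_p"] = np.minimum(1.0, 2.0 * np.minimum(up["rp_p"], down["rp_p"]))
    res["q"] = bh_fdr(res["rp_p"])
    logger.info("meta-analysis over %d studies, %d genes", len(tables), len(res))
    return res


def map_orthologs(table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Translate a differential table's gene namespace via a 2-column mapping.

    ``mapping`` columns: source_id, target_id.  Untranslated genes are
    dropped with a logged count; duplicate targets keep the smallest p.
    """
    m = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    keep = table.index.isin(m)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("ortholog mapping: %d gene(s) untranslated, dropped", dropped)
    out = table.loc[keep].copy()
    out.index = [m[g] for g in out.index]
    out = out.sort_values("p").loc[~out.index.duplicated(keep="first")] \
        if "p" in out.columns else out.loc[~out.index.duplicated(keep="first")]
    return out


def concordant_signature(meta: pd.DataFrame, reference: pd.DataFrame,
                         cfg: AnalysisConfig | None = None) -> list:
    """Genes significant in the meta-analysis and direction-concordant with a reference.

    Keeps genes with meta q < ``meta_fdr``, Fisher p < ``meta_fisher_p``
    and majority meta direction equal to the reference contrast's
    fold-change sign.  The reference table must share the meta table's
    (pre-mapped) gene namespace.
    """
    cfg = cfg or AnalysisConfig()
    common = meta.index.intersection(reference.index)
    if len(common) == 0:
        raise ValueError("no namespace overlap between meta result and reference")
    m = meta.loc[common]
    ref_sign = np.sign(reference.loc[common, "log2FC"])
    ok = (m["q"] < cfg.meta_fdr) & (m["fisher_p"] < cfg.meta_fisher_p) \
        & (m["majority_sign"] == ref_sign) & (m["majority_sign"] != 0)
    sig = sorted(common[ok.fillna(False)])
    logger.info("concordant signature: %d of %d genes", len(sig), len(common))
    return sig
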