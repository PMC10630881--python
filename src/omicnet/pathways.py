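"""Pathway summary scoring and hypergeometric over-representation tests.

The pathway summary metric condenses a member-gene expression block into
one number per sample: genes are median-normalized (each divided by its
across-sample median on the linear scale, then log2), and the per-sample
summary is the median across member genes; condition contrasts are then a
paired t-test across replicates.  Over-representation (including the lipid
acyl-chain enrichment) is the exact hypergeometric upper tail computed
with integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .data import logger


def median_normalize(matrix: pd.DataFrame, log_first: bool = False):
    """Divide each feature by its across-sample median, then log2.

    Input is on the linear scale by default (``log_first`` instead
    subtracts the median of already-logged data, the alternative
    convention).  Features with a zero or undefined median are flagged and
    excluded.  Returns ``(normalized DataFrame, flagged feature list)``.
    """
    med = matrix.median(axis=1, skipna=True)
    if log_first:
        flagged = list(matrix.index[med.isna()])
        norm = matrix.sub(med, axis=0)
    else:
        bad = med.isna() | (med == 0)
        flagged = list(matrix.index[bad])
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.log2(matrix.div(med, axis=0))
    if flagged:
        logger.warning("median_normalize: %d feature(s) flagged (zero/undefined median)",
                       len(flagged))
    return norm.drop(index=flagged), flagged


@dataclass
class PathwaySummary:
    """Per-sample pathway summary and paired-contrast tests."""

    pathway: str
    n_members_used: int
    summary: pd.Series                 # per-sample S_{p,s}
    contrasts: pd.DataFrame            # per contrast: mean_diff, p, n_pairs


def pathway_summary_metric(normalized: pd.DataFrame, members, sample_groups,
                           contrasts, pathway: str = "pathway",
                           replicate=None) -> PathwaySummary:
    """Median-of-members summary per sample with paired t-tests per contrast.

    ``normalized`` is a median-normalized log2 matrix (features x samples);
    ``members`` the pathway's gene set (only members present are used; at
    least two required); ``sample_groups`` maps sample -> condition;
    ``contrasts`` is a list of (treatment, control) condition pairs whose
    samples are paired by ``replicate`` id (default: order within group).
    """
    present = [g for g in members if g in normalized.index]
    if len(present) < 2:
        raise ValueError(f"pathway {pathway!r} has {len(present)} member(s) in the "
                         "matrix; need >= 2")
    groups = pd.Series(sample_groups)
    summary = normalized.loc[present].median(axis=0)

    rows = []
    for treat, ctrl in contrasts:
        st = [s for s in summary.index if groups.get(s) == treat]
        sc = [s for s in summary.index if groups.get(s) == ctrl]
        if replicate is not None:
            rep = pd.Series(replicate)
            st = sorted(st, key=lambda s: rep[s])
            sc = sorted(sc, key=lambda s: rep[s])
        n = min(len(st), len(sc))
        if n < 2:
            raise ValueError(f"contrast {treat} vs {ctrl}: need >= 2 paired replicates")
        a = summary[st[:n]].to_numpy()
        b = summary[sc[:n]].to_numpy()
        t = stats.ttest_rel(a, b)
        rows.append({"treatment": treat, "control": ctrl,
                     "mean_diff": float(np.mean(a - b)),
                     "p": float(t.pvalue), "n_pairs": n})
    return PathwaySummary(pathway=pathway, n_members_used=len(present),
                          summary=summary, contrasts=pd.DataFrame(rows))


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    Integer/rational summation, so the tail is exact to float rounding.
    ``k > min(K, n)`` returns 0 (impossible overlap); ``k <= 0`` returns 1.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid margins N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        logger.debug("hypergeometric_tail: k=%d exceeds min(K, n)=%d; p=0", k, hi)
        return 0.0
    total = comb(N, n)
    acc = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1))
    return float(Fraction(acc, total))


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of an annotation in a selection."""

    universe_size: int       # N
    annotated: int           # K
    selected: int            # n
    overlap: int             # k
    p: float


def annotation_enrichment(selected, predicate, universe) -> EnrichmentResult:
    """Test whether a selection is enriched for features matching a predicate.

    ``predicate`` is a callable on feature ids (e.g. "lipid_annotation
    contains a 20:5 or 22:6 acyl chain"); ``selected`` must be a subset of
    ``universe``.
    """
    universe = list(universe)
    sel = set(selected)
    outside = sel - set(universe)
    if outside:
        raise ValueError(f"selected features outside the universe: {sorted(outside)[:5]}")
    annotated = {f for f in universe if predicate(f)}
    N, K, n = len(universe), len(annotated), len(sel)
    k = len(sel & annotated)
    res = EnrichmentResult(universe_size=N, annotated=K, selected=n, overlap=k,
                           p=hypergeometric_tail(N, K, n, k))
    logger.info("enrichment: overlap %d/%d selected, %d/%d annotated, p=%.4g",
                k, n, K, N, res.p)
    return res


def acyl_chain_predicate(feature_meta: pd.DataFrame, chains=("20:5", "22:6"),
                         lipid_class: str | None = "TG"):
    """Predicate factory: lipid of a given class carrying any of the acyl chains."""
    def pred(fid) -> bool:
        if fid not in feature_meta.index:
            return False
        row = feature_meta.loc[fid]
        if lipid_class is not None and row.get("lipid_class") != lipid_class:
            return False
        ac = row.get("acyl_chains")
        return isinstance(ac, str) and any(c in ac for c in chains)
    return pred
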