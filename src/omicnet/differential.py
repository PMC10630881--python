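"""Per-feature group contrasts, BH multiple-testing control, and the
four-way treatment-reversal categorization.

A feature is *disease-affected* when the disease-diet vs reference contrast
passes the node gate (BH q < ``node_fdr`` and, for categorization, raw
p < ``reversal_p``).  A treatment arm *reverses* the feature when its own
contrast against the disease diet is significant (p < ``reversal_p``) with
fold change of the opposite sign to the disease effect.  Each affected
feature then falls into exactly one of four categories: reversed by arm A
only, by arm B only, by both, or by neither.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import AnalysisConfig, OmicsStudy, logger

CATEGORIES = ("A_only", "B_only", "A_and_B", "none")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing entries are propagated as NaN and excluded from the family size.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if (p[mask] < 0).any() or (p[mask] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def differential_stats(study: OmicsStudy, contrast: tuple[str, str],
                       method: str = "welch_t") -> pd.DataFrame:
    """Per-feature contrast of ``contrast[0]`` (treatment) vs ``contrast[1]`` (control).

    Returns a DataFrame indexed by feature_id with log2FC (mean difference on
    the stored scale), two-sided p, BH q within this contrast family, group
    sizes, and a ``tested`` flag.  Features with fewer than two non-missing
    values in either group are flagged untested; features constant across
    both groups get p = 1 and log2FC = 0.
    """
    if method not in ("welch_t", "mann_whitney"):
        raise ValueError(f"unknown method {method!r}")
    gx, gy = contrast
    x = study.group_values(gx).to_numpy(dtype=float)
    y = study.group_values(gy).to_numpy(dtype=float)
    n_x = (~np.isnan(x)).sum(axis=1)
    n_y = (~np.isnan(y)).sum(axis=1)
    tested = (n_x >= 2) & (n_y >= 2)

    with np.errstate(invalid="ignore"):
        mean_x = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
        mean_y = np.nanmean(np.where(np.isnan(y), np.nan, y), axis=1)
    log2fc = mean_x - mean_y

    p = np.full(x.shape[0], np.nan)
    if method == "welch_t":
        res = stats.ttest_ind(x, y, axis=1, equal_var=False, nan_policy="omit")
        p[tested] = np.asarray(res.pvalue)[tested]
    else:
        for i in np.where(tested)[0]:
            xi = x[i][~np.isnan(x[i])]
            yi = y[i][~np.isnan(y[i])]
            p[i] = stats.mannwhitneyu(xi, yi, alternative="two-sided").pvalue

    # constant in both groups: no evidence either way
    const = tested & (np.nanstd(x, axis=1) == 0) & (np.nanstd(y, axis=1) == 0) \
        & (mean_x == mean_y)
    if const.any():
        logger.warning("%d feature(s) constant in both groups of %s vs %s; p set to 1",
                       const.sum(), gx, gy)
    p[const] = 1.0
    log2fc[const] = 0.0
    p[tested & np.isnan(p)] = 1.0  # degenerate Welch (zero variance, equal means)

    out = pd.DataFrame({
        "log2FC": log2fc, "p": p, "q": bh_fdr(p),
        "n_treatment": n_x, "n_control": n_y, "tested": tested,
    }, index=study.values.index)
    out.index.name = "feature_id"
    logger.info("differential %s vs %s: %d/%d features tested", gx, gy,
                int(tested.sum()), len(out))
    return out


def categorize_treatment_effects(disease: pd.DataFrame, treatA: pd.DataFrame,
                                 treatB: pd.DataFrame,
                                 cfg: AnalysisConfig | None = None,
                                 require_p: bool = True) -> pd.DataFrame:
    """Label each disease-affected feature by which treatment arms reverse it.

    ``disease`` must be the disease-diet vs reference contrast; ``treatA`` /
    ``treatB`` the treatment-arm vs disease-diet contrasts, all over the same
    feature set.  A feature is disease-affected iff its disease q <
    ``node_fdr`` (and p < ``reversal_p`` when ``require_p``, the default
    conjunction gate).  An arm reverses the feature iff its p <
    ``reversal_p`` and its fold change has the opposite sign to the disease
    fold change.  Categories (mutually exclusive, affected features only):
    ``A_only``, ``B_only``, ``A_and_B``, ``none``.
    """
    cfg = cfg or AnalysisConfig()
    if not (disease.index.equals(treatA.index) and disease.index.equals(treatB.index)):
        raise ValueError("the three differential tables must cover identical feature sets")

    affected = (disease["q"] < cfg.node_fdr).fillna(False)
    if require_p:
        affected &= (disease["p"] < cfg.reversal_p).fillna(False)
    d_sign = np.sign(disease["log2FC"])

    def reverses(t: pd.DataFrame) -> pd.Series:
        sig = (t["p"] < cfg.reversal_p).fillna(False)
        opposite = np.sign(t["log2FC"]) == -d_sign
        return sig & opposite & (d_sign != 0)

    rev_a = reverses(treatA)
    rev_b = reverses(treatB)
    category = pd.Series(pd.NA, index=disease.index, dtype="object")
    category[affected & rev_a & ~rev_b] = "A_only"
    category[affected & ~rev_a & rev_b] = "B_only"
    category[affected & rev_a & rev_b] = "A_and_B"
    category[affected & ~rev_a & ~rev_b] = "none"

    out = pd.DataFrame({
        "disease_affected": affected,
        "category": category,
        "log2FC_disease": disease["log2FC"],
    })
    counts = category.value_counts().to_dict()
    logger.info("categorized %d affected features: %s", int(affected.sum()), counts)
    return out
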