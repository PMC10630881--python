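"""Synthetic multi-omic data with planted, fully known ground truth.

The generators emulate the statistical shape of a four-group dietary
intervention: a reference diet, a disease-inducing diet, and two treatment
arms layered on the disease diet.  Expression-like features live on a log2
scale with Gaussian replicate noise; planted disease effects shift the
disease-arm means, planted reversal categories shift treated means back to
the reference level, and correlated modules share a latent per-sample
factor whose loading gives a closed-form target correlation.  Single-cell
counts are negative binomial with cluster-restricted marker elevation, and
the meta-analysis generator produces per-study differential tables with a
planted direction-concordant gene set.  Every generator is deterministic in
its seed and returns the truth needed to score each downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd

from .data import OmicsStudy, logger

DEFAULT_GROUPS = ("reference", "disease", "treatA", "treatB")


@dataclass
class Module:
    """A correlated feature module driven by one latent factor.

    With ``affected=True`` every member also receives a same-direction
    planted disease effect, so the module passes the disease node gate and
    its edges carry consistent fold-change signs; a flipped-loading
    violation member then contradicts the fold-change sign rule exactly as
    a correlation false positive would.
    """

    omic_class: str
    size: int
    rho_target: float = 0.8
    n_violations: int = 0  # members with flipped loading (correlation only)
    affected: bool = False

    def __post_init__(self):
        if not (-1 < self.rho_target < 1):
            raise ValueError("rho_target must be in (-1, 1)")


@dataclass
class SimDesign:
    """Study layout and planted structure for :func:`simulate_multiomic_study`."""

    n_per_group: int = 8
    groups: tuple = DEFAULT_GROUPS
    n_features: dict = field(default_factory=lambda: {
        "gene": 120, "lipid": 40, "metabolite": 15, "biochemical": 8,
        "anthropometric": 5})
    n_affected: dict = field(default_factory=lambda: {
        "A_only": 15, "B_only": 15, "A_and_B": 15, "none": 15})
    effect_range: tuple = (0.5, 2.0)
    modules: tuple = ()
    noise_sd: float = 0.5
    lipid_epa_dha_fraction: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        total_affected = sum(self.n_affected.values())
        if total_affected > self.n_features.get("gene", 0):
            raise ValueError("more affected features planted than genes available")
        for m in self.modules:
            if m.size > self.n_features.get(m.omic_class, 0):
                raise ValueError(
                    f"module of size {m.size} exceeds the {m.omic_class} class")


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    category: dict = field(default_factory=dict)          # feature -> planted category
    effect: dict = field(default_factory=dict)            # feature -> disease log2FC
    module_members: list = field(default_factory=list)    # list of member lists
    true_edges: list = field(default_factory=list)        # (u, v, sign)
    violation_pairs: list = field(default_factory=list)   # (u, v)
    bottleneck: object = None
    marker_map: dict = field(default_factory=dict)        # gene -> cluster
    true_positive_genes: list = field(default_factory=list)
    rng_seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _feature_meta(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for omic, n in design.n_features.items():
        for i in range(n):
            fid = f"{omic[:3]}_{i:04d}"
            lipid_class, chains = None, None
            if omic == "lipid":
                if rng.random() < design.lipid_epa_dha_fraction:
                    lipid_class = "TG"
                    chains = "/".join(["16:0", rng.choice(["20:5", "22:6"]), "18:1"])
                else:
                    lipid_class = rng.choice(["TG", "PC", "PE", "PG", "SM"])
                    chains = "/".join(rng.choice(
                        ["14:0", "16:0", "16:1", "18:0", "18:1", "18:2"], size=3))
            rows.append({"feature_id": fid, "omic_class": omic,
                         "lipid_class": lipid_class, "acyl_chains": chains})
    return pd.DataFrame(rows).set_index("feature_id")


def _loading(rho: float, noise_sd: float) -> float:
    # x = lam * z + eps  with z ~ N(0,1), eps ~ N(0, sd^2)
    # => corr(x1, x2) = lam^2 / (lam^2 + sd^2) = rho  (Pearson, same loading)
    return float(np.sqrt(abs(rho) / (1 - abs(rho))) * noise_sd) * np.sign(rho)


def simulate_multiomic_study(design: SimDesign) -> tuple[OmicsStudy, SimTruth]:
    """Four-group multi-omic study with planted effects, categories and modules.

    Disease-affected features (genes, by construction) get a disease-vs-
    reference mean shift drawn from ``effect_range`` with random sign; a
    treatment arm planted to reverse a feature returns its mean to the
    reference level, otherwise the treated mean stays at the disease level.
    Module members share a per-sample latent factor with loading chosen so
    the within-group pairwise Pearson correlation equals ``rho_target``
    (Spearman is slightly attenuated, ``(6/pi) asin(rho/2)`` for Gaussians);
    violation members flip the loading sign only, leaving mean shifts
    untouched, so their retained edges contradict the fold-change sign rule.
    """
    rng = np.random.default_rng(design.rng_seed)
    meta = _feature_meta(design, rng)
    features = list(meta.index)
    groups = list(design.groups)
    samples, group_of = [], []
    for g in groups:
        for i in range(design.n_per_group):
            samples.append(f"{g}_{i:02d}")
            group_of.append(g)
    sample_meta = pd.DataFrame({"group": group_of},
                               index=pd.Index(samples, name="sample_id"))

    n_feat, n_samp = len(features), len(samples)
    baseline = rng.normal(8.0, 1.0, size=n_feat)
    values = baseline[:, None] + rng.normal(0.0, design.noise_sd, size=(n_feat, n_samp))

    truth = SimTruth(rng_seed=design.rng_seed)
    fidx = {f: i for i, f in enumerate(features)}
    gmask = {g: np.array([gg == g for gg in group_of]) for g in groups}
    ref, dis, ta, tb = groups[:4]

    genes = [f for f in features if meta.loc[f, "omic_class"] == "gene"]
    pool = list(rng.permutation(genes))
    for cat, n_cat in design.n_affected.items():
        for _ in range(n_cat):
            f = pool.pop()
            eff = rng.uniform(*design.effect_range) * rng.choice([-1.0, 1.0])
            i = fidx[f]
            values[i, gmask[dis]] += eff
            values[i, gmask[ta]] += 0.0 if cat in ("A_only", "A_and_B") else eff
            values[i, gmask[tb]] += 0.0 if cat in ("B_only", "A_and_B") else eff
            truth.category[f] = cat
            truth.effect[f] = eff
    for f in features:
        truth.category.setdefault(f, "unaffected")

    # latent-factor modules, drawn per group so correlation holds within groups
    by_class = {c: [f for f in features if meta.loc[f, "omic_class"] == c]
                for c in design.n_features}
    used: set = set(truth.effect)
    for mod in design.modules:
        avail = [f for f in by_class[mod.omic_class] if f not in used]
        if len(avail) < mod.size:
            avail = by_class[mod.omic_class]
        members = list(rng.permutation(avail)[:mod.size])
        used |= set(members)
        lam = _loading(mod.rho_target, design.noise_sd)
        flips = set(members[:mod.n_violations])
        z = rng.normal(size=n_samp)
        for f in members:
            sign = -1.0 if f in flips else 1.0
            values[fidx[f]] += sign * lam * z
            if mod.affected:
                eff = rng.uniform(*design.effect_range)
                i = fidx[f]
                for g in (dis, ta, tb):  # neither arm reverses module members
                    values[i, gmask[g]] += eff
                truth.category[f] = "none"
                truth.effect[f] = eff
        truth.module_members.append(members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                u, v = members[a], members[b]
                s = -1 if (u in flips) != (v in flips) else 1
                truth.true_edges.append((u, v, s))
                if s == -1:
                    truth.violation_pairs.append((u, v))

    vals = pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                        columns=samples)
    study = OmicsStudy(values=vals, feature_meta=meta, sample_meta=sample_meta)
    logger.info("simulated study: %d features x %d samples, %d planted-affected, "
                "%d modules", n_feat, n_samp, len(truth.effect), len(design.modules))
    return study, truth


def simulate_bottleneck_network_data(m1: int = 30, m2: int = 30,
                                     n_per_group: int = 50,
                                     rho_target: float = 0.8,
                                     bridge_loading: float = 1.0,
                                     noise_sd: float = 0.5,
                                     effect_range: tuple = (1.0, 2.0),
                                     groups: tuple = DEFAULT_GROUPS,
                                     seed: int = 0,
                                     include_bridge: bool = True
                                     ) -> tuple[OmicsStudy, SimTruth]:
    """Two correlated modules joined through one designated bridge feature.

    Module 1 is genes, module 2 lipids; the bridge (a gene) loads on both
    latent factors, so it correlates with both modules while cross-module
    correlations are otherwise ~0.  All features carry positive planted
    disease effects (every node passes the disease gate and the causality
    filter at large n), and in the ground-truth graph removing the bridge
    disconnects module 1 from module 2.  With ``include_bridge=False`` the
    bridge feature is pure noise (negative-control variant).
    """
    rng = np.random.default_rng(seed)
    mod1 = [f"gen_{i:04d}" for i in range(m1)]
    mod2 = [f"lip_{i:04d}" for i in range(m2)]
    bridge = "gen_bridge"
    features = mod1 + mod2 + [bridge]
    meta = pd.DataFrame({
        "omic_class": ["gene"] * m1 + ["lipid"] * m2 + ["gene"],
        "lipid_class": [None] * m1 + ["TG"] * m2 + [None],
        "acyl_chains": [None] * m1 + ["16:0/18:1/18:2"] * m2 + [None],
    }, index=pd.Index(features, name="feature_id"))

    groups = list(groups)
    samples, group_of = [], []
    for g in groups:
        for i in range(n_per_group):
            samples.append(f"{g}_{i:02d}")
            group_of.append(g)
    n_samp = len(samples)

    lam = _loading(rho_target, noise_sd)
    a = bridge_loading * lam
    z1 = rng.normal(size=n_samp)
    z2 = rng.normal(size=n_samp)
    values = np.zeros((len(features), n_samp))
    baseline = rng.normal(8.0, 1.0, size=len(features))
    values += baseline[:, None] + rng.normal(0, noise_sd, size=values.shape)
    for i, _ in enumerate(mod1):
        values[i] += lam * z1
    for j, _ in enumerate(mod2):
        values[m1 + j] += lam * z2
    if include_bridge:
        values[-1] += a * z1 + a * z2

    truth = SimTruth(rng_seed=seed, bottleneck=bridge if include_bridge else None)
    dis_mask = np.array([g != groups[0] for g in group_of])  # all non-reference arms
    for i, f in enumerate(features):
        eff = rng.uniform(*effect_range)
        values[i, dis_mask] += eff
        truth.effect[f] = eff
        truth.category[f] = "A_and_B"
    truth.module_members = [mod1, mod2]
    for mod in (mod1, mod2):
        for x in range(len(mod)):
            for y in range(x + 1, len(mod)):
                truth.true_edges.append((mod[x], mod[y], 1))
    if include_bridge:
        for f in mod1 + mod2:
            truth.true_edges.append((bridge, f, 1))

    sample_meta = pd.DataFrame({"group": group_of},
                               index=pd.Index(samples, name="sample_id"))
    vals = pd.DataFrame(values, index=meta.index, columns=samples)
    return OmicsStudy(values=vals, feature_meta=meta, sample_meta=sample_meta), truth


def simulate_single_cell(n_clusters: int = 12, n_genes: int = 500,
                         n_cells: int = 3000, marker_map: dict | None = None,
                         markers_per_cluster: int = 5,
                         baseline_mean: float | None = None, marker_fold: float = 4.0,
                         dispersion: float = 2.0, n_mito_genes: int = 10,
                         frac_low_library: float = 0.02,
                         frac_high_mito: float = 0.02,
                         seed: int = 0) -> tuple[ad.AnnData, SimTruth]:
    """Clustered negative-binomial single-cell counts with planted markers.

    Marker genes have ``marker_fold``-times elevated mean only in their own
    cluster; all other genes are uniform across clusters (truth label
    ``"Not assigned"``).  A stated fraction of cells violates the QC rules
    (scaled-down library for the small-library rule; inflated mitochondrial
    counts, gene names prefixed ``mt-``, for the mitochondrial-fraction
    rule) so the filters have something to remove.  Returns an AnnData
    (cells x genes) with cluster labels in ``obs["cluster"]``.

    ``baseline_mean`` defaults to ``1.5 * 5000 / n_genes`` so a normal
    cell's library size sits ~50% above the QC floor while the planted
    low-library cells (half the baseline) fall cleanly below it.
    """
    rng = np.random.default_rng(seed)
    if baseline_mean is None:
        baseline_mean = 1.5 * 5000 / n_genes
    clusters = [f"C{i:02d}" for i in range(n_clusters)]
    mito = [f"mt-g{i:03d}" for i in range(n_mito_genes)]
    rest = [f"g{i:04d}" for i in range(n_genes - n_mito_genes)]
    genes = mito + rest

    if marker_map is None:
        pool = [g for g in rest]
        marker_map = {}
        k = 0
        for c in clusters:
            for _ in range(markers_per_cluster):
                marker_map[pool[k]] = c
                k += 1
    for g, c in marker_map.items():
        if c not in clusters:
            raise ValueError(f"marker {g!r} assigned to unknown cluster {c!r}")
        if g not in genes:
            raise ValueError(f"marker {g!r} not among the simulated genes")

    cell_cluster = rng.choice(clusters, size=n_cells)
    mean = np.full((n_cells, n_genes), baseline_mean)
    gidx = {g: i for i, g in enumerate(genes)}
    for g, c in marker_map.items():
        mean[cell_cluster == c, gidx[g]] *= marker_fold

    low_lib = rng.random(n_cells) < frac_low_library
    mean[low_lib] *= 0.5  # library size drops below the QC floor
    # NB with mean mu and dispersion theta: var = mu + mu^2 / theta
    theta = dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(np.int32)

    high_mito = (~low_lib) & (rng.random(n_cells) < frac_high_mito)
    counts[np.ix_(high_mito, [gidx[g] for g in mito])] *= 12

    adata = ad.AnnData(X=counts,
                       obs=pd.DataFrame({"cluster": cell_cluster},
                                        index=[f"cell_{i:05d}" for i in range(n_cells)]),
                       var=pd.DataFrame(index=genes))
    adata.obs["true_low_library"] = low_lib
    adata.obs["true_high_mito"] = high_mito
    truth = SimTruth(rng_seed=seed, marker_map=dict(marker_map))
    for g in genes:
        truth.category[g] = marker_map.get(g, "Not assigned")
    logger.info("simulated single-cell: %d cells x %d genes, %d clusters, %d markers",
                n_cells, n_genes, n_clusters, len(marker_map))
    return adata, truth


def simulate_meta_studies(n_studies: int = 7, n_genes: int = 2000,
                          n_true_positives: int = 50, effect: float = 4.0,
                          fc_scale: float = 0.5, seed: int = 0
                          ) -> tuple[list[pd.DataFrame], pd.DataFrame, SimTruth]:
    """Per-study differential tables with a planted concordant gene set.

    Each study reports a z-statistic-derived (log2FC, p) per gene: null
    genes have standard-normal z (uniform two-sided p, random direction);
    true positives share a fixed direction with mean shift ``effect`` in
    every study.  Also returns a reference differential table (the
    disease-contrast analog) whose fold-change signs match the planted
    directions for true positives and are random for nulls.
    """
    if n_studies < 2:
        raise ValueError("need >= 2 studies")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    true_set = list(rng.choice(genes, size=n_true_positives, replace=False))
    direction = pd.Series(0.0, index=genes)
    direction[true_set] = rng.choice([-1.0, 1.0], size=n_true_positives)

    from scipy import stats as _st
    tables = []
    for s in range(n_studies):
        z = rng.normal(size=n_genes)
        z += direction.to_numpy() * effect
        p = 2 * _st.norm.sf(np.abs(z))
        tables.append(pd.DataFrame({"log2FC": z * fc_scale, "p": p},
                                   index=pd.Index(genes, name="gene_id")))

    ref_sign = direction.replace(0.0, np.nan)
    ref_sign = ref_sign.fillna(pd.Series(rng.choice([-1.0, 1.0], size=n_genes),
                                         index=genes))
    reference = pd.DataFrame({"log2FC": ref_sign * rng.uniform(0.5, 2.0, n_genes),
                              "p": rng.uniform(size=n_genes)}, index=genes)
    truth = SimTruth(rng_seed=seed, true_positive_genes=true_set)
    return tables, reference, truth
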