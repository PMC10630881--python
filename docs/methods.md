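# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they hold, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer should know about.

## Data model

An `OmicsStudy` is one numeric feature × sample matrix spanning several
omic classes, with per-feature metadata (class; for lipids a class string
such as `TG` and a slash-separated acyl-chain list) and a sample → group
map. Gene/lipid/metabolite values are assumed to live on a log2-like scale
where mean differences are log2 fold changes; anthropometric features may
be on their native scale, and only the *sign* of their mean difference is
used downstream. Missing values stay missing (pairwise-complete handling
everywhere); they are never imputed as zero, because zero-filling
fabricates correlation in lipidomics-style missingness.

All thresholds live in `AnalysisConfig`; every exported artifact embeds the
config hash and RNG seed so a network file can be traced to the settings
that produced it.

## Differential contrasts and reversal categories

Contrasts are Welch t-tests on the stored scale (Mann–Whitney selectable),
two-sided, with BH adjustment within each contrast family. The disease
gate is the conjunction q < `node_fdr` (0.10) **and** p < `reversal_p`
(0.05); a q-only gate is available (`require_p=False`) because the two
formulations are both defensible readings of an FDR-plus-p screening
convention and they differ only for marginal features.

A treatment arm reverses a feature iff its arm-vs-disease contrast has
p < 0.05 **and** fold change of opposite sign to the disease effect — the
conjunction is explicit, so an arm that significantly *amplifies* the
disease shift is never a reversal. The four categories partition the
affected set by construction. Testing of a combined-arm diet is supported
behind the same machinery but excluded from categories.

## Network reconstruction

Edges are Spearman correlations computed per experimental group over the
disease-diet arms only; the reference group is excluded because correlation
under the reference condition reflects baseline physiology, not the
disease process being modeled. Per-group p uses the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df (exact permutation available for n ≤ 8);
|ρ| = 1 maps to a machine-floor p with a warning rather than 0 so Fisher's
statistic stays finite.

The meta-filter requires (i) one strict shared sign across groups (any
ρ = 0 fails), (ii) every per-group p < 0.20, (iii) Fisher combined
p < 0.05, (iv) BH q < 0.10. BH families are per omic-class block pair
(gene–gene, gene–lipid, …) with a global-BH option; q is computed over the
*full* candidate family, not the survivors of steps i–iii, which keeps the
cascade monotone: tightening any threshold can only remove edges.

The causality filter encodes the expectation that a real association
between two disease-responsive features should have a correlation sign
equal to the product of their disease fold-change signs; contradicting
edges ("unexpected correlations") are removed and their fraction reported
as the PUC. The filter is applied uniformly across omic blocks; a
restriction flag exists. Plain removal is implemented; a
deviation-from-expected-proportion test variant is deliberately out of
scope.

Candidate generation is vectorized (rank transform, then a correlation
matrix per group) and walks the feature list in chunks, so memory is
bounded by one chunk × feature-count block rather than the full pair set.

## Bipartite betweenness centrality

`bibc(v)` sums, over all cross-group pairs (s ∈ G1, t ∈ G2), the fraction
of shortest s–t paths through v, with v excluded when it is an endpoint of
the pair; disconnected pairs contribute 0, and scores are computed on the
full graph (no largest-component restriction). Paths are unweighted —
correlation magnitudes do not define distances. Each unordered pair is
counted once; note that networkx's subset betweenness halves undirected
scores, so it reports exactly half of this definition.

The implementation is a Brandes dependency accumulation restricted to the
target set, vectorized over sources with a level-synchronous BFS on a
dense adjacency matrix (all sources advance one BFS level per matrix
product). It is checked exactly (≤ 1e-12) against a brute-force
shortest-path enumeration oracle on random graphs.

Group overlap is an error by default (`on_overlap="exclude"` drops the
intersection). Scaling to 0–100 is min–max (rank-based scaling would
discard the magnitude gaps that distinguish a dominant bottleneck from a
merely first-ranked node); an all-equal score vector scales to all 0 with
a warning. Cell-pair aggregation computes BiBC for every unordered cluster
pair (66 pairs for 12 clusters) and aggregates per node by max or mean;
unassigned nodes still receive scores as intermediaries. Joint selection
takes nodes in the top fraction (default 10%) of *both* BiBC and degree,
or, in absolute mode, degree > 50 with BiBC in the top 1%.

## Random-network significance

Each null replicate draws a uniform G(n, m) graph with the observed
network's node and edge counts, relabels the two groups uniformly at
random with preserved sizes, and records the BiBC of an analog node.
Because no canonical node correspondence exists between a real network and
a G(n, m) draw, three strategies ship: `degree_matched` (default — the
node whose degree is closest to the observed node's, ties uniform),
`random_node`, and `all_nodes`. The empirical p is #{null ≥ observed}/R
with no add-one correction, so a value above every null reports 0 and is
formatted "< 1/R"; an add-one variant is trivially obtained from the
retained null sample, which is kept in the result for plotting or reuse.
Calibration is verified by drawing the observed value from the null
itself, which makes the empirical p uniform (KS-tested).

## Single-cell overlay

QC removes cells with library size < 5,000 or mitochondrial fraction
> 12%, then genes detected in fewer than 3 remaining cells (cell rules
before the gene rule; the report's counts reconcile exactly).
Normalization is counts-per-10k; means and the pseudocount-1 log2FC are on
the normalized linear scale and the rank-sum test on log1p values. The
"mean normalized expression > 1.0" assignment threshold applies to the
normalized mean by default (a raw-mean option exists, since the unit of
such thresholds varies between workflows). "Uniquely expressed" is
operationalized as the highest-mean rule among clusters passing all three
thresholds, with a deterministic lexicographic tiebreak on exact mean
ties. Clustering itself is consumed as input labels — this package never
clusters, embeds, or detects doublets.

## Meta-analysis

Ranks are per-study evidence ranks by fold change (rank 1 = most extreme
in the requested direction, average ranks for ties); RP is their geometric
mean over the studies where the gene is present, so unequal platforms are
handled by gene-specific study subsets with matching nulls. Two one-sided
runs (up, down) are combined by reporting the better direction with its p
doubled. Significance is exact enumeration of the per-study rank grid when
its size is ≤ 1e5, else Monte-Carlo permutation (default 1,000 rounds)
with the add-one correction (count+1)/(n_perm+1) — add-one keeps null
p-values valid and, with BH at 15%, makes a single spuriously extreme gene
unable to clear the threshold alone. The concordant signature takes genes
with RP q < 15%, Fisher p < 5%, and majority direction equal to the
reference contrast's sign. Orthology translation is a two-column input
mapping; untranslated genes are dropped with a logged count.

## Pathway scores and enrichment

Median normalization divides each feature by its across-sample median on
the linear scale and then takes log2 (a log-first variant subtracts the
median of logged values); zero or undefined medians are flagged and
excluded. The pathway summary is the per-sample median across member genes
present in the matrix (≥ 2 required), compared between conditions by a
paired t-test with replicates paired by order within group or an explicit
replicate id. The summary is invariant to non-member genes by
construction.

Over-representation is the exact hypergeometric upper tail computed with
integer arithmetic (no large-N approximation), monotone in the overlap and
symmetric in (K, n). For the EPA/DHA acyl-chain scenario with margins
N=357, K=9, n=5, k=2 the exact tail is 5.4e-3 — the package reports the
exact value of whatever margins it is given rather than any pre-computed
bound.

## Synthetic data: what it emulates, and what it does not

The multi-omic generator reproduces the *statistical shape* of a
four-group dietary-intervention study: 8 samples per group by default,
five omic classes at reduced dimensionality (120 genes rather than ~20k —
scale is configurable), log2-scale Gaussian replicate noise (sd 0.5, a
typical replicate CV for expression data on this scale), planted disease
shifts drawn from ±(0.5–2) log2 units, and reversal planted as a full
return of the treated mean to the reference level. Correlated modules
share one latent N(0,1) factor per module with loading
λ = σ√(ρ/(1−ρ)), giving within-module Pearson correlation exactly ρ
(Spearman is attenuated to (6/π)·asin(ρ/2) for Gaussians — ~0.79 for
ρ = 0.8, well inside the tolerance of every test that uses it). Violation
members flip the loading sign only, leaving the mean shift untouched —
precisely the signature the causality filter is built to remove. The
bottleneck generator joins two modules through one bridge feature loading
on both factors, with all-positive planted effects so every node clears
the gates.

Single-cell counts are negative binomial (dispersion 2) with markers
elevated 4× in their own cluster and QC violators planted at 2% each; the
per-gene baseline mean defaults to 1.5·5000/n_genes so normal libraries
sit 50% above the QC floor and planted low-library cells (half baseline)
fall cleanly below it. Meta-analysis studies are z-score draws: planted
genes share a direction with mean shift 4 SDs; nulls are standard normal
with uniform two-sided p.

None of the generators emulate count overdispersion structure in bulk
data, batch effects, feature-specific missingness, correlated noise across
omic layers, or compositional effects — so green tests demonstrate that
the machinery recovers what it is designed to recover under its own model
assumptions, not that those assumptions hold on any particular real
dataset.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at the scales that make their guarantees sharp but
cheap: 100 seeds for bottleneck recovery, 50 null seeds for edge
calibration, 20 seeds at R = 1,000 for null significance (the R = 5,000
default in `AnalysisConfig` remains the recommended production setting),
20 seeds for single-cell assignment, and 1,000 permutations for the
rank-product p. The acceptance script uses the same conditions with
slightly fewer seeds per stage; every reported number is recomputed at run
time from the given seed.

## Interfaces

The package is a library: the public functions plus the `examples/`
scripts are the interface, and file exchange uses plain formats (TSV/CSV
with dialect sniffing, GraphML/SIF for networks, GMT for gene sets, MTX +
sidecar lists for counts, JSON for truth and reports). No shell CLI is
shipped; the stages compose naturally in a few lines of Python and the
examples double as runnable templates.

## Known limitations

- Spearman p-values use the t approximation; at n = 8 per group this is
  adequate only because the meta-filter combines three groups and an FDR
  step — single-group p near the 0.20 gate should not be over-read.
- The PUC is reported as a plain removed fraction; it is an estimate of
  the unexpected-correlation burden, not a formal test.
- Degree-matched null analogs are a heuristic correspondence; the three
  strategies can disagree for nodes whose degree is atypical of the
  G(n, m) ensemble, which is why the full null sample is retained.
- The exhaustive rank-product path requires all genes present in all
  studies; mixed-presence inputs always use the permutation path.
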