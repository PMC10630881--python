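"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omicnet import AnalysisConfig, OmicsStudy


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def tiny_study():
    """15 features (10 genes + 5 lipids) x 32 samples over 4 groups of 8."""
    rng = np.random.default_rng(7)
    features = [f"gen_{i}" for i in range(10)] + [f"lip_{i}" for i in range(5)]
    groups = ["reference", "disease", "treatA", "treatB"]
    samples = [f"{g}_{i}" for g in groups for i in range(8)]
    values = pd.DataFrame(rng.normal(8, 1, (15, 32)), index=features, columns=samples)
    feature_meta = pd.DataFrame(
        {"omic_class": ["gene"] * 10 + ["lipid"] * 5},
        index=pd.Index(features, name="feature_id"))
    sample_meta = pd.DataFrame(
        {"group": [g for g in groups for _ in range(8)]},
        index=pd.Index(samples, name="sample_id"))
    return OmicsStudy(values=values, feature_meta=feature_meta, sample_meta=sample_meta)


# ---------------------------------------------------------------------------
# brute-force BiBC oracle: explicit BFS shortest-path enumeration
# ---------------------------------------------------------------------------

def _all_shortest_paths(adj: dict, s, t):
    """Enumerate every shortest s-t path by BFS predecessor expansion."""
    from collections import deque
    dist = {s: 0}
    preds: dict = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                preds[w] = [u]
                q.append(w)
            elif dist[w] == dist[u] + 1:
                preds[w].append(u)
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append([s] + acc[::-1])
            return
        for p in preds[node]:
            back(p, acc + [node])

    back(t, [])
    return paths


def brute_force_bibc(graph, group1, group2) -> dict:
    """Oracle: per-node sum over cross-group pairs of path fractions through it."""
    adj = {n: sorted(graph.neighbors(n)) for n in graph.nodes()}
    score = {n: 0.0 for n in graph.nodes()}
    for s in group1:
        for t in group2:
            if s == t:
                continue
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:  # endpoints excluded
                    score[v] += 1.0 / sigma
    return score


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Oracle: literal step-up definition q_i = min_{p_(j) >= p_i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
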