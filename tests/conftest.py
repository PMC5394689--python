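from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from omiclust.clustering import CopheneticMatrix, Dendrogram, DistanceMatrix
from omiclust.io_model import CountMatrix, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = np.array(
        [[1, 3], [3, 7], [7, 15]], dtype=np.int64
    )
    return CountMatrix(("g1", "g2", "g3"), ("s1", "s2"), counts, "mrna")


@pytest.fixture
def meta_frame() -> pd.DataFrame:
    rows = []
    k = 0
    for phase in ("exponential", "stationary"):
        for batch in ("b1", "b2"):
            for rep in ("r1", "r2"):
                k += 1
                rows.append(
                    {
                        "sample_id": f"s{k}",
                        "omics_kind": "mrna",
                        "growth_phase": phase,
                        "carbon_source": "glucose",
                        "na_mM": 5.0,
                        "mg_mM": 0.8,
                        "batch": batch,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def sample_table(meta_frame) -> SampleTable:
    return SampleTable(meta_frame)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios on the +1 pseudocounted matrix, computed naively."""
    pseudo = counts.astype(float) + 1.0
    n_genes, n_samples = pseudo.shape
    refs = np.array([np.prod(pseudo[g]) ** (1.0 / n_samples) for g in range(n_genes)])
    factors = []
    for s in range(n_samples):
        ratios = [pseudo[g, s] / refs[g] for g in range(n_genes)]
        factors.append(float(np.median(ratios)))
    return np.array(factors)


def brute_force_complete_linkage(d: np.ndarray):
    """Naive agglomerator: rescan every cluster pair against the original
    pairwise table at every step.  Returns (merges, cophenetic matrix)."""
    n = d.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    coph = np.zeros((n, n))
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
            la, lb = min(clusters[a]), min(clusters[b])
            key = (dist, min(la, lb), max(la, lb))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dist, _, _), a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        left, right = (a, b) if min(clusters[a]) <= min(clusters[b]) else (b, a)
        merges.append((left, right, dist))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges, coph


def brute_force_bh(p: list[float]) -> list[float]:
    """Direct transcription of the step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def exhaustive_null(coph: np.ndarray, labels: list[str]):
    """All distinct label permutations; returns pooled same-label means."""
    n = len(labels)
    stats = []
    for perm in set(itertools.permutations(labels)):
        total, pairs = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                if perm[i] == perm[j]:
                    total += coph[i, j]
                    pairs += 1
        stats.append(total / pairs)
    return np.array(stats)


def random_ultrametric(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random ultrametric matrix built from a random binary merge order."""
    clusters = [[i] for i in range(n)]
    c = np.zeros((n, n))
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.1, 1.0))
        a, b = rng.choice(len(clusters), size=2, replace=False)
        for i in clusters[a]:
            for j in clusters[b]:
                c[i, j] = c[j, i] = height
        merged = clusters[a] + clusters[b]
        clusters = [cl for k, cl in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return c
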