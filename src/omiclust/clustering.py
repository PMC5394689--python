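"""Euclidean sample distances, complete-linkage dendrograms, cophenetic matrices.

The agglomerator is implemented here (Lance–Williams update with an
explicit, platform-independent tie-breaking rule) rather than delegated
to :func:`scipy.cluster.hierarchy.linkage`, because downstream
permutation statistics require bit-reproducible merge order even on tied
distances.  Nodes follow the scipy convention: leaves are ``0..n-1`` and
the ``i``-th merge creates node ``n + i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from omiclust.errors import ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    d: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape}, expected {(n, n)}")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if d.size and d.min() < 0:
            raise ValidationError("distances must be nonnegative")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree; ``merges[i] = (left, right, height)`` creates node n+i."""

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        merges = tuple((int(a), int(b), float(h)) for a, b, h in self.merges)
        n = len(self.leaves)
        if len(merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges, got {len(merges)}")
        heights = [h for _, _, h in merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")
        seen: set[int] = set()
        for i, (a, b, _) in enumerate(merges):
            for node in (a, b):
                if node in seen:
                    raise ValidationError(f"node {node} merged twice")
                if not 0 <= node < n + i:
                    raise ValidationError(f"merge {i} references invalid node {node}")
                seen.add(node)
        object.__setattr__(self, "merges", merges)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class CopheneticMatrix:
    """Merge heights of lowest common merges; always ultrametric."""

    sample_ids: tuple[str, ...]
    c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        c = np.asarray(self.c, dtype=float)
        n = len(self.sample_ids)
        if c.shape != (n, n):
            raise ValidationError(f"cophenetic matrix shape {c.shape}, expected {(n, n)}")
        object.__setattr__(self, "c", c)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def euclidean_distances(
    x: np.ndarray, sample_ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Euclidean distances between the rows of ``x`` (samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("feature matrix must be 2-D (samples x features)")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(x.shape[0])]
    if len(sample_ids) != x.shape[0]:
        raise ValidationError("sample_ids length does not match matrix rows")
    bad = ~np.isfinite(x)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite feature value for sample {sample_ids[i]!r}, feature {j}"
        )
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(tuple(sample_ids), d)


def complete_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate with complete linkage (inter-cluster distance = max pair).

    Ties are broken deterministically: among minimal-distance cluster
    pairs, choose the pair whose clusters have the lexicographically
    smallest (sorted) pair of minimal leaf indices.
    """
    n = dm.n
    if n < 2:
        raise ValidationError("at least 2 samples required for clustering")
    dist = dm.d.copy()
    active = list(range(n))  # node ids of live clusters
    min_leaf = {i: i for i in range(n)}  # node id -> smallest leaf index
    node_dist = {(min(i, j), max(i, j)): dist[i, j]
                 for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_node = n
    for _ in range(n - 1):
        best = None
        best_key = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d_ab = node_dist[(min(a, b), max(a, b))]
                la, lb = min_leaf[a], min_leaf[b]
                key = (d_ab, min(la, lb), max(la, lb))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        height = best_key[0]  # type: ignore[index]
        left, right = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        merges.append((left, right, height))
        new = next_node
        next_node += 1
        active = [x for x in active if x not in (a, b)]
        for other in active:
            d_new = max(
                node_dist[(min(a, other), max(a, other))],
                node_dist[(min(b, other), max(b, other))],
            )
            node_dist[(min(new, other), max(new, other))] = d_new
        active.append(new)
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
    return Dendrogram(leaves=dm.sample_ids, merges=tuple(merges))


def _leaf_sets(t: Dendrogram) -> list[set[int]]:
    """Leaf sets of every node (leaves then internal nodes, scipy order)."""
    n = t.n_leaves
    sets: list[set[int]] = [{i} for i in range(n)]
    for a, b, _ in t.merges:
        sets.append(sets[a] | sets[b])
    return sets

def cophenetic_matrix(t: Dendrogram) -> CopheneticMatrix:
    """c(i, j) = height of the lowest merge whose subtree contains both."""
    n = t.n_leaves
    sets = _leaf_sets(t)
    c = np.zeros((n, n), dtype=float)
    # merges processed bottom-up: the first merge joining i and j is lowest
    for a, b, h in t.merges:
        for i in sets[a]:
            for j in sets[b]:
                c[i, j] = h
                c[j, i] = h
    return CopheneticMatrix(sample_ids=t.leaves, c=c)


def to_newick(t: Dendrogram) -> str:
    """Newick string; branch lengths are parent-minus-child merge heights."""
    n = t.n_leaves
    heights = [0.0] * n + [h for _, _, h in t.merges]

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - heights[node]
        if node < n:
            return f"{t.leaves[node]}:{bl:.10g}"
        a, b, h = t.merges[node - n]
        return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

    a, b, h = t.merges[-1]
    return f"({render(a, h)},{render(b, h)});"


def write_matrix_tsv(sample_ids: Sequence[str], m: np.ndarray, path) -> None:
    import pandas as pd

    df = pd.DataFrame(m, index=list(sample_ids), columns=list(sample_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_cophenetic_tsv(path) -> CopheneticMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError("cophenetic TSV row/column labels differ")
    return CopheneticMatrix(tuple(df.columns.astype(str)), df.to_numpy(dtype=float))
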