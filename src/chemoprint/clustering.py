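"""Unsupervised relatedness inference on fingerprint matrices.

The similarity between two fingerprints is the *uncentered correlation*
(the Cluster 3.0 convention): a cosine-like coefficient normalized about
zero rather than about the mean,

    r = (1/n) * sum_i (x_i / sx0) (y_i / sy0),   sx0 = sqrt((1/n) sum x_i^2)

which is appropriate for relative-abundance profiles where the zero level
is meaningful.  Distance is ``d = 1 - r`` (range [0, 2]).  Agglomeration
is classic single linkage — inter-cluster distance is the minimum pairwise
member distance — written out explicitly because its merge sequence and
tie-breaking (smallest index pair) are part of this package's contract.
Trees export to Newick with branch lengths equal to the height difference
between parent and child nodes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .fingerprint import FingerprintMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise DataError("distance matrix must be square")
        if len(self.ids) != n:
            raise DataError("ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` is the ordered sequence of ``(node_a, node_b, height,
    new_node_id)``; leaves are nodes ``0 .. n-1`` and internal nodes are
    numbered ``n, n+1, ...`` in merge order.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    def __post_init__(self):
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise DataError(f"{n} leaves require {n - 1} merges, "
                            f"got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise DataError("merge heights must be non-decreasing")
        seen = set(range(n))
        used = set()
        for a, b, _, new in self.merges:
            if a not in seen or b not in seen or a in used or b in used:
                raise DataError("invalid node reference in merge sequence")
            used.update((a, b))
            seen.add(new)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise cophenetic distances: height of the lowest common merge."""
        n = self.n_leaves
        members = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for a, b, h, new in self.merges:
            for i in members[a]:
                for j in members[b]:
                    out[i, j] = out[j, i] = h
            members[new] = members.pop(a) + members.pop(b)
        return out

    def cut(self, k: int) -> list[int]:
        """Cluster assignment per leaf after removing the k-1 highest merges.

        Because single-linkage heights are non-decreasing, this is the
        partition after the first ``n - k`` merges.
        """
        n = self.n_leaves
        if not (1 <= k <= n):
            raise ConfigError(f"k must be in [1, {n}], got {k}")
        members = {i: [i] for i in range(n)}
        for a, b, _, new in self.merges[: n - k]:
            members[new] = members.pop(a) + members.pop(b)
        assign = np.empty(n, dtype=int)
        for cluster_id, node in enumerate(sorted(members)):
            for leaf in members[node]:
                assign[leaf] = cluster_id
        return assign.tolist()


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def uncentered_correlation(x, y) -> float:
    """Uncentered (about-zero) correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise DataError("vectors must be 1-D, non-empty and of equal length")
    sx = np.sqrt(np.mean(x**2))
    sy = np.sqrt(np.mean(y**2))
    if sx == 0 or sy == 0:
        raise DataError("uncentered correlation is undefined for an all-zero vector")
    return float(np.mean((x / sx) * (y / sy)))


_METRICS = ("uncentered_correlation", "pearson", "euclidean")


def distance_matrix(
    m: FingerprintMatrix | np.ndarray,
    metric: str = "uncentered_correlation",
    ids: Optional[Sequence[str]] = None,
) -> DistanceMatrix:
    """Pairwise sample distances: ``1 - r`` for correlation metrics,
    Euclidean norm otherwise."""
    if metric not in _METRICS:
        raise ConfigError(f"metric must be one of {_METRICS}, got {metric!r}")
    if isinstance(m, FingerprintMatrix):
        data = m.values
        ids = list(m.sample_ids) if ids is None else list(ids)
    else:
        data = np.asarray(m, dtype=float)
        ids = [f"sample_{i}" for i in range(data.shape[0])] if ids is None else list(ids)
    n = data.shape[0]
    if n < 2:
        raise DataError("distance_matrix needs at least 2 samples")
    if metric in ("uncentered_correlation", "pearson"):
        norms = np.sqrt(np.mean(data**2, axis=1))
        zero = np.flatnonzero(norms == 0)
        if len(zero):
            raise DataError(
                f"all-zero fingerprint row(s): {[ids[i] for i in zero]}"
            )
    if metric == "uncentered_correlation":
        scaled = data / np.sqrt(np.mean(data**2, axis=1))[:, None]
        sim = (scaled @ scaled.T) / data.shape[1]
        d = 1.0 - sim
    elif metric == "pearson":
        c = np.corrcoef(data)
        d = 1.0 - c
    else:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(data))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    np.maximum(d, 0.0, out=d)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# single linkage
# ---------------------------------------------------------------------------

def single_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate by repeatedly merging the closest pair of clusters.

    Inter-cluster distance is the minimum pairwise member distance; the
    merge height is that minimum.  Ties break toward the smallest
    ``(i, j)`` node-id pair, making the merge sequence deterministic.
    """
    n = len(d)
    if n < 2:
        raise DataError("single_linkage needs at least 2 samples")
    # dist[node] holds current min-distance to every other active node
    active: dict[int, np.ndarray | None] = {i: None for i in range(n)}
    dist = {
        (i, j): d.values[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_id
        next_id += 1
        del dist[(a, b)]
        others = [o for o in active if o not in (a, b)]
        for o in others:
            da = dist.pop((min(a, o), max(a, o)))
            db = dist.pop((min(b, o), max(b, o)))
            dist[(o, new)] = min(da, db)
        del active[a], active[b]
        active[new] = None
        merges.append((a, b, float(h), new))
    return Dendrogram(merges, list(d.ids))


# ---------------------------------------------------------------------------
# Newick export and purity
# ---------------------------------------------------------------------------

def _escape_label(label: str) -> str:
    label = re.sub(r"\s+", "_", label.strip())
    return re.sub(r"[();:,\[\]']", "_", label)


def to_newick(t: Dendrogram) -> str:
    """Serialize a dendrogram to Newick.

    Branch lengths are parent-height minus child-height (leaves sit at
    height 0).  Whitespace and Newick metacharacters in labels are
    replaced by underscores; duplicate labels are disambiguated with a
    numeric suffix and a warning.
    """
    labels = [_escape_label(l) for l in t.leaf_labels]
    seen: dict[str, int] = {}
    for i, l in enumerate(labels):
        if l in seen:
            seen[l] += 1
            labels[i] = f"{l}_{seen[l]}"
            warnings.warn(
                f"duplicate leaf label {l!r} disambiguated as {labels[i]!r}",
                RuntimeWarning, stacklevel=2,
            )
        else:
            seen[l] = 0

    def render(node: int, parent_height: float) -> str:
        length = parent_height - t.node_height(node)
        if node < t.n_leaves:
            return f"{labels[node]}:{length:.10g}"
        a, b, h, _ = t.merges[node - t.n_leaves]
        return f"({render(a, h)},{render(b, h)}):{length:.10g}"

    root = t.merges[-1][3]
    a, b, h, _ = t.merges[-1]
    return f"({render(a, h)},{render(b, h)});"


def cluster_purity(t: Dendrogram, labels: Sequence[str], k: int) -> float:
    """Majority-label purity of the k-cluster cut of the tree.

    The tree is cut into ``k`` clusters by removing the ``k - 1`` highest
    merges; purity is the summed majority-class count per cluster over the
    number of leaves (1.0 = every cluster is single-species).
    """
    labels = [str(l) for l in labels]
    if len(labels) != t.n_leaves:
        raise DataError("labels must parallel the dendrogram leaves")
    assign = t.cut(k)
    total = 0
    for cluster in set(assign):
        members = [labels[i] for i in range(len(labels)) if assign[i] == cluster]
        counts = {}
        for l in members:
            counts[l] = counts.get(l, 0) + 1
        total += max(counts.values())
    return total / t.n_leaves
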