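"""Agglomerative clustering of individuals into functional-size nodes.

Clustering operates on a single trait per side (predicted nectar holder
depth for flowers, intertegular distance for bees) with Euclidean, i.e.
absolute-difference, distances and average (UPGMA) linkage.  Two cut modes
are supported: constrained (number of nodes fixed to the species count of
that side) and unconstrained (number of nodes chosen by a majority vote of
cluster-validity indices).

The merge order is fully deterministic: when several cluster pairs are at
the minimal average distance, the pair whose members carry the lowest
original leaf indices (smaller index first, then larger) is merged.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "MergeTree",
    "NodeSummary",
    "ClusterNodes",
    "pairwise_distance",
    "agglomerate",
    "cut_clusters",
    "cut_labels",
    "optimal_k",
    "DEFAULT_INDEX_PANEL",
]


@dataclass(frozen=True)
class MergeTree:
    """A UPGMA dendrogram over 1-D trait values.

    Leaves are numbered ``0..n-1`` in input order; the merge at position
    ``t`` (0-based) creates cluster ``n + t``, following the scipy linkage
    convention.  ``merges`` holds ``(cluster_a, cluster_b, height)`` with
    ``cluster_a < cluster_b`` and non-decreasing heights.
    """

    values: tuple[float, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NodeSummary:
    trait_min: float
    trait_max: float
    trait_mean: float
    size: int
    species: Mapping[str, int]


@dataclass
class ClusterNodes:
    """Assignment of individuals to functional-size nodes for one side.

    Node ids are ``B01..Bk`` (bees) or ``F01..Fk`` (flowers), ordered by
    ascending mean trait.
    """

    side: str
    k: int
    labels: dict[str, str]  # individual id -> node id
    nodes: dict[str, NodeSummary] = field(default_factory=dict)

    def node_order(self) -> list[str]:
        return sorted(self.nodes)


def pairwise_distance(values: Sequence[float]) -> np.ndarray:
    """Full matrix of 1-D Euclidean distances ``d(i, j) = |x_i - x_j|``."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    return np.abs(x[:, None] - x[None, :])


def agglomerate(values: Sequence[float], linkage: str = "average") -> MergeTree:
    """UPGMA clustering of 1-D trait values.

    At each step the pair of clusters with minimal average pairwise
    inter-cluster distance is merged (Lance-Williams update, which is exact
    for average linkage).  Ties break toward the pair with the lowest
    (smaller, then larger) original leaf indices, where a cluster is
    represented by its smallest member index.
    """
    if linkage != "average":
        raise ValueError(f"only 'average' linkage is supported, got {linkage!r}")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    D = pairwise_distance(x)
    np.fill_diagonal(D, np.inf)

    # slot bookkeeping: each active slot holds one cluster
    cluster_id = list(range(n))  # slot -> scipy-style cluster id
    rep = list(range(n))  # slot -> smallest original leaf index
    size = [1] * n
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        # minimal distance over active pairs, deterministic tie-break
        act = np.array(active)
        sub = D[np.ix_(act, act)]
        iu, ju = np.triu_indices(len(act), k=1)
        vals = sub[iu, ju]
        m_min = vals.min()
        a = b = -1
        best_key = None
        for idx in np.nonzero(vals == m_min)[0]:
            ca, cb = int(act[iu[idx]]), int(act[ju[idx]])
            key = (min(rep[ca], rep[cb]), max(rep[ca], rep[cb]))
            if best_key is None or key < best_key:
                best_key, a, b = key, ca, cb
        height = float(D[a, b])
        lo, hi = sorted((cluster_id[a], cluster_id[b]))
        merges.append((lo, hi, height))
        # Lance-Williams average-linkage update into slot a
        sa, sb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = (sa * D[a, c] + sb * D[b, c]) / (sa + sb)
        size[a] = sa + sb
        rep[a] = min(rep[a], rep[b])
        cluster_id[a] = n + step
        active.remove(b)
        D[b, :] = np.inf
        D[:, b] = np.inf
    return MergeTree(values=tuple(float(v) for v in x), merges=tuple(merges))


def cut_labels(tree: MergeTree, k: int) -> np.ndarray:
    """Flat cluster labels (0-based, arbitrary numbering) for a k-cluster cut."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t, (a, b, _h) in enumerate(tree.merges[: n - k]):
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for leaf in range(n):
        r = find(leaf)
        out[leaf] = roots.setdefault(r, len(roots))
    return out


def cut_clusters(
    tree: MergeTree,
    k: int,
    ids: Sequence[str],
    species: Sequence[str],
    side: str,
) -> ClusterNodes:
    """Cut the dendrogram into ``k`` nodes with labels, ranges and composition.

    ``ids`` and ``species`` run parallel to the tree leaves.  Node ids are
    assigned by ascending mean trait; in 1-D UPGMA the resulting trait
    ranges never interleave.
    """
    if len(ids) != tree.n_leaves or len(species) != tree.n_leaves:
        raise ValueError("ids/species must match the number of leaves")
    if side not in ("bee", "plant"):
        raise ValueError(f"side must be 'bee' or 'plant', got {side!r}")
    flat = cut_labels(tree, k)
    values = np.asarray(tree.values)
    means = [values[flat == c].mean() for c in range(k)]
    order = sorted(range(k), key=lambda c: (means[c], c))
    prefix = "B" if side == "bee" else "F"
    width = max(2, len(str(k)))
    node_of = {c: f"{prefix}{rank + 1:0{width}d}" for rank, c in enumerate(order)}

    labels = {ids[i]: node_of[flat[i]] for i in range(tree.n_leaves)}
    nodes: dict[str, NodeSummary] = {}
    for c in range(k):
        mask = flat == c
        members = values[mask]
        comp = Counter(sp for sp, m in zip(species, mask) if m)
        nodes[node_of[c]] = NodeSummary(
            trait_min=float(members.min()),
            trait_max=float(members.max()),
            trait_mean=float(members.mean()),
            size=int(mask.sum()),
            species=dict(sorted(comp.items())),
        )
    return ClusterNodes(side=side, k=k, labels=labels, nodes=nodes)


# ---------------------------------------------------------------------------
# optimal number of clusters


def _dunn(x: np.ndarray, labels: np.ndarray) -> float:
    clusters = [x[labels == c] for c in np.unique(labels)]
    diam = max(float(np.ptp(c)) if len(c) > 1 else 0.0 for c in clusters)
    sep = min(
        float(np.min(np.abs(a[:, None] - b[None, :])))
        for a, b in itertools.combinations(clusters, 2)
    )
    if diam == 0.0:
        return np.inf if sep > 0 else 0.0
    return sep / diam

def _c_index(x: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(x), k=1)
    d = np.abs(x[:, None] - x[None, :])[iu]
    within = (labels[:, None] == labels[None, :])[iu]
    n_w = int(within.sum())
    if n_w == 0:
        return 0.5
    s = float(d[within].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        return 0.5
    return (s - s_min) / (s_max - s_min)


#: (name, score function on (X, labels), direction) — direction +1 maximizes.
DEFAULT_INDEX_PANEL = (
    ("silhouette", lambda X, lab: silhouette_score(X, lab), +1),
    ("calinski_harabasz", lambda X, lab: calinski_harabasz_score(X, lab), +1),
    ("davies_bouldin", lambda X, lab: davies_bouldin_score(X, lab), -1),
    ("dunn", lambda X, lab: _dunn(X[:, 0], lab), +1),
    ("c_index", lambda X, lab: _c_index(X[:, 0], lab), -1),
)


def optimal_k(
    values: Sequence[float],
    k_range: Sequence[int] | None = None,
    panel=DEFAULT_INDEX_PANEL,
) -> tuple[int, dict[str, int]]:
    """Choose the number of clusters by a majority vote of validity indices.

    Average-linkage cuts are evaluated for each candidate ``k`` (default
    ``2..min(15, n - 1)``) under a five-index panel: silhouette,
    Calinski-Harabasz, Dunn (maximized), Davies-Bouldin, C-index
    (minimized).  Each index votes for its best ``k``; ties in an index and
    in the vote both resolve toward the smallest ``k``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"optimal_k needs n >= 4, got {n}")
    if k_range is None:
        k_range = range(2, min(15, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("empty k_range after bounds check")
    tree = agglomerate(x)
    X = x.reshape(-1, 1)
    cuts = {k: cut_labels(tree, k) for k in k_range}
    votes: dict[str, int] = {}
    for name, score_fn, direction in panel:
        best_k, best_score = None, None
        for k in k_range:
            lab = cuts[k]
            if len(np.unique(lab)) < 2:
                continue
            try:
                score = direction * float(score_fn(X, lab))
            except ValueError:
                continue
            if best_score is None or score > best_score:
                best_k, best_score = k, score
        if best_k is not None:
            votes[name] = best_k
    if not votes:
        raise ValueError("no validity index produced a score")
    counts = Counter(votes.values())
    top = max(counts.values())
    k_best = min(k for k, c in counts.items() if c == top)
    return k_best, votes
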