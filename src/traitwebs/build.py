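"""Aggregation of interaction records into quantitative bipartite matrices.

The interaction weight is always the visit count; matrices are never
binarized.  Rows are plant nodes, columns are bee nodes, and both are
ordered by ascending mean member trait (ties by label), matching the
smallest-to-largest node layout used for network figures.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from traitwebs.clustering import ClusterNodes
from traitwebs.data import InteractionRecord

__all__ = ["QuantNetwork", "build_species_network", "build_trait_network"]


@dataclass
class QuantNetwork:
    """A quantitative bipartite network: plant nodes x bee nodes."""

    matrix: np.ndarray  # non-negative integer counts
    row_labels: list[str]
    col_labels: list[str]
    row_meta: dict = field(default_factory=dict)
    col_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if (self.matrix < 0).any():
            raise ValueError("matrix must be non-negative")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if self.matrix.size and (
            (self.matrix.sum(axis=1) == 0).any() or (self.matrix.sum(axis=0) == 0).any()
        ):
            raise ValueError("matrix has an all-zero row or column")

    @property
    def m(self) -> int:
        """Total number of interactions."""
        return int(self.matrix.sum())

    @property
    def n_plants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bees(self) -> int:
        return self.matrix.shape[1]


def _ordered_labels(trait_sums: dict[str, float], counts: dict[str, int]) -> list[str]:
    # ascending mean member trait, ties by label
    return sorted(trait_sums, key=lambda s: (trait_sums[s] / counts[s], s))


def build_species_network(
    records: Sequence[InteractionRecord],
    plant_size: Mapping[str, float] | None = None,
    bee_size: Mapping[str, float] | None = None,
) -> QuantNetwork:
    """Species-based network: one node per species, weight = visit count.

    ``plant_size`` / ``bee_size`` optionally map record_id to the functional
    size used for node ordering (predicted NHD, measured ITD); without them
    the raw floral display size and ITD from the records are used.
    """
    if not records:
        raise ValueError("no interaction records")
    p_sum: dict[str, float] = defaultdict(float)
    p_cnt: dict[str, int] = defaultdict(int)
    b_sum: dict[str, float] = defaultdict(float)
    b_cnt: dict[str, int] = defaultdict(int)
    pairs: Counter[tuple[str, str]] = Counter()
    for r in records:
        psz = plant_size[r.record_id] if plant_size is not None else r.fds_mm
        bsz = bee_size[r.record_id] if bee_size is not None else r.itd_mm
        p_sum[r.plant_species] += psz
        p_cnt[r.plant_species] += 1
        b_sum[r.bee_species] += bsz
        b_cnt[r.bee_species] += 1
        pairs[(r.plant_species, r.bee_species)] += 1
    rows = _ordered_labels(p_sum, p_cnt)
    cols = _ordered_labels(b_sum, b_cnt)
    matrix = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {s: i for i, s in enumerate(rows)}
    ci = {s: j for j, s in enumerate(cols)}
    for (p, b), w in pairs.items():
        matrix[ri[p], ci[b]] = w
    row_meta = {
        s: {"kind": "species", "n_records": p_cnt[s], "mean_size_mm": p_sum[s] / p_cnt[s]}
        for s in rows
    }
    col_meta = {
        s: {"kind": "species", "n_records": b_cnt[s], "mean_size_mm": b_sum[s] / b_cnt[s]}
        for s in cols
    }
    return QuantNetwork(matrix, rows, cols, row_meta, col_meta)


def build_trait_network(
    records: Sequence[InteractionRecord],
    plant_nodes: ClusterNodes,
    bee_nodes: ClusterNodes,
) -> QuantNetwork:
    """Trait-based network: nodes are functional-size clusters of individuals.

    Each record contributes one visit to the cell (plant node of its flower,
    bee node of its bee); the total interaction count is preserved.
    """
    if not records:
        raise ValueError("no interaction records")
    pairs: Counter[tuple[str, str]] = Counter()
    for r in records:
        try:
            p_node = plant_nodes.labels[r.record_id]
            b_node = bee_nodes.labels[r.record_id]
        except KeyError as exc:
            raise KeyError(
                f"record {r.record_id!r} has no cluster assignment on one side"
            ) from exc
        pairs[(p_node, b_node)] += 1
    # cluster ids sort by ascending mean trait by construction
    rows = [n for n in plant_nodes.node_order() if any(p == n for p, _ in pairs)]
    cols = [n for n in bee_nodes.node_order() if any(b == n for _, b in pairs)]
    matrix = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {s: i for i, s in enumerate(rows)}
    ci = {s: j for j, s in enumerate(cols)}
    for (p, b), w in pairs.items():
        matrix[ri[p], ci[b]] = w

    def _meta(nodes: ClusterNodes, labels: list[str]) -> dict:
        return {
            lab: {
                "kind": "cluster",
                "trait_min_mm": nodes.nodes[lab].trait_min,
                "trait_max_mm": nodes.nodes[lab].trait_max,
                "mean_size_mm": nodes.nodes[lab].trait_mean,
                "n_individuals": nodes.nodes[lab].size,
                "species": dict(nodes.nodes[lab].species),
            }
            for lab in labels
        }

    return QuantNetwork(matrix, rows, cols, _meta(plant_nodes, rows), _meta(bee_nodes, cols))
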