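"""Quantitative network metrics.

Network level: weighted connectance (Cq, entropy-based effective partner
counts after Bersier), weighted nestedness (WNODF, Almeida-Neto & Ulrich),
interaction evenness (IE, Shannon) and complementary specialization (H2').
Node level: specialization (d', standardized Kullback-Leibler divergence
from partner availability) and species strength (sum of dependencies).

Log bases follow the source definitions: base 2 inside Cq's effective
partner numbers, natural log everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricReport",
    "weighted_connectance",
    "wnodf",
    "interaction_evenness",
    "h2prime",
    "d_prime",
    "strength",
    "metric_report",
]


def _as_matrix(net, drop_empty: bool = False) -> np.ndarray:
    M = np.asarray(getattr(net, "matrix", net), dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("need a non-empty 2-D matrix")
    if (M < 0).any():
        raise ValueError("matrix must be non-negative")
    if M.sum() <= 0:
        raise ValueError("matrix must contain interactions")
    if drop_empty:
        # network-level metrics ignore unobserved nodes, so randomized
        # matrices with empty rows/columns score like their reduced form
        M = M[M.sum(axis=1) > 0][:, M.sum(axis=0) > 0]
    return M


def _shannon(p: np.ndarray, base: float = np.e) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def weighted_connectance(net) -> float:
    """Quantitative (weighted) connectance Cq.

    Each node's effective number of partners is ``2**H`` with ``H`` the
    base-2 Shannon entropy of its interaction proportions; the quantitative
    linkage density ``LDq = (1/2m) * (sum_j B_j n_j + sum_i A_i n_i)`` is
    divided by the total number of nodes ``P + A``.
    """
    M = _as_matrix(net, drop_empty=True)
    m = M.sum()
    A_i = M.sum(axis=1)
    B_j = M.sum(axis=0)
    n_rows = np.array(
        [2.0 ** _shannon(M[i] / A_i[i], base=2.0) if A_i[i] > 0 else 0.0 for i in range(M.shape[0])]
    )
    n_cols = np.array(
        [2.0 ** _shannon(M[:, j] / B_j[j], base=2.0) if B_j[j] > 0 else 0.0 for j in range(M.shape[1])]
    )
    ldq = ((B_j * n_cols).sum() + (A_i * n_rows).sum()) / (2.0 * m)
    return float(ldq / (M.shape[0] + M.shape[1]))


def _wnodf_axis(M: np.ndarray) -> list[float]:
    """Row-pair scores after sorting rows by decreasing totals (stable)."""
    totals = M.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    Ms = M[order]
    t = totals[order]
    scores: list[float] = []
    for u in range(len(t)):
        for v in range(u + 1, len(t)):
            if t[u] > t[v]:
                fill_v = int(np.count_nonzero(Ms[v]))
                if fill_v == 0:
                    scores.append(0.0)
                else:
                    overlap = int(np.count_nonzero((Ms[v] > 0) & (Ms[v] < Ms[u])))
                    scores.append(100.0 * overlap / fill_v)
            else:
                scores.append(0.0)
    return scores


def wnodf(net) -> float:
    """Weighted NODF in [0, 100].

    Rows and columns are ordered by decreasing marginal totals; for each
    ordered pair with strictly decreasing totals the score is the
    percentage of the lower line's nonzero cells that are strictly smaller
    than the corresponding cell of the upper line.  Pairs with tied or
    increasing totals score 0.  WNODF is the mean over all row and column
    pairs.
    """
    M = _as_matrix(net, drop_empty=True)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("WNODF needs at least a 2x2 matrix")
    scores = _wnodf_axis(M) + _wnodf_axis(M.T)
    return float(np.mean(scores))


def interaction_evenness(net, denominator: str = "all_cells") -> float:
    """Shannon interaction evenness in [0, 1].

    ``all_cells`` (default) normalizes the interaction entropy by
    ``ln(P * A)``; ``realized_links`` by the log of the number of nonzero
    cells.
    """
    M = _as_matrix(net, drop_empty=True)
    m = M.sum()
    H = _shannon(M.ravel() / m)
    if denominator == "all_cells":
        denom = np.log(M.shape[0] * M.shape[1])
    elif denominator == "realized_links":
        denom = np.log(np.count_nonzero(M))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        return 0.0
    return float(H / denom)


def _h2_min_greedy(row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    """Entropy of the most heterogeneous margin-preserving integer fill.

    Greedy: repeatedly place ``min(largest remaining row, largest remaining
    column)`` interactions in that cell (ties toward the lowest index).
    """
    r = row_tot.astype(np.int64).copy()
    c = col_tot.astype(np.int64).copy()
    m = r.sum()
    cells: list[float] = []
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        x = min(r[i], c[j])
        cells.append(x / m)
        r[i] -= x
        c[j] -= x
    return _shannon(np.asarray(cells))


def h2prime(net) -> float:
    """Complementary network specialization H2' in [0, 1].

    ``H2' = (H2max - H2) / (H2max - H2min)`` with H2 the natural-log
    entropy of the interaction proportions, H2max the entropy of the
    margin-proportional expected table and H2min the greedy
    largest-remaining-margin integer fill (a heuristic lower bound).
    """
    M = _as_matrix(net, drop_empty=True)
    if M.shape[0] < 2 and M.shape[1] < 2:
        return 0.0  # single node on both sides: specialization undefined
    m = M.sum()
    h2 = _shannon(M.ravel() / m)
    row_tot = M.sum(axis=1)
    col_tot = M.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / (m * m)
    h2_max = _shannon(expected.ravel())
    h2_min = _h2_min_greedy(row_tot, col_tot)
    if h2_max - h2_min <= 1e-12:
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


def _d_raw(counts: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence of a node's partner use from availability."""
    total = counts.sum()
    p = counts / total
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / q[nz])).sum())


def _d_max(total: int, partner_totals: np.ndarray, q: np.ndarray) -> float:
    """d of the most specialized margin-feasible allocation.

    Visits are piled greedily onto partners in order of ascending
    availability, each capped by the partner's own total.
    """
    order = np.argsort(q, kind="stable")
    alloc = np.zeros_like(q)
    remaining = float(total)
    for j in order:
        take = min(remaining, float(partner_totals[j]))
        alloc[j] = take
        remaining -= take
        if remaining <= 0:
            break
    return _d_raw(alloc, q)


def d_prime(net, side: str = "bee") -> np.ndarray:
    """Standardized specialization d' per node of one side, in [0, 1].

    Raw d is the KL divergence of the node's interaction proportions from
    the availability of its potential partners (their share of all
    interactions); it is divided by the d of the most specialized
    margin-feasible allocation (d_min taken as 0).
    """
    M = _as_matrix(net)
    if side == "bee":
        M = M.T  # nodes as rows
    elif side != "plant":
        raise ValueError(f"side must be 'bee' or 'plant', got {side!r}")
    m = M.sum()
    partner_totals = M.sum(axis=0)
    q = partner_totals / m
    out = np.zeros(M.shape[0])
    for i in range(M.shape[0]):
        total = M[i].sum()
        if total <= 0:
            raise ValueError(f"node {i} of side {side!r} has no interactions")
        d = _d_raw(M[i], q)
        dmax = _d_max(total, partner_totals, q)
        out[i] = 0.0 if dmax <= 1e-12 else min(1.0, d / dmax)
    return out


def strength(net, side: str = "bee") -> np.ndarray:
    """Species strength: sum of the opposite side's dependencies on a node.

    A bee's strength is ``sum_i a_ij / A_i`` (its share of each plant's
    visits); a plant's strength is ``sum_j a_ij / B_j``.  Over all nodes
    the bee strengths sum to P and the plant strengths to A.
    """
    M = _as_matrix(net)
    A_i = M.sum(axis=1)
    B_j = M.sum(axis=0)
    if (A_i == 0).any() or (B_j == 0).any():
        raise ValueError("strength undefined with all-zero rows or columns")
    if side == "bee":
        return (M / A_i[:, None]).sum(axis=0)
    if side == "plant":
        return (M / B_j[None, :]).sum(axis=1)
    raise ValueError(f"side must be 'bee' or 'plant', got {side!r}")


@dataclass
class MetricReport:
    """All network- and node-level metrics for one network."""

    cq: float
    wnodf: float
    ie: float
    h2prime: float
    d_prime_bee: np.ndarray
    d_prime_plant: np.ndarray
    strength_bee: np.ndarray
    strength_plant: np.ndarray

    def summary(self) -> dict[str, float]:
        def ms(x: np.ndarray) -> tuple[float, float]:
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            return float(np.mean(x)), sd

        db, db_sd = ms(self.d_prime_bee)
        dp, dp_sd = ms(self.d_prime_plant)
        sb, sb_sd = ms(self.strength_bee)
        sp, sp_sd = ms(self.strength_plant)
        return {
            "Cq": self.cq,
            "WNODF": self.wnodf,
            "IE": self.ie,
            "H2prime": self.h2prime,
            "d_prime_bee_mean": db,
            "d_prime_bee_sd": db_sd,
            "d_prime_plant_mean": dp,
            "d_prime_plant_sd": dp_sd,
            "strength_bee_mean": sb,
            "strength_bee_sd": sb_sd,
            "strength_plant_mean": sp,
            "strength_plant_sd": sp_sd,
        }


def metric_report(net, ie_denominator: str = "all_cells") -> MetricReport:
    """Compute every metric for a network (WNODF is NaN below 2x2)."""
    M = _as_matrix(net)
    can_nest = M.shape[0] >= 2 and M.shape[1] >= 2
    return MetricReport(
        cq=weighted_connectance(M),
        wnodf=wnodf(M) if can_nest else float("nan"),
        ie=interaction_evenness(M, denominator=ie_denominator),
        h2prime=h2prime(M),
        d_prime_bee=d_prime(M, "bee"),
        d_prime_plant=d_prime(M, "plant"),
        strength_bee=strength(M, "bee"),
        strength_plant=strength(M, "plant"),
    )
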