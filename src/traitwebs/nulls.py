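"""Constraint-preserving null models and significance tests.

``patefield_sample`` draws uniformly from contingency tables with both
margins fixed (the r2dtable null model) by sequential multivariate
hypergeometric filling.  Three weaker nestedness nulls are provided:
CRT (conserve row totals), CCT (conserve column totals) and RCTA (conserve
only the grand total, cell probabilities proportional to the average of
the marginal proportions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NullEnsemble",
    "SignificanceResult",
    "NestednessTest",
    "patefield_sample",
    "falcon_null_sample",
    "null_distribution",
    "zscore",
    "nestedness_significance",
]


@dataclass
class NullEnsemble:
    model: str
    n: int
    seed: int | None
    samples: np.ndarray
    n_dropped: int = 0
    drop_messages: list[str] = field(default_factory=list)

    @property
    def n_effective(self) -> int:
        return len(self.samples)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0


@dataclass
class SignificanceResult:
    observed: float
    z: float
    p_two_sided: float
    convention: str  # "standard" | "paper"


@dataclass
class NestednessTest:
    model: str
    observed: float
    z_standard: float
    z_paper: float
    p_two_sided: float
    n_final: int


def _matrix_of(net) -> np.ndarray:
    return np.asarray(getattr(net, "matrix", net), dtype=np.int64)


def patefield_sample(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One uniform draw from tables with the given margins (Patefield).

    Rows are filled sequentially; row ``i`` is a multivariate
    hypergeometric draw of ``row_totals[i]`` items from the remaining
    column capacities, which realizes the exact fixed-margins law.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be non-negative")
    if r.sum() != c.sum() or r.sum() == 0:
        raise ValueError(
            f"margin mismatch: sum(rows)={int(r.sum())} != sum(cols)={int(c.sum())} (or zero)"
        )
    remaining = c.copy()
    out = np.zeros((len(r), len(c)), dtype=np.int64)
    for i, ri in enumerate(r):
        row = rng.multivariate_hypergeometric(remaining, int(ri))
        out[i] = row
        remaining -= row
    return out


def falcon_null_sample(
    matrix,
    model: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw from a weaker nestedness null model.

    CRT: each row total is redistributed over the columns by a multinomial
    with uniform cell probabilities.  CCT: symmetric for columns.  RCTA:
    all ``m`` interactions are placed by a single multinomial with cell
    probability ``(A_i/m + B_j/m) / (P + A)``; only ``m`` is conserved.
    """
    M = _matrix_of(matrix)
    P, A = M.shape
    if model == "CRT":
        out = np.zeros_like(M)
        probs = np.full(A, 1.0 / A)
        for i in range(P):
            out[i] = rng.multinomial(int(M[i].sum()), probs)
        return out
    if model == "CCT":
        return falcon_null_sample(M.T, "CRT", rng).T
    if model == "RCTA":
        m = int(M.sum())
        A_i = M.sum(axis=1) / m
        B_j = M.sum(axis=0) / m
        probs = (A_i[:, None] + B_j[None, :]) / (P + A)
        flat = rng.multinomial(m, probs.ravel())
        return flat.reshape(P, A).astype(np.int64)
    raise ValueError(f"unknown null model {model!r}")


def _sample_matrix(M: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "r2dtable":
        return patefield_sample(M.sum(axis=1), M.sum(axis=0), rng)
    return falcon_null_sample(M, model, rng)


def null_distribution(
    net,
    metric_fn: Callable[[np.ndarray], float],
    model: str = "r2dtable",
    n: int = 1000,
    seed: int | None = None,
) -> NullEnsemble:
    """Metric values on ``n`` randomized matrices; reproducible given seed.

    Samples on which the metric raises are dropped (and logged); the
    ensemble reports its effective size.
    """
    if n < 2:
        raise ValueError("ensemble size must be >= 2")
    M = _matrix_of(net)
    rng = np.random.default_rng(seed)
    samples: list[float] = []
    drops: list[str] = []
    for _ in range(n):
        rand = _sample_matrix(M, model, rng)
        try:
            samples.append(float(metric_fn(rand)))
        except (ValueError, ZeroDivisionError) as exc:
            drops.append(str(exc))
    return NullEnsemble(
        model=model,
        n=n,
        seed=seed,
        samples=np.asarray(samples),
        n_dropped=len(drops),
        drop_messages=drops[:10],
    )


def _empirical_p(observed: float, samples: np.ndarray) -> float:
    """Two-sided empirical p with add-one smoothing."""
    n = len(samples)
    n_ge = int(np.count_nonzero(samples >= observed))
    n_le = int(np.count_nonzero(samples <= observed))
    r = min(n_ge, n_le)
    return min(1.0, 2.0 * (r + 1) / (n + 1))


def zscore(
    observed: float,
    ensemble: NullEnsemble,
    convention: str = "standard",
) -> SignificanceResult:
    """z-score and empirical two-sided p against a null ensemble.

    ``standard``: z = (obs - null_mean) / null_sd.  ``paper``: the sign is
    flipped, so positive z means the observed value lies below the null
    mean.  With null_sd = 0 the z is undefined (NaN) and p comes from tie
    counting alone.
    """
    if convention not in ("standard", "paper"):
        raise ValueError(f"unknown z convention {convention!r}")
    sd = ensemble.null_sd
    if sd > 0:
        z = (observed - ensemble.null_mean) / sd
        if convention == "paper":
            z = -z
    else:
        z = float("nan")
    return SignificanceResult(
        observed=float(observed),
        z=float(z),
        p_two_sided=_empirical_p(observed, ensemble.samples),
        convention=convention,
    )


def nestedness_significance(
    net,
    metric_fn: Callable[[np.ndarray], float],
    models: Sequence[str] = ("CRT", "CCT", "RCTA"),
    start_n: int = 500,
    max_n: int = 10000,
    p_tol: float = 0.005,
    seed: int | None = None,
) -> dict[str, NestednessTest]:
    """Adaptive-ensemble nestedness test per null model.

    The ensemble starts at ``start_n`` samples and doubles until the
    empirical p changes by less than ``p_tol`` between stages or ``max_n``
    is reached.
    """
    M = _matrix_of(net)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("nestedness test needs at least a 2x2 matrix")
    observed = float(metric_fn(M))
    results: dict[str, NestednessTest] = {}
    for mi, model in enumerate(models):
        rng = np.random.default_rng(None if seed is None else seed + 7919 * mi)
        samples: list[float] = []

        def grow(target: int) -> None:
            while len(samples) < target:
                rand = _sample_matrix(M, model, rng)
                try:
                    samples.append(float(metric_fn(rand)))
                except (ValueError, ZeroDivisionError):
                    continue

        grow(start_n)
        p_prev = _empirical_p(observed, np.asarray(samples))
        n = start_n
        while n < max_n:
            n = min(2 * n, max_n)
            grow(n)
            p_new = _empirical_p(observed, np.asarray(samples))
            if abs(p_new - p_prev) < p_tol:
                p_prev = p_new
                break
            p_prev = p_new
        arr = np.asarray(samples)
        ens = NullEnsemble(model=model, n=len(arr), seed=seed, samples=arr)
        z_std = zscore(observed, ens, "standard")
        results[model] = NestednessTest(
            model=model,
            observed=observed,
            z_standard=z_std.z,
            z_paper=-z_std.z if np.isfinite(z_std.z) else float("nan"),
            p_two_sided=p_prev,
            n_final=len(arr),
        )
    return results
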