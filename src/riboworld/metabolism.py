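"""The shared implicit-metabolism arithmetic and broken-stick sampling.

The metabolism is a hypothetical reaction network needing all ``A``
enzymatic activities at once: the metabolic function of an environment
(a surface neighbourhood or a vesicle) is the geometric mean of the
per-activity summed strengths, so it is zero as soon as any single
activity is missing.  Replication lotteries weigh each contestant by
its claim ``C = R * M`` and sample one winner by the broken-stick
(roulette-wheel) method.
"""

from __future__ import annotations

import math
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "metabolic_function",
    "replication_claim",
    "broken_stick",
    "broken_stick_index",
    "EMPTY_SITE",
]

#: token naming the "no event / stay empty" owner in claim lists
EMPTY_SITE = "__empty__"


def metabolic_function(sums: Sequence[float] | np.ndarray, A: int | None = None) -> float:
    """Geometric mean ``M = (prod_e s_e)**(1/A)`` of activity sums.

    Zero whenever any activity sum is zero (an incomplete metabolism
    produces no monomers).  Computed in log space when all sums are
    positive, for robustness at large A.
    """
    s = np.asarray(sums, dtype=float)
    if A is None:
        A = s.shape[0]
    elif s.shape[0] != A:
        raise ValueError(f"expected {A} activity sums, got {s.shape[0]}")
    if A < 1:
        raise ValueError("A must be >= 1")
    if np.any(s < 0):
        raise ValueError("activity sums must be non-negative")
    if np.any(s == 0):
        return 0.0
    return float(math.exp(np.log(s).sum() / A))


def replication_claim(R: float, M: float) -> float:
    """Replication claim ``C = R * M`` of one replicator."""
    if R <= 0:
        raise ValueError("replicability must be positive")
    if M < 0:
        raise ValueError("metabolic support must be non-negative")
    return R * M


def broken_stick_index(
    values: np.ndarray, rng: np.random.Generator, u: float | None = None
) -> int:
    """Broken-stick draw over non-negative weights; returns an index.

    Consumes exactly one uniform variate (or uses the supplied one);
    returns -1 without consuming randomness when all weights are zero.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0.0:
        return -1
    if u is None:
        u = rng.random()
    idx = int(np.searchsorted(np.cumsum(values), u * total, side="right"))
    return min(idx, values.shape[0] - 1)  # guard the u -> 1 rounding edge


def broken_stick(
    claims: dict[Hashable, float] | Sequence[tuple[Hashable, float]],
    rng: np.random.Generator,
    default: Hashable = EMPTY_SITE,
) -> Hashable:
    """Sample one owner with probability proportional to its claim.

    ``claims`` maps owners to non-negative weights.  With an all-zero
    total the designated default owner is returned and no randomness is
    consumed.
    """
    items = list(claims.items()) if isinstance(claims, dict) else list(claims)
    weights = np.array([v for _, v in items], dtype=float)
    if np.any(weights < 0):
        raise ValueError("claims must be non-negative")
    idx = broken_stick_index(weights, rng)
    if idx < 0:
        return default
    return items[idx][0]
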