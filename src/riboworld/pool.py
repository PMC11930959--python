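"""Random replicator pools and catalytic enrichment.

Both models are initialised from an unevolved pool of random RNA
sequences: lengths Poisson(lambda = 45), bases i.i.d. uniform.  Because
random sequences are rarely catalytic, the pool is "enriched" by
duplicating randomly chosen active entries until a target fraction
(default 80%) of entries carries at least one enzymatic activity —
a bootstrap guaranteeing at least a few metabolically complete seed
neighbourhoods on a finite lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import Chemistry, Replicator
from .folding import MIN_FOLDABLE_LENGTH, RNA_BASES

__all__ = ["ReplicatorPool", "random_pool", "enrich_pool", "EnrichmentError"]


class EnrichmentError(RuntimeError):
    """No catalytically active entry to duplicate; use a larger pool."""


@dataclass
class ReplicatorPool:
    """A list of replicators with their cached traits."""

    entries: list[Replicator]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def active_fraction(self) -> float:
        if not self.entries:
            return 0.0
        return sum(r.traits.is_active for r in self.entries) / len(self.entries)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.entries]


def random_pool(
    n: int, lam: float, chem: Chemistry, rng: np.random.Generator
) -> ReplicatorPool:
    """``n`` random sequences with Poisson(lam) lengths (truncated at >= 8)."""
    if n < 1:
        raise ValueError("pool size must be >= 1")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    lengths = rng.poisson(lam, size=n)
    lengths = np.maximum(lengths, MIN_FOLDABLE_LENGTH)
    entries = []
    for L in lengths:
        seq = "".join(np.array(list(RNA_BASES))[rng.integers(0, 4, size=int(L))])
        entries.append(chem.replicator(seq))
    return ReplicatorPool(entries)


def enrich_pool(
    pool: ReplicatorPool,
    rng: np.random.Generator,
    target_fraction: float = 0.8,
) -> ReplicatorPool:
    """Duplicate active entries until ``active_fraction >= target_fraction``.

    Original entries are retained; a new pool is returned.  Raises
    :class:`EnrichmentError` when the pool holds no active entry.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target fraction must be in [0, 1]")
    entries = list(pool.entries)
    active = [r for r in entries if r.traits.is_active]
    n_active = len(active)
    if pool.active_fraction >= target_fraction:
        return ReplicatorPool(entries)
    if n_active == 0:
        raise EnrichmentError(
            "pool has no catalytically active replicator; generate a larger pool"
        )
    while n_active / len(entries) < target_fraction:
        entries.append(active[rng.integers(len(active))])
        n_active += 1
    return ReplicatorPool(entries)
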