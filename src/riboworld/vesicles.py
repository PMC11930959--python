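"""The Stochastic Corrector Model: replicator communities in vesicles.

N compartments each hold 0..S-1 replicators.  An update step is one
degradation event (a pooled broken-stick draw over every replicator's
{P_deg, 1-P_deg} tokens — equivalently, a uniformly chosen replicator
degrades with its own P_deg) followed by one replication event (claims
C = M_v * R pooled over all vesicles; the winner appends a mutagenic
complementary copy to its own vesicle).  A vesicle reaching the split
size S immediately fissions into daughters of sizes floor(S/2) and
ceil(S/2) assorted hypergeometrically (uniform without-replacement
sampling); one daughter keeps the parent slot, the other overwrites a
random other compartment, so N is constant.  One SCM timestep is
floor(N*(S-1)/2) update steps, making the event count comparable to a
lattice generation.

Vesicle-level selection arises implicitly: metabolically incomplete
vesicles (M_v = 0) never replicate, and fission randomly re-assorts
communities (the stochastic corrector's heritable variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import Chemistry, Replicator
from .folding import MIN_FOLDABLE_LENGTH
from .metabolism import metabolic_function

__all__ = ["SCMParams", "Vesicle", "SCMPopulation"]


@dataclass(frozen=True)
class SCMParams:
    N: int = 1000  # number of compartments
    S: int = 90    # split size

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.S < 2:
            raise ValueError("S must be >= 2")

    @property
    def steps_per_timestep(self) -> int:
        return self.N * (self.S - 1) // 2


class Vesicle:
    """One compartment; caches its activity sums, M_v and summed R."""

    __slots__ = ("members", "act_sums", "M", "R_sum")

    def __init__(self, members: list[Replicator] | None = None, A: int = 1) -> None:
        self.members: list[Replicator] = list(members) if members else []
        self.act_sums = np.zeros(A)
        self.M = 0.0
        self.R_sum = 0.0
        self._recompute(A)

    def _recompute(self, A: int) -> None:
        if self.members:
            self.act_sums = np.sum([r.traits.activities for r in self.members], axis=0)
            self.R_sum = float(sum(r.traits.R for r in self.members))
        else:
            self.act_sums = np.zeros(A)
            self.R_sum = 0.0
        self.M = metabolic_function(self.act_sums)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_complete(self) -> bool:
        """True iff every activity is represented (equivalently M_v > 0)."""
        return bool(np.all(self.act_sums > 0))

    def add(self, rep: Replicator) -> None:
        self.members.append(rep)
        self._recompute(self.act_sums.shape[0])

    def remove(self, index: int) -> Replicator:
        rep = self.members.pop(index)
        self._recompute(self.act_sums.shape[0])
        return rep


class SCMPopulation:
    """Fixed-size population of N vesicles over a shared chemistry."""

    def __init__(
        self,
        vesicles: list[Vesicle],
        params: SCMParams,
        chem: Chemistry,
        rng: np.random.Generator,
    ) -> None:
        if len(vesicles) != params.N:
            raise ValueError(f"expected {params.N} vesicles, got {len(vesicles)}")
        for v in vesicles:
            if v.size > params.S:
                raise ValueError("vesicles cannot start above the split size")
        self.vesicles = vesicles
        self.params = params
        self.chem = chem
        self.rng = rng
        self.update_steps = 0
        self.timesteps = 0
        self.n_degradations = 0
        self.n_replications = 0
        self.n_splits = 0

    @classmethod
    def empty(
        cls, params: SCMParams, chem: Chemistry, rng: np.random.Generator
    ) -> "SCMPopulation":
        A = chem.rules.A
        return cls([Vesicle(A=A) for _ in range(params.N)], params, chem, rng)

    # -- observables -----------------------------------------------------

    @property
    def n_replicators(self) -> int:
        return sum(v.size for v in self.vesicles)

    @property
    def n_nonempty(self) -> int:
        return sum(v.size > 0 for v in self.vesicles)

    @property
    def n_complete(self) -> int:
        return sum(v.is_complete for v in self.vesicles)

    def replicators(self) -> list[Replicator]:
        return [r for v in self.vesicles for r in v.members]

    # -- events ----------------------------------------------------------

    def degradation_event(self) -> None:
        """Pick a uniform replicator; degrade it with its P_deg.

        Identical in law to one broken-stick draw over the pooled
        {P_deg, 1 - P_deg} tokens of all replicators, because every
        replicator's total token mass is 1.  No-op on an empty
        population.
        """
        sizes = np.fromiter((v.size for v in self.vesicles), dtype=np.int64,
                            count=len(self.vesicles))
        total = int(sizes.sum())
        if total == 0:
            return
        k = int(self.rng.integers(total))
        vi = int(np.searchsorted(np.cumsum(sizes), k, side="right"))
        offset = k - int(np.cumsum(sizes)[vi - 1]) if vi > 0 else k
        ves = self.vesicles[vi]
        rep = ves.members[offset]
        if self.rng.random() < rep.traits.P_deg:
            ves.remove(offset)
            self.n_degradations += 1

    def degradation_event_pooled(self) -> None:
        """Reference implementation: explicit 2n-token broken stick."""
        reps = [(vi, i) for vi, v in enumerate(self.vesicles) for i in range(v.size)]
        if not reps:
            return
        tokens = []
        for vi, i in reps:
            p = self.vesicles[vi].members[i].traits.P_deg
            tokens.append((("deg", vi, i), p))
            tokens.append((("live", vi, i), 1.0 - p))
        from .metabolism import broken_stick

        kind, vi, i = broken_stick(tokens, self.rng)
        if kind == "deg":
            self.vesicles[vi].remove(i)
            self.n_degradations += 1

    def replication_event(self) -> None:
        """Pooled broken-stick over all claims C = M_v * R; copy + split."""
        weights = np.fromiter(
            (v.M * v.R_sum for v in self.vesicles), dtype=float,
            count=len(self.vesicles),
        )
        total = weights.sum()
        if total <= 0.0:
            return
        u = self.rng.random() * total
        cum = np.cumsum(weights)
        vi = min(int(np.searchsorted(cum, u, side="right")), len(weights) - 1)
        ves = self.vesicles[vi]
        # within the vesicle, claims are proportional to R (common factor M_v)
        rs = np.fromiter((r.traits.R for r in ves.members), dtype=float,
                         count=ves.size)
        # the same uniform, restricted to this vesicle's segment of the stick,
        # rescaled from claim units (M_v * R) to R units: one pooled draw overall
        inner = (u - (cum[vi - 1] if vi > 0 else 0.0)) / ves.M
        ri = min(int(np.searchsorted(np.cumsum(rs), inner, side="right")), ves.size - 1)
        template = ves.members[ri].sequence
        copy = self.chem.mutate_copy(template, self.rng)
        if len(copy) < MIN_FOLDABLE_LENGTH:
            return
        ves.add(self.chem.replicator(copy))
        self.n_replications += 1
        if ves.size == self.params.S:
            self.split_vesicle(vi)

    def split_vesicle(self, index: int) -> None:
        """Hypergeometric fission of a full vesicle; N stays constant."""
        params = self.params
        parent = self.vesicles[index]
        if parent.size != params.S:
            raise RuntimeError("split requires a vesicle holding exactly S replicators")
        order = self.rng.permutation(params.S)
        half = params.S // 2
        members = parent.members
        d1 = [members[i] for i in order[:half]]
        d2 = [members[i] for i in order[half:]]
        A = self.chem.rules.A
        if self.rng.random() < 0.5:
            d1, d2 = d2, d1
        self.vesicles[index] = Vesicle(d1, A=A)
        other = int(self.rng.integers(params.N - 1)) if params.N > 1 else None
        if other is not None:
            if other >= index:
                other += 1
            self.vesicles[other] = Vesicle(d2, A=A)
        self.n_splits += 1

    def update_step(self) -> None:
        """One degradation event then one replication event."""
        self.degradation_event()
        self.replication_event()
        self.update_steps += 1

    def run_timestep(self) -> None:
        """floor(N*(S-1)/2) update steps = one SCM timestep."""
        for _ in range(self.params.steps_per_timestep):
            self.update_step()
        self.timesteps += 1

    def run(self, timesteps: int, recorder=None, record_every: int = 1) -> None:
        for _ in range(timesteps):
            self.run_timestep()
            if recorder is not None and self.timesteps % record_every == 0:
                recorder(self)
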