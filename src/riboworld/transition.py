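"""Moving replicator communities from the surface into vesicles.

The prebiotic take-off is modelled by sampling circular patches of the
lattice ("melting" vesicles off the surface) and enclosing their
replicator content in SCM compartments.  Patch diameters follow a
truncated Gaussian; sampling copies replicators, leaving the source
lattice unchanged (the sampled surface run is reported not to change
significantly during sampling).

Four SCM initialisation modes are supported: ``random`` (each vesicle
filled with pool draws), ``single`` (one sampled vesicle), ``simultaneous``
(n_sampling vesicles from one lattice snapshot) and ``sequential``
(n_sampling fresh samples per generation from a co-running surface
simulation over dt_trans generations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import Chemistry, Replicator
from .pool import ReplicatorPool
from .surface import Lattice, SurfaceSimulation
from .vesicles import SCMParams, SCMPopulation, Vesicle

__all__ = [
    "TransitionParams",
    "sample_circle",
    "sample_vesicle",
    "initialize_scm",
    "vesicle_completeness",
]

MODES = ("random", "single", "simultaneous", "sequential")


@dataclass(frozen=True)
class TransitionParams:
    """Sampling-circle and initialisation parameters.

    The Gaussian diameter defaults are chosen so that, on a lattice at
    the typical ~80% quasi-stationary occupancy, a patch contains ~35
    replicators on average (0.8 * pi * (7.5/2)^2 ~= 35.3).
    """

    n_sampling: int = 100       # vesicles sampled per transition event
    diameter_mean: float = 7.5  # cells
    diameter_sd: float = 1.0    # cells
    diameter_min: float = 2.0   # truncation floor (cells)
    dt_trans: int = 10          # generations of sequential sampling
    n_init: int = 20            # replicators per vesicle for random init
    mode: str = "simultaneous"

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def sample_circle(
    lattice: Lattice, centre: tuple[int, int], diameter: float
) -> list[Replicator]:
    """Copies of all replicators within toroidal distance diameter/2.

    The centre is a cell coordinate; distances are Euclidean with
    wrap-around.  The lattice is not modified.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    Z = lattice.Z
    cy, cx = centre
    radius = diameter / 2.0
    r_int = int(np.floor(radius))
    out: list[Replicator] = []
    if 2 * r_int + 1 >= Z:
        # the window would wrap onto itself: scan every cell once with
        # the toroidal metric
        for y in range(Z):
            for x in range(Z):
                dy = min(abs(y - cy), Z - abs(y - cy))
                dx = min(abs(x - cx), Z - abs(x - cx))
                if dy * dy + dx * dx > radius * radius:
                    continue
                pid = lattice.grid[y, x]
                if pid >= 0:
                    out.append(lattice.chem.replicator_by_id(int(pid)))
        return out
    for dy in range(-r_int, r_int + 1):
        for dx in range(-r_int, r_int + 1):
            if dy * dy + dx * dx > radius * radius:
                continue
            pid = lattice.grid[(cy + dy) % Z, (cx + dx) % Z]
            if pid >= 0:
                out.append(lattice.chem.replicator_by_id(int(pid)))
    return out


def sample_vesicle(
    lattice: Lattice,
    params: TransitionParams,
    chem: Chemistry,
    rng: np.random.Generator,
    max_size: int | None = None,
) -> Vesicle:
    """One sampling event: random centre, Gaussian (truncated) diameter.

    If the patch holds more than ``max_size`` replicators (it must stay
    below the SCM split size), a uniform random subset of that size is
    kept.
    """
    Z = lattice.Z
    centre = (int(rng.integers(Z)), int(rng.integers(Z)))
    diameter = max(
        params.diameter_min, float(rng.normal(params.diameter_mean, params.diameter_sd))
    )
    members = sample_circle(lattice, centre, diameter)
    if max_size is not None and len(members) > max_size:
        keep = rng.choice(len(members), size=max_size, replace=False)
        members = [members[int(i)] for i in keep]
    return Vesicle(members, A=chem.rules.A)


def vesicle_completeness(vesicle: Vesicle, A: int | None = None) -> bool:
    """True iff every activity has positive summed strength (M_v > 0)."""
    if A is not None and vesicle.act_sums.shape[0] != A:
        raise ValueError("vesicle was built for a different system size A")
    return vesicle.is_complete


def initialize_scm(
    mode: str,
    params: TransitionParams,
    scm_params: SCMParams,
    chem: Chemistry,
    rng: np.random.Generator,
    pool: ReplicatorPool | None = None,
    lattice: Lattice | None = None,
    surface_sim: SurfaceSimulation | None = None,
) -> SCMPopulation:
    """Build an SCM population in one of the four initialisation modes."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    A = chem.rules.A
    N = scm_params.N

    if mode == "random":
        if pool is None:
            raise ValueError("random initialisation needs a pool")
        seqs = pool.sequences()
        vesicles = []
        for _ in range(N):
            picks = rng.integers(0, len(seqs), size=params.n_init)
            vesicles.append(Vesicle([chem.replicator(seqs[i]) for i in picks], A=A))
        return SCMPopulation(vesicles, scm_params, chem, rng)

    if mode == "single":
        if lattice is None:
            raise ValueError("single-vesicle initialisation needs a lattice")
        vesicles = [sample_vesicle(lattice, params, chem, rng, scm_params.S - 1)]
        vesicles += [Vesicle(A=A) for _ in range(N - 1)]
        return SCMPopulation(vesicles, scm_params, chem, rng)

    if mode == "simultaneous":
        if lattice is None:
            raise ValueError("simultaneous initialisation needs a lattice")
        if params.n_sampling > N:
            raise ValueError("n_sampling exceeds the number of compartments")
        vesicles = [
            sample_vesicle(lattice, params, chem, rng, scm_params.S - 1)
            for _ in range(params.n_sampling)
        ]
        vesicles += [Vesicle(A=A) for _ in range(N - params.n_sampling)]
        return SCMPopulation(vesicles, scm_params, chem, rng)

    # sequential: co-run the surface simulation, injecting samples per generation
    if surface_sim is None:
        raise ValueError("sequential initialisation needs a running surface simulation")
    if params.n_sampling > N:
        raise ValueError("n_sampling exceeds the number of compartments")
    pop = SCMPopulation.empty(scm_params, chem, rng)
    for _ in range(params.dt_trans):
        surface_sim.run_generation()
        empty_slots = [i for i, v in enumerate(pop.vesicles) if v.size == 0]
        take = min(params.n_sampling, len(empty_slots))
        chosen = rng.choice(len(empty_slots), size=take, replace=False)
        for idx in chosen:
            pop.vesicles[empty_slots[int(idx)]] = sample_vesicle(
                surface_sim.lattice, params, chem, rng, scm_params.S - 1
            )
        pop.run_timestep()
    return pop
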