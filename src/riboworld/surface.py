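"""The surface-bound replicator lattice (MCRS).

A Z x Z toroidal grid of cells, each empty or holding one replicator.
Per generation, Z*Z randomly chosen cells are updated asynchronously
(with replacement): an occupied cell degrades its replicator with
probability P_deg; for an empty cell, the occupants of its replication
neighbourhood compete to place a mutagenic complementary copy, each
weighted by the claim C = R * M where M is the geometric-mean metabolic
function over the contestant's *own* metabolic neighbourhood.  The empty
site holds a fixed claim C_e to stay empty.  After every cell update, D
random Toffoli-Margolus 2x2 block rotations model limited surface
diffusion (D * Z^2 rotations per generation in total).

Neighbourhoods are quasi-circular patches: the N lattice offsets
nearest to the origin by Euclidean distance, with a deterministic
angle-based tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import Chemistry, Replicator
from .folding import MIN_FOLDABLE_LENGTH
from .pool import ReplicatorPool

__all__ = [
    "MCRSParams",
    "NeighbourhoodMask",
    "neighbourhood_offsets",
    "Lattice",
    "SurfaceSimulation",
    "init_lattice",
]

EMPTY = -1


@dataclass(frozen=True)
class MCRSParams:
    """Spatial parameters of the surface model."""

    Z: int = 300          # lattice side length (cells)
    N_met: int = 57       # metabolic neighbourhood size (cells, incl. focal)
    N_rep: int = 49       # replication neighbourhood size (cells)
    D: int = 4            # diffusion block-rotations per cell update
    C_e: float = 0.1      # claim of an empty site to remain empty

    def __post_init__(self) -> None:
        if self.Z < 2:
            raise ValueError("Z must be >= 2")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        for name in ("N_met", "N_rep"):
            n = getattr(self, name)
            if not 1 <= n <= self.Z * self.Z:
                raise ValueError(f"{name} must be in [1, Z^2]")


@dataclass(frozen=True)
class NeighbourhoodMask:
    """N (dy, dx) offsets defining a quasi-circular neighbourhood."""

    size: int
    offsets: tuple[tuple[int, int], ...]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        dy = np.array([o[0] for o in self.offsets], dtype=np.int64)
        dx = np.array([o[1] for o in self.offsets], dtype=np.int64)
        return dy, dx


def neighbourhood_offsets(N: int, Z: int | None = None) -> NeighbourhoodMask:
    """The N offsets closest to the origin (Euclidean), ties by angle.

    Deterministic: candidates are ranked by (distance^2, angle from the
    +x axis in [0, 2pi), dy, dx), producing quasi-circular patches that
    reduce to the von Neumann neighbourhood at N = 5 and the 3x3 Moore
    block at N = 9.  The origin (0, 0) is always the first offset.
    """
    if N < 1:
        raise ValueError("neighbourhood size must be >= 1")
    if Z is not None and N > Z * Z:
        raise ValueError(f"neighbourhood size {N} exceeds lattice capacity {Z * Z}")
    r = 1
    while (2 * r + 1) ** 2 < N:
        r += 1
    r += 1  # margin so the candidate square surely contains the N nearest
    cands = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            ang = math.atan2(dy, dx) % (2 * math.pi)
            cands.append((d2, ang, dy, dx))
    cands.sort()
    offsets = tuple((dy, dx) for _, _, dy, dx in cands[:N])
    return NeighbourhoodMask(N, offsets)


class Lattice:
    """Toroidal grid of replicator ids (EMPTY = -1) over a shared registry."""

    def __init__(self, Z: int, chem: Chemistry) -> None:
        self.Z = Z
        self.chem = chem
        self.grid = np.full((Z, Z), EMPTY, dtype=np.int64)
        self.generation = 0

    @property
    def occupancy(self) -> int:
        return int((self.grid != EMPTY).sum())

    @property
    def occupancy_fraction(self) -> float:
        return self.occupancy / (self.Z * self.Z)

    def replicators(self) -> list[Replicator]:
        """The current occupants (one entry per occupied cell)."""
        ids = self.grid[self.grid != EMPTY]
        return [self.chem.replicator_by_id(int(i)) for i in ids]

    def place(self, y: int, x: int, sequence: str) -> None:
        self.grid[y, x] = self.chem.replicator_id(sequence)

    def sequence_multiset_checksum(self) -> int:
        """Order-independent hash of all occupants (diffusion invariant)."""
        ids = np.sort(self.grid[self.grid != EMPTY])
        return hash(ids.tobytes())


def init_lattice(
    pool: ReplicatorPool,
    fill_fraction: float,
    Z: int,
    chem: Chemistry,
    rng: np.random.Generator,
) -> Lattice:
    """Fill ``floor(fill_fraction * Z^2)`` distinct cells from the pool.

    Sites are chosen uniformly without replacement; occupants are
    independent uniform draws (with replacement) from the pool.
    """
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill fraction must be in [0, 1]")
    if len(pool) == 0:
        raise ValueError("pool is empty")
    lat = Lattice(Z, chem)
    n_fill = int(fill_fraction * Z * Z)
    sites = rng.choice(Z * Z, size=n_fill, replace=False)
    seqs = pool.sequences()
    picks = rng.integers(0, len(seqs), size=n_fill)
    flat = lat.grid.ravel()
    for s, p in zip(sites, picks):
        flat[s] = chem.replicator_id(seqs[p])
    return lat


class SurfaceSimulation:
    """Generation loop of the MCRS on one lattice.

    All randomness flows through the supplied numpy Generator; with a
    fixed seed, backend and chemistry the run is fully deterministic.
    """

    def __init__(
        self,
        lattice: Lattice,
        params: MCRSParams,
        rng: np.random.Generator,
    ) -> None:
        if params.Z != lattice.Z:
            raise ValueError("params.Z does not match the lattice")
        self.lattice = lattice
        self.params = params
        self.chem = lattice.chem
        self.rng = rng
        Z = params.Z
        self._met_dy, self._met_dx = neighbourhood_offsets(params.N_met, Z).arrays()
        rep_dy, rep_dx = neighbourhood_offsets(params.N_rep, Z).arrays()
        # flat-index lookup of every site's replication neighbourhood
        def flat_table(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
            shape = (Z, Z, dy.shape[0])
            yy = np.broadcast_to(
                (np.arange(Z)[:, None, None] + dy[None, None, :]) % Z, shape
            )
            xx = np.broadcast_to(
                (np.arange(Z)[None, :, None] + dx[None, None, :]) % Z, shape
            )
            return np.ascontiguousarray((yy * Z + xx).reshape(Z * Z, dy.shape[0]))

        # flat-index lookups of every site's neighbourhoods
        self._rep_nbr_flat = flat_table(rep_dy, rep_dx)
        self._met_nbr_flat = flat_table(self._met_dy, self._met_dx)
        # bookkeeping for audits
        self.n_degradations = 0
        self.n_replications = 0
        self.n_failed_copies = 0

    # -- single events ---------------------------------------------------

    def contestant_claims(
        self, site_flat: int, grid_flat: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Claims of the occupied cells in an empty site's N_rep.

        Returns (contestant ids, claims); each contestant's metabolic
        function is the geometric mean of activity sums over its own
        metabolic neighbourhood (focal replicator included).
        """
        nbr_flat = self._rep_nbr_flat[site_flat]
        nbr_ids = grid_flat[nbr_flat]
        occ = nbr_ids != EMPTY
        if not occ.any():
            return nbr_ids[:0], np.empty(0)
        cids = nbr_ids[occ]
        met_ids = grid_flat[self._met_nbr_flat[nbr_flat[occ]]]
        sums = self.chem.act_padded[met_ids + 1].sum(axis=1)  # (k, A)
        A = self.chem.rules.A
        # prod ** (1/A) is the geometric mean; rows with a zero sum give M = 0
        M = np.prod(sums, axis=1) ** (1.0 / A)
        claims = self.chem.R_padded[cids + 1] * M
        return cids, claims

    def update_cell(self, y: int, x: int, u: float | None = None) -> None:
        """One asynchronous cell update (degradation or replication)."""
        grid_flat = self.lattice.grid.ravel()
        site = y * self.params.Z + x
        pid = grid_flat[site]
        if u is None:
            u = self.rng.random()
        if pid != EMPTY:
            if u < self.chem.pdeg_padded[pid + 1]:
                grid_flat[site] = EMPTY
                self.n_degradations += 1
            return
        cids, claims = self.contestant_claims(site, grid_flat)
        if cids.size == 0:
            return
        total = claims.sum() + self.params.C_e
        target = u * total
        cum = np.cumsum(claims)
        idx = int(np.searchsorted(cum, target, side="right"))
        if idx >= cids.size:
            return  # the empty site keeps its claim
        template = self.chem.replicator_by_id(int(cids[idx])).sequence
        copy = self.chem.mutate_copy(template, self.rng)
        if len(copy) < MIN_FOLDABLE_LENGTH:
            self.n_failed_copies += 1
            return
        grid_flat[site] = self.chem.replicator_id(copy)
        self.n_replications += 1

    def diffusion_step(
        self, y: int | None = None, x: int | None = None, clockwise: bool | None = None
    ) -> None:
        """Rotate one random 2x2 Toffoli-Margolus block by 90 degrees."""
        Z = self.params.Z
        if y is None:
            y = int(self.rng.integers(Z))
            x = int(self.rng.integers(Z))
            clockwise = bool(self.rng.random() < 0.5)
        g = self.lattice.grid
        y2 = (y + 1) % Z
        x2 = (x + 1) % Z
        a, b = g[y, x], g[y, x2]
        c, d = g[y2, x], g[y2, x2]
        if clockwise:  # (a b / c d) -> (c a / d b)
            g[y, x], g[y, x2], g[y2, x], g[y2, x2] = c, a, d, b
        else:
            g[y, x], g[y, x2], g[y2, x], g[y2, x2] = b, d, a, c

    # -- generation loop -------------------------------------------------

    def run_generation(self) -> None:
        """Z^2 cell updates at random sites, D rotations after each.

        Semantically identical to calling :meth:`update_cell` and
        :meth:`diffusion_step` in the interleaved order; randomness is
        pre-drawn per generation and hot paths are inlined.
        """
        Z = self.params.Z
        D = self.params.D
        C_e = self.params.C_e
        A = self.chem.rules.A
        invA = 1.0 / A
        n = Z * Z
        rng = self.rng
        sites = rng.integers(0, n, size=n).tolist()
        u = rng.random(n).tolist()
        if D > 0:
            ay = rng.integers(0, Z, size=n * D).tolist()
            ax = rng.integers(0, Z, size=n * D).tolist()
            cw = (rng.random(n * D) < 0.5).tolist()
        grid_flat = self.lattice.grid.ravel()
        rep_nbr = self._rep_nbr_flat
        met_nbr = self._met_nbr_flat
        chem = self.chem
        pdeg = chem.pdeg_padded
        R_arr = chem.R_padded
        act = chem.act_padded
        min_len = MIN_FOLDABLE_LENGTH
        for j in range(n):
            site = sites[j]
            pid = grid_flat[site]
            uj = u[j]
            if pid != EMPTY:
                if uj < pdeg[pid + 1]:
                    grid_flat[site] = EMPTY
                    self.n_degradations += 1
            else:
                nbr_flat = rep_nbr[site]
                nbr_ids = grid_flat[nbr_flat]
                occ = nbr_ids != EMPTY
                if occ.any():
                    cids = nbr_ids[occ]
                    met_ids = grid_flat[met_nbr[nbr_flat[occ]]]
                    sums = act[met_ids + 1].sum(axis=1)
                    M = np.prod(sums, axis=1) ** invA
                    claims = R_arr[cids + 1] * M
                    total = float(claims.sum())
                    target = uj * (total + C_e)
                    if target < total:
                        idx = int(
                            np.searchsorted(np.cumsum(claims), target, side="right")
                        )
                        if idx < cids.shape[0]:
                            template = chem.replicator_by_id(int(cids[idx])).sequence
                            copy = chem.mutate_copy(template, rng)
                            if len(copy) >= min_len:
                                grid_flat[site] = chem.replicator_id(copy)
                                self.n_replications += 1
                                # registry arrays may have been reallocated
                                pdeg = chem.pdeg_padded
                                R_arr = chem.R_padded
                                act = chem.act_padded
                            else:
                                self.n_failed_copies += 1
            if D > 0:
                base = j * D
                for t in range(base, base + D):
                    y = ay[t]
                    x = ax[t]
                    y2 = y + 1
                    if y2 == Z:
                        y2 = 0
                    x2 = x + 1
                    if x2 == Z:
                        x2 = 0
                    p00 = y * Z + x
                    p01 = y * Z + x2
                    p10 = y2 * Z + x
                    p11 = y2 * Z + x2
                    a = grid_flat[p00]
                    b = grid_flat[p01]
                    c = grid_flat[p10]
                    d = grid_flat[p11]
                    if cw[t]:  # (a b / c d) -> (c a / d b)
                        grid_flat[p00] = c
                        grid_flat[p01] = a
                        grid_flat[p10] = d
                        grid_flat[p11] = b
                    else:
                        grid_flat[p00] = b
                        grid_flat[p01] = d
                        grid_flat[p10] = a
                        grid_flat[p11] = c
        self.lattice.generation += 1

    def run(self, generations: int, recorder=None, record_every: int = 1) -> None:
        """Advance the simulation, optionally recording at a cadence.

        ``recorder`` is called as ``recorder(self)`` after every
        ``record_every``-th generation.
        """
        for _ in range(generations):
            self.run_generation()
            if recorder is not None and self.lattice.generation % record_every == 0:
                recorder(self)
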