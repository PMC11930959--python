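"""Lattice neighbourhoods, updates, diffusion and the generation loop."""

import numpy as np
import pytest

from riboworld.chemistry import Chemistry, RuleTable
from riboworld.folding import Folder, NussinovBackend
from riboworld.metabolism import metabolic_function
from riboworld.pool import ReplicatorPool, enrich_pool, random_pool
from riboworld.surface import (
    EMPTY,
    Lattice,
    MCRSParams,
    SurfaceSimulation,
    init_lattice,
    neighbourhood_offsets,
)


def _active_sequence():
    # folds into a hairpin with a 7-loop whose centre is AGC (rule 1)
    return "GGGGGUUAGCUUCCCCC"


@pytest.fixture()
def small_sim(chem3):
    rng = np.random.default_rng(0)
    lat = Lattice(12, chem3)
    params = MCRSParams(Z=12, N_met=5, N_rep=5, D=0)
    return SurfaceSimulation(lat, params, rng)


class TestNeighbourhoodOffsets:
    def test_five_is_von_neumann(self):
        mask = neighbourhood_offsets(5)
        assert set(mask.offsets) == {(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}
        assert mask.offsets[0] == (0, 0)

    def test_nine_is_moore_block(self):
        mask = neighbourhood_offsets(9)
        assert set(mask.offsets) == {
            (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        }

    def test_thirteen_adds_next_nearest_axials(self):
        mask = neighbourhood_offsets(13)
        moore = {(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)}
        assert set(mask.offsets) == moore | {(2, 0), (-2, 0), (0, 2), (0, -2)}

    def test_deterministic_and_sized(self):
        for N in (5, 9, 21, 49, 57):
            a = neighbourhood_offsets(N)
            b = neighbourhood_offsets(N)
            assert a == b
            assert len(a.offsets) == N
            assert len(set(a.offsets)) == N

    def test_oversized_neighbourhood_rejected(self):
        with pytest.raises(ValueError):
            neighbourhood_offsets(26, Z=5)


class TestInitLattice:
    def _pool(self, chem):
        rng = np.random.default_rng(3)
        return random_pool(50, 45.0, chem, rng)

    @pytest.mark.parametrize("fill,expected", [(0.8, 80), (0.0, 0), (1.0, 100)])
    def test_fill_counts(self, chem3_nussinov, fill, expected):
        rng = np.random.default_rng(1)
        lat = init_lattice(self._pool(chem3_nussinov), fill, 10, chem3_nussinov, rng)
        assert lat.occupancy == expected

    def test_invalid_fill_rejected(self, chem3_nussinov, rng):
        with pytest.raises(ValueError):
            init_lattice(self._pool(chem3_nussinov), 1.5, 10, chem3_nussinov, rng)


class TestUpdateCell:
    def test_empty_site_with_no_neighbours_stays_empty(self, small_sim):
        small_sim.update_cell(5, 5)
        assert small_sim.lattice.occupancy == 0

    def test_incomplete_metabolic_neighbourhood_gives_zero_claim(self, chem3):
        """A lone active replicator lacks the other activities: M = 0."""
        rng = np.random.default_rng(0)
        lat = Lattice(12, chem3)
        lat.place(5, 5, _active_sequence())
        sim = SurfaceSimulation(lat, MCRSParams(Z=12, N_met=5, N_rep=5, D=0), rng)
        cids, claims = sim.contestant_claims(5 * 12 + 6, lat.grid.ravel())
        assert cids.size == 1
        assert claims[0] == 0.0
        # the site therefore never fills
        for _ in range(200):
            sim.update_cell(5, 6)
        assert lat.grid[5, 6] == EMPTY

    def test_degradation_frequency_matches_pdeg(self, chem3):
        rng = np.random.default_rng(0)
        lat = Lattice(4, chem3)
        params = MCRSParams(Z=4, N_met=5, N_rep=5, D=0)
        sim = SurfaceSimulation(lat, params, rng)
        seq = "A" * 20  # open chain: P_deg = 0.9
        pdeg = chem3.replicator(seq).traits.P_deg
        assert pdeg == pytest.approx(0.9)
        n = 100_000
        removed = 0
        for _ in range(n):
            lat.place(0, 0, seq)
            sim.update_cell(0, 0)
            if lat.grid[0, 0] == EMPTY:
                removed += 1
            lat.grid[0, 0] = EMPTY
        se = np.sqrt(pdeg * (1 - pdeg) / n)
        assert abs(removed / n - pdeg) < 3 * se

    def test_claims_match_metabolism_core(self, chem3):
        """Vectorised lattice claims equal R * metabolic_function exactly."""
        rng = np.random.default_rng(12)
        pool = random_pool(60, 45.0, chem3, rng)
        lat = init_lattice(pool, 0.7, 10, chem3, rng)
        params = MCRSParams(Z=10, N_met=9, N_rep=9, D=0)
        sim = SurfaceSimulation(lat, params, rng)
        met = neighbourhood_offsets(9)
        grid_flat = lat.grid.ravel()
        for site in range(100):
            if grid_flat[site] != EMPTY:
                continue
            cids, claims = sim.contestant_claims(site, grid_flat)
            y, x = divmod(site, 10)
            # brute-force oracle over the replication neighbourhood
            expected = []
            for dy, dx in neighbourhood_offsets(9).offsets:
                cy, cx = (y + dy) % 10, (x + dx) % 10
                pid = lat.grid[cy, cx]
                if pid == EMPTY:
                    continue
                sums = np.zeros(3)
                for mdy, mdx in met.offsets:
                    qid = lat.grid[(cy + mdy) % 10, (cx + mdx) % 10]
                    if qid != EMPTY:
                        sums += chem3.replicator_by_id(int(qid)).traits.activities
                M = metabolic_function(sums, 3)
                expected.append(chem3.replicator_by_id(int(pid)).traits.R * M)
            assert claims == pytest.approx(np.array(expected), rel=1e-9)


class TestDiffusion:
    def test_clockwise_rotation_schematic(self, chem3):
        rng = np.random.default_rng(0)
        lat = Lattice(4, chem3)
        sim = SurfaceSimulation(lat, MCRSParams(Z=4, N_met=5, N_rep=5, D=0), rng)
        a, b, c, d = 10, 11, 12, 13
        lat.grid[0, 0], lat.grid[0, 1], lat.grid[1, 0], lat.grid[1, 1] = a, b, c, d
        sim.diffusion_step(0, 0, clockwise=True)
        assert (
            lat.grid[0, 0], lat.grid[0, 1], lat.grid[1, 0], lat.grid[1, 1]
        ) == (c, a, d, b)

    def test_four_rotations_restore_block(self, chem3):
        rng = np.random.default_rng(0)
        lat = Lattice(4, chem3)
        sim = SurfaceSimulation(lat, MCRSParams(Z=4, N_met=5, N_rep=5, D=0), rng)
        lat.grid[:2, :2] = [[1, 2], [3, 4]]
        before = lat.grid.copy()
        for _ in range(4):
            sim.diffusion_step(0, 0, clockwise=True)
        assert (lat.grid == before).all()

    def test_diffusion_conserves_replicator_multiset(self, chem3_nussinov):
        rng = np.random.default_rng(8)
        pool = random_pool(100, 45.0, chem3_nussinov, rng)
        lat = init_lattice(pool, 0.5, 16, chem3_nussinov, rng)
        sim = SurfaceSimulation(
            lat, MCRSParams(Z=16, N_met=5, N_rep=5, D=4), rng
        )
        checksum = lat.sequence_multiset_checksum()
        for _ in range(2000):
            sim.diffusion_step()
        assert lat.sequence_multiset_checksum() == checksum
        assert lat.occupancy == int(0.5 * 16 * 16)


class TestRunGeneration:
    def test_zero_diffusion_executes_no_rotations(self, chem3_nussinov):
        """With D = 0 the generation loop must not touch the RNG for
        diffusion: total draws per generation are exactly 2*Z^2 plus
        replication draws."""
        rng = np.random.default_rng(0)
        lat = Lattice(8, chem3_nussinov)
        sim = SurfaceSimulation(lat, MCRSParams(Z=8, N_met=5, N_rep=5, D=0), rng)
        sim.run_generation()  # empty lattice: no replication randomness
        shadow = np.random.default_rng(0)
        shadow.integers(0, 64, size=64)
        shadow.random(64)
        assert rng.bit_generator.state == shadow.bit_generator.state

    def test_population_bookkeeping_identity(self, chem3):
        rng = np.random.default_rng(21)
        pool = enrich_pool(random_pool(300, 45.0, chem3, rng), rng)
        lat = init_lattice(pool, 0.8, 14, chem3, rng)
        sim = SurfaceSimulation(lat, MCRSParams(Z=14, N_met=9, N_rep=9, D=4), rng)
        start = lat.occupancy
        sim.run(5)
        assert lat.occupancy == start + sim.n_replications - sim.n_degradations

    def test_lattice_without_one_activity_decays_to_extinction(self, chem3):
        """Occupants covering only 2 of 3 activities can never replicate."""
        rng = np.random.default_rng(4)
        pool = random_pool(500, 45.0, chem3, rng)
        missing = [
            r
            for r in pool.entries
            if r.traits.activities[1] == 0  # nobody catalyses reaction 2
        ]
        lat = init_lattice(ReplicatorPool(missing), 0.8, 10, chem3, rng)
        sim = SurfaceSimulation(lat, MCRSParams(Z=10, N_met=9, N_rep=9, D=4), rng)
        occ = [lat.occupancy]
        for _ in range(60):
            sim.run_generation()
            occ.append(lat.occupancy)
        assert sim.n_replications == 0
        assert occ[-1] == 0  # P_deg >= 0.1 drives everything extinct

    def test_fixed_seed_reproducible(self, rules3):
        def one_run():
            rng = np.random.default_rng(99)
            chem = Chemistry(rules3, folder=Folder(NussinovBackend()))
            pool = enrich_pool(random_pool(200, 30.0, chem, rng), rng)
            lat = init_lattice(pool, 0.6, 10, chem, rng)
            sim = SurfaceSimulation(lat, MCRSParams(Z=10, N_met=9, N_rep=5, D=2), rng)
            sim.run(8)
            return lat.grid.copy(), [r.sequence for r in lat.replicators()]

        g1, s1 = one_run()
        g2, s2 = one_run()
        assert (g1 == g2).all()
        assert s1 == s2
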