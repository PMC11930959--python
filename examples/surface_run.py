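"""A small surface-bound (MCRS) simulation from an enriched random pool.

Generates a random replicator pool, enriches it to 80% catalytic
activity, fills 80% of a toroidal lattice and runs the asynchronous
degradation/replication/diffusion dynamics for a few hundred
generations, printing the occupancy trajectory.
"""

import numpy as np

import riboworld as rw

rng = np.random.default_rng(2)
chem = rw.Chemistry(rw.RuleTable.default(A=3))

pool = rw.enrich_pool(rw.random_pool(1000, 45.0, chem, rng), rng)
print(f"pool: {len(pool)} sequences, {100 * pool.active_fraction:.1f}% active")

Z = 30
lattice = rw.init_lattice(pool, 0.8, Z, chem, rng)
sim = rw.SurfaceSimulation(
    lattice, rw.MCRSParams(Z=Z, N_met=49, N_rep=49, D=4), rng
)

recorder = rw.TraitRecorder(A=3)
sim.run(100, recorder=recorder, record_every=20)
for row in recorder.rows:
    print(
        f"gen {row['time']:4d}: occupancy {100 * row['occupancy']:5.1f}%  "
        f"mean R {row['mean_R']:5.2f}  mean L {row['mean_L']:5.1f}  "
        f"mean dG {row['mean_dG']:6.1f}"
    )

# Occupancy first dips while metabolically incomplete regions are
# cleared, then recovers toward the ~80% quasi-stationary level as
# complete neighbourhoods expand; mean dG_min drifts downward as
# selection favours stable (low-degradation) folds.
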