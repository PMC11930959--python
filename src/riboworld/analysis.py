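"""Analysis surfaces: trait time series, promiscuity matrices, viability sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from .chemistry import Chemistry, Replicator, complement
from .pool import enrich_pool, random_pool
from .surface import Lattice, MCRSParams, SurfaceSimulation, init_lattice

__all__ = [
    "trait_row",
    "TraitRecorder",
    "promiscuity_matrix",
    "viability_sweep",
    "occupancy_experiment",
]


def occupancy_experiment(
    *,
    A: int,
    Z: int,
    N_met: int,
    N_rep: int,
    D: int,
    generations: int,
    tail: int,
    seeds: Iterable[int],
    pool_size: int = 2000,
    lam: float = 45.0,
    fill_fraction: float = 0.8,
    backend: str = "auto",
) -> dict:
    """Quasi-stationary grid occupancy of replicate surface runs.

    Runs one enriched-pool MCRS simulation per seed and averages the
    occupancy fraction over the last ``tail`` generations, then across
    replicates.  Because a quasi-stationary occupancy only exists for a
    living population — and stochastic extinction of an activity class
    is a real finite-size risk that the full-scale system does not
    share — the survivor-conditioned mean is reported alongside the
    unconditional one, with per-seed values and survival flags.
    """
    from .chemistry import ChemistryParams, RuleTable

    per_seed = []
    survived = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        chem = Chemistry(RuleTable.default(A), ChemistryParams(), backend)
        pool = enrich_pool(random_pool(pool_size, lam, chem, rng), rng)
        lattice = init_lattice(pool, fill_fraction, Z, chem, rng)
        sim = SurfaceSimulation(
            lattice, MCRSParams(Z=Z, N_met=N_met, N_rep=N_rep, D=D), rng
        )
        occ = np.empty(generations)
        for g in range(generations):
            sim.run_generation()
            occ[g] = lattice.occupancy_fraction
        per_seed.append(float(occ[-tail:].mean()))
        survived.append(lattice.occupancy > 0)
    alive = [v for v, s in zip(per_seed, survived) if s]
    return {
        "per_seed_percent": [100.0 * v for v in per_seed],
        "survived": survived,
        "n_survived": int(sum(survived)),
        "mean_percent": 100.0 * float(np.mean(per_seed)),
        "surviving_mean_percent": 100.0 * float(np.mean(alive)) if alive else 0.0,
        "n_cells": Z * Z,
        "generations": generations,
    }


def _activity_class(rep: Replicator) -> str:
    """Activity-set label of a strand, e.g. "E1", "E1,3" or "parasite"."""
    ids = rep.traits.active_rule_ids
    if not ids:
        return "parasite"
    return "E" + ",".join(str(i) for i in ids)


def trait_row(replicators: list[Replicator], A: int) -> dict:
    """One summary row over a set of replicators (shared MCRS/SCM schema).

    Reports population size, mean replicability, length, minimal free
    energy and activity, per-activity-class relative frequencies and
    counts of strands carrying n = 0..A activities.
    """
    row: dict = {"n_replicators": len(replicators)}
    if not replicators:
        row.update(mean_R=0.0, mean_L=0.0, mean_dG=0.0, mean_activity=0.0)
        for n in range(A + 1):
            row[f"n_with_{n}_activities"] = 0
        return row
    R = np.array([r.traits.R for r in replicators])
    L = np.array([r.traits.L for r in replicators])
    dG = np.array([r.traits.dG_min for r in replicators])
    act_tot = np.array([r.traits.activities.sum() for r in replicators])
    row.update(
        mean_R=float(R.mean()),
        mean_L=float(L.mean()),
        mean_dG=float(dG.mean()),
        mean_activity=float(act_tot.mean()),
    )
    n_acts = np.array([r.traits.n_activities for r in replicators])
    for n in range(A + 1):
        row[f"n_with_{n}_activities"] = int((n_acts == n).sum())
    classes = pd.Series([_activity_class(r) for r in replicators])
    freqs = classes.value_counts(normalize=True)
    for cls, f in freqs.items():
        row[f"freq_{cls}"] = float(f)
    return row


@dataclass
class TraitRecorder:
    """Collects per-sample trait rows from a running simulation.

    Works as the ``recorder`` callback of both
    :meth:`riboworld.surface.SurfaceSimulation.run` and
    :meth:`riboworld.vesicles.SCMPopulation.run`.
    """

    A: int
    rows: list[dict] = field(default_factory=list)

    def __call__(self, sim) -> None:
        from .vesicles import SCMPopulation  # avoid cycle at import time

        if isinstance(sim, SCMPopulation):
            row = {"time": sim.timesteps, "model": "scm"}
            row.update(trait_row(sim.replicators(), self.A))
            row["n_nonempty_vesicles"] = sim.n_nonempty
            row["n_complete_vesicles"] = sim.n_complete
        else:
            row = {"time": sim.lattice.generation, "model": "mcrs"}
            row.update(trait_row(sim.lattice.replicators(), self.A))
            row["occupancy"] = sim.lattice.occupancy_fraction
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).fillna(0.0)


def promiscuity_matrix(replicators: list[Replicator], chem: Chemistry) -> pd.DataFrame:
    """Cross-tabulate strand activity sets against error-free complements.

    Rows are the activity-set label of each strand, columns that of its
    error-free complement; cells hold relative frequencies summing to 1.
    Rows/columns with zero mass are omitted.  Real parasites (neither
    strand active) fall in the ("parasite", "parasite") cell.
    """
    if not replicators:
        return pd.DataFrame()
    rows = []
    for rep in replicators:
        comp = chem.replicator(complement(rep.sequence))
        rows.append((_activity_class(rep), _activity_class(comp)))
    df = pd.DataFrame(rows, columns=["strand", "complement"])
    table = pd.crosstab(df["strand"], df["complement"], normalize=True)
    return table


def _survived(sim: SurfaceSimulation) -> bool:
    return sim.lattice.occupancy > 0


def viability_sweep(
    A_values: Iterable[int],
    N_met_values: Iterable[int],
    N_rep_values: Iterable[int],
    D_values: Iterable[int],
    *,
    Z: int,
    generations: int,
    replicates: int,
    seed: int,
    pool_size: int = 2000,
    lam: float = 45.0,
    fill_fraction: float = 0.8,
    backend: str = "auto",
    chemistry_params=None,
) -> pd.DataFrame:
    """Survival fraction over a (A, N_met, N_rep, D) grid of small runs.

    Each cell runs ``replicates`` simulations from independently seeded
    enriched pools and reports the fraction still populated at the
    horizon plus the mean end-state parasite frequency (strands with no
    activity) among survivors.  Seeds are recorded per replicate.
    """
    from .chemistry import ChemistryParams, RuleTable

    records = []
    for A, N_met, N_rep, D in product(A_values, N_met_values, N_rep_values, D_values):
        rules = RuleTable.default(A)
        survived = []
        parasite_freqs = []
        seeds = []
        for rep_i in range(replicates):
            run_seed = (seed + 1009 * rep_i + hash((A, N_met, N_rep, D)) % 100003) % (
                2**31
            )
            seeds.append(run_seed)
            rng = np.random.default_rng(run_seed)
            chem = Chemistry(rules, chemistry_params or ChemistryParams(), backend)
            pool = enrich_pool(random_pool(pool_size, lam, chem, rng), rng)
            lat = init_lattice(pool, fill_fraction, Z, chem, rng)
            sim = SurfaceSimulation(lat, MCRSParams(Z=Z, N_met=N_met, N_rep=N_rep, D=D), rng)
            sim.run(generations)
            alive = _survived(sim)
            survived.append(alive)
            if alive:
                occupants = lat.replicators()
                parasite_freqs.append(
                    float(np.mean([not r.traits.is_active for r in occupants]))
                )
        records.append(
            {
                "A": A,
                "N_met": N_met,
                "N_rep": N_rep,
                "D": D,
                "survival": float(np.mean(survived)),
                "mean_parasite_freq": float(np.mean(parasite_freqs))
                if parasite_freqs
                else np.nan,
                "replicates": replicates,
                "seeds": ",".join(map(str, seeds)),
            }
        )
    return pd.DataFrame.from_records(records)
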