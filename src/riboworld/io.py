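"""Serialization: FASTA pools, TSV snapshots, JSON run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chemistry import Chemistry, Replicator
from .pool import ReplicatorPool
from .surface import EMPTY, Lattice
from .vesicles import SCMParams, SCMPopulation, Vesicle

__all__ = [
    "write_pool_fasta",
    "read_pool_fasta",
    "traits_frame",
    "write_lattice_snapshot",
    "read_lattice_snapshot",
    "write_scm_snapshot",
    "read_scm_snapshot",
    "write_manifest",
]


def traits_frame(replicators: list[Replicator]) -> pd.DataFrame:
    """Tabular trait sidecar for a set of replicators."""
    rows = []
    for i, r in enumerate(replicators):
        t = r.traits
        rows.append(
            {
                "index": i,
                "sequence": r.sequence,
                "L": t.L,
                "dG_min": t.dG_min,
                "P_deg": t.P_deg,
                "P_fold": t.P_fold,
                "R": t.R,
                "n_activities": t.n_activities,
                "active_rules": ",".join(map(str, t.active_rule_ids)),
                "structure": r.structure.dot_bracket,
            }
        )
    return pd.DataFrame(rows)


def write_pool_fasta(pool: ReplicatorPool, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=f"rep{i}", description="")
        for i, r in enumerate(pool.entries)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pool_fasta(path: str | Path, chem: Chemistry) -> ReplicatorPool:
    entries = [
        chem.replicator(str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return ReplicatorPool(entries)


def write_lattice_snapshot(lattice: Lattice, path: str | Path) -> None:
    rows = []
    Z = lattice.Z
    for y in range(Z):
        for x in range(Z):
            pid = lattice.grid[y, x]
            if pid != EMPTY:
                rows.append(
                    {"row": y, "col": x,
                     "sequence": lattice.chem.replicator_by_id(int(pid)).sequence}
                )
    pd.DataFrame(rows, columns=["row", "col", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_lattice_snapshot(path: str | Path, Z: int, chem: Chemistry) -> Lattice:
    lat = Lattice(Z, chem)
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        lat.place(int(row.row), int(row.col), str(row.sequence))
    return lat


def write_scm_snapshot(pop: SCMPopulation, path: str | Path) -> None:
    rows = []
    for vi, v in enumerate(pop.vesicles):
        for r in v.members:
            rows.append({"vesicle": vi, "sequence": r.sequence})
    pd.DataFrame(rows, columns=["vesicle", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_scm_snapshot(
    path: str | Path, params: SCMParams, chem: Chemistry, rng
) -> SCMPopulation:
    df = pd.read_csv(path, sep="\t")
    A = chem.rules.A
    vesicles = [Vesicle(A=A) for _ in range(params.N)]
    groups: dict[int, list] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(int(row.vesicle), []).append(chem.replicator(str(row.sequence)))
    for vi, members in groups.items():
        vesicles[vi] = Vesicle(members, A=A)
    return SCMPopulation(vesicles, params, chem, rng)


def write_manifest(path: str | Path, **fields) -> None:
    """JSON run manifest (config, seed, outputs) for reproducibility."""
    from . import __version__

    payload = {"riboworld_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
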