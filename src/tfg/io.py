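"""Readers and writers for library and screen artifacts.

FASTA carries sequences (template; one mutant record per clone), TSV carries
mutation and colony tables, JSON carries aggregate reports.  All TSV outputs
have a header row preceded by a comment line documenting that coordinates
are 0-based homology-axis positions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tfg.library import CloneGenotype, Mutation, classify_effect

COORD_COMMENT = "# pos: 0-based coordinate on the homology axis\n"

__all__ = [
    "write_template_fasta",
    "read_template_fasta",
    "write_clone_fasta",
    "read_clone_fasta",
    "mutation_table",
    "write_mutation_table",
    "read_mutation_table",
    "write_clone_metadata",
    "read_library_tsv",
    "write_json_report",
]


def write_template_fasta(template: str, path, name: str = "template") -> None:
    SeqIO.write([SeqRecord(Seq(template), id=name, description="")], str(path), "fasta")


def read_template_fasta(path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def apply_mutations(template: str, mutations: Sequence[Mutation]) -> str:
    seq = list(template)
    for m in mutations:
        if seq[m.pos] != m.ref:
            raise ValueError(f"reference mismatch at {m.pos}")
        seq[m.pos] = m.alt
    return "".join(seq)


def write_clone_fasta(clones: Sequence[CloneGenotype], template: str, path) -> None:
    """One record per clone; the description encodes the recombinant flag."""
    records = [
        SeqRecord(
            Seq(apply_mutations(template, c.mutations)),
            id=c.clone_id,
            description=f"recombinant={int(c.recombinant)} n_mutations={len(c.mutations)}",
        )
        for c in clones
    ]
    SeqIO.write(records, str(path), "fasta")


def read_clone_fasta(path, template: str) -> list[CloneGenotype]:
    """Reconstruct clone genotypes by diffing each record against the template."""
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) != len(template):
            raise ValueError(f"clone {rec.id} length differs from template")
        recombinant = "recombinant=1" in rec.description
        muts = tuple(
            Mutation(i, template[i], seq[i])
            for i in range(len(seq))
            if seq[i] != template[i]
        )
        clones.append(CloneGenotype(rec.id, recombinant, muts))
    return clones


def mutation_table(
    clones: Sequence[CloneGenotype], template: str, orf_interval: tuple[int, int]
) -> pd.DataFrame:
    """One row per mutation: clone_id, pos, ref, alt, effect."""
    cache: dict[tuple[int, str], str] = {}
    rows = []
    for c in clones:
        for m in c.mutations:
            key = (m.pos, m.alt)
            eff = cache.get(key)
            if eff is None:
                eff = classify_effect(template, orf_interval, m)
                cache[key] = eff
            rows.append(
                {"clone_id": c.clone_id, "pos": m.pos, "ref": m.ref, "alt": m.alt, "effect": eff}
            )
    return pd.DataFrame(rows, columns=["clone_id", "pos", "ref", "alt", "effect"])


def write_mutation_table(
    clones: Sequence[CloneGenotype],
    template: str,
    orf_interval: tuple[int, int],
    path,
) -> None:
    df = mutation_table(clones, template, orf_interval)
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_clone_metadata(clones: Sequence[CloneGenotype], path) -> None:
    """Sidecar table listing every clone (including mutation-free ones)."""
    df = pd.DataFrame(
        {
            "clone_id": [c.clone_id for c in clones],
            "recombinant": [int(c.recombinant) for c in clones],
            "n_mutations": [len(c.mutations) for c in clones],
        }
    )
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_library_tsv(mutations_path, clones_path) -> list[CloneGenotype]:
    """Rebuild a clone library from a mutation table plus clone metadata."""
    muts = read_mutation_table(mutations_path)
    meta = pd.read_csv(clones_path, sep="\t", comment="#")
    by_clone: dict[str, list[Mutation]] = {}
    for row in muts.itertuples(index=False):
        by_clone.setdefault(row.clone_id, []).append(
            Mutation(int(row.pos), row.ref, row.alt)
        )
    return [
        CloneGenotype(
            row.clone_id, bool(row.recombinant), tuple(by_clone.get(row.clone_id, ()))
        )
        for row in meta.itertuples(index=False)
    ]


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
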