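"""FASTA and modification-sidecar I/O.

Unmodified sequences travel as plain FASTA (via Biopython).  Modifications
ride in a sidecar TSV with columns ``record_id``, ``position`` (1-based
peptide position, or ``c-term``), and ``tag`` (``phospho``,
``pyroglutamate``, ``d-stereo``, ``iso-aspartate``, or ``amide`` for the
C-terminus).  Inline canonical strings (``DAEFRHDS[p]GYEVHHQ-NH2``) remain
the compact alternative handled by :func:`abepitope.parse_peptide`.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptide import C_TERM_AMIDE, C_TERM_FREE, MOD_NONE, ModifiedPeptide, PeptideError

__all__ = ["read_fasta", "write_fasta", "read_modified_fasta", "write_sidecar"]


def read_fasta(path: Union[str, Path]) -> dict[str, ModifiedPeptide]:
    """Unmodified peptides keyed by record id."""
    return {
        rec.id: ModifiedPeptide(str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(peptides: dict[str, ModifiedPeptide], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=name, description="") for name, p in peptides.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_modified_fasta(
    fasta_path: Union[str, Path], sidecar_path: Union[str, Path]
) -> dict[str, ModifiedPeptide]:
    """FASTA plus modification sidecar TSV -> modified peptides."""
    plain = read_fasta(fasta_path)
    mods: dict[str, list[str]] = {name: [MOD_NONE] * len(p) for name, p in plain.items()}
    amide: dict[str, bool] = {name: False for name in plain}
    with open(sidecar_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["record_id"]
            if name not in plain:
                raise PeptideError(f"sidecar references unknown record {name!r}")
            tag = row["tag"].strip()
            if row["position"].strip().lower() == "c-term":
                if tag != "amide":
                    raise PeptideError(f"unknown C-terminal tag {tag!r}")
                amide[name] = True
                continue
            pos = int(row["position"])
            if not (1 <= pos <= len(plain[name])):
                raise PeptideError(f"sidecar position {pos} outside {name!r}")
            mods[name][pos - 1] = tag
    return {
        name: ModifiedPeptide(
            p.residues,
            tuple(mods[name]),
            c_term=C_TERM_AMIDE if amide[name] else C_TERM_FREE,
        )
        for name, p in plain.items()
    }


def write_sidecar(peptides: dict[str, ModifiedPeptide], path: Union[str, Path]) -> None:
    """Write the modification sidecar TSV for a set of peptides."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "position", "tag"])
        for name, p in peptides.items():
            for i, tag in enumerate(p.mods, start=1):
                if tag != MOD_NONE:
                    writer.writerow([name, i, tag])
            if p.c_term == C_TERM_AMIDE:
                writer.writerow([name, "c-term", "amide"])
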