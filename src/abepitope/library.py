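"""Design of the three peptide-array library classes.

* overlapping tiling libraries (window/step k-mers over a long sequence),
* deep positional-substitution scans (every position x every other
  proteinogenic amino acid), and
* post-translational-modification (PTM) variant panels in which each
  modified peptide is paired with its unmodified control for head-to-head
  comparison.

Probe identifiers encode their provenance (wildtype name, scanned position,
substituted letter) so downstream analysis never has to re-parse sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .peptide import (
    AMINO_ACIDS,
    ModifiedPeptide,
    PeptideError,
    abeta_peptide,
    abeta_positions,
    parse_peptide,
    to_canonical,
)

__all__ = [
    "Probe",
    "ProbeLibrary",
    "tile_sequence",
    "positional_scan",
    "ptm_panel",
    "PTM_SPECS",
]

ROLE_TILE = "tile"
ROLE_WILDTYPE = "wildtype"
ROLE_SUBSTITUTION = "substitution"
ROLE_PTM = "ptm-variant"

_ROLES = {ROLE_TILE, ROLE_WILDTYPE, ROLE_SUBSTITUTION, ROLE_PTM}


@dataclass(frozen=True)
class Probe:
    """One arrayed peptide with its role and provenance."""

    probe_id: str
    peptide: ModifiedPeptide
    role: str
    wt_position: Optional[int] = None  # 1-based peptide position of the substitution
    substitution: Optional[str] = None
    partner_id: Optional[str] = None  # unmodified control of a ptm-variant

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown probe role {self.role!r}")


class ProbeLibrary:
    """Ordered collection of probes with unique identifiers."""

    def __init__(self, probes: Iterable[Probe], name: str = "library"):
        self.probes: list[Probe] = list(probes)
        self.name = name
        seen: set[str] = set()
        for p in self.probes:
            if p.probe_id in seen:
                raise ValueError(f"duplicate probe id {p.probe_id!r}")
            seen.add(p.probe_id)
        wt = self.wildtype
        for p in self.probes:
            if p.role == ROLE_SUBSTITUTION:
                if wt is None:
                    raise ValueError("substitution probes require a wildtype reference probe")
                diff = [
                    i
                    for i, (a, b) in enumerate(zip(p.peptide.residues, wt.peptide.residues))
                    if a != b
                ]
                if len(p.peptide) != len(wt.peptide) or len(diff) != 1:
                    raise ValueError(
                        f"substitution probe {p.probe_id!r} must differ from wildtype at "
                        f"exactly one position"
                    )

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __getitem__(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    @property
    def wildtype(self) -> Optional[Probe]:
        for p in self.probes:
            if p.role == ROLE_WILDTYPE:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.probes:
            rows.append(
                {
                    "probe_id": p.probe_id,
                    "sequence": to_canonical(p.peptide),
                    "role": p.role,
                    "wt_position": p.wt_position,
                    "substitution": p.substitution,
                    "abeta_start": p.peptide.abeta_start,
                    "partner_id": p.partner_id,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], name: Optional[str] = None) -> "ProbeLibrary":
        df = pd.read_csv(path)
        probes = []
        for row in df.itertuples(index=False):
            start = None if pd.isna(row.abeta_start) else int(row.abeta_start)
            pep = parse_peptide(row.sequence, "canonical", abeta_start=start)
            probes.append(
                Probe(
                    probe_id=row.probe_id,
                    peptide=pep,
                    role=row.role,
                    wt_position=None if pd.isna(row.wt_position) else int(row.wt_position),
                    substitution=None if pd.isna(row.substitution) else row.substitution,
                    partner_id=None
                    if ("partner_id" not in df.columns or pd.isna(row.partner_id))
                    else row.partner_id,
                )
            )
        return cls(probes, name=name or Path(path).stem)


def tile_sequence(
    seq: str,
    window: int = 15,
    step: int = 1,
    *,
    name: str = "tile",
    abeta_start: Optional[int] = None,
) -> ProbeLibrary:
    """Overlapping window tiles of ``seq``, left to right.

    Emits ``floor((L - window)/step) + 1`` probes; with ``step=1`` adjacent
    tiles share ``window - 1`` residues.  If ``abeta_start`` is given the
    tiles carry Abeta coordinates (numbering that skips position 0).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    coords = abeta_positions(abeta_start, len(seq)) if abeta_start is not None else None
    probes = []
    for i in range(0, len(seq) - window + 1, step):
        start = coords[i] if coords is not None else None
        label = f"ab{start}" if start is not None else f"{i + 1}"
        probes.append(
            Probe(
                probe_id=f"{name}:{label}",
                peptide=ModifiedPeptide(seq[i : i + window], abeta_start=start),
                role=ROLE_TILE,
            )
        )
    return ProbeLibrary(probes, name=name)


def positional_scan(
    wt: Union[str, ModifiedPeptide],
    alphabet: str = AMINO_ACIDS,
    *,
    name: str = "scan",
    abeta_start: Optional[int] = None,
) -> ProbeLibrary:
    """Deep positional-substitution scan of an unmodified wildtype peptide.

    For every position, one probe per alphabet letter different from the
    wildtype letter, plus a single wildtype reference probe: a total of
    ``L * (|alphabet| - 1) + 1`` probes for the default 20-letter alphabet.
    """
    if isinstance(wt, str):
        wt = ModifiedPeptide(wt, abeta_start=abeta_start)
    if wt.is_modified:
        raise PeptideError("positional scans are defined on unmodified wildtype peptides")
    if not alphabet:
        raise ValueError("empty substitution alphabet")
    probes = [Probe(probe_id=f"{name}:wt", peptide=wt, role=ROLE_WILDTYPE)]
    for pos in range(1, len(wt) + 1):
        wt_letter = wt.residues[pos - 1]
        for letter in alphabet:
            if letter == wt_letter:
                continue
            probes.append(
                Probe(
                    probe_id=f"{name}:{wt_letter}{pos}{letter}",
                    peptide=wt.with_substitution(pos, letter),
                    role=ROLE_SUBSTITUTION,
                    wt_position=pos,
                    substitution=letter,
                )
            )
    return ProbeLibrary(probes, name=name)


# Supported PTM panel specs: builders keyed by name.  Each takes the region
# span and returns keyword arguments for abeta_peptide.
PTM_SPECS = {
    "pSer8": {"phospho_at": (8,)},
    "pSer26": {"phospho_at": (26,)},
    "pE3": {"pyroglu": True},
    "D-Asp1": {"d_stereo_at": (1,)},
    "iso-Asp1": {"iso_asp_at": (1,)},
    "C-amide": {"c_amide": True},
}


def ptm_panel(
    start: int,
    end: int,
    variants: Sequence[str],
    *,
    name: Optional[str] = None,
) -> ProbeLibrary:
    """PTM variant panel over the Abeta span ``start..end``.

    Each requested variant is emitted alongside the unmodified peptide of the
    same span (role ``wildtype``) so the two can be compared head to head.
    ``pE3`` requires the span to begin at Abeta position 3 (cyclization is an
    N-terminal event); phospho/stereo specs require their target position
    inside the span.
    """
    if not variants:
        raise ValueError("no PTM variants requested")
    name = name or f"ptm_ab{start}-{end}"
    control = abeta_peptide(start, end)
    control_id = f"{name}:unmod"
    probes = [Probe(probe_id=control_id, peptide=control, role=ROLE_WILDTYPE)]
    for spec in variants:
        if spec not in PTM_SPECS:
            raise PeptideError(f"unsupported PTM spec {spec!r}; known: {sorted(PTM_SPECS)}")
        if spec == "pE3" and start != 3:
            raise PeptideError("pE3 requires the span to start at Abeta position 3")
        pep = abeta_peptide(start, end, **PTM_SPECS[spec])
        probes.append(
            Probe(
                probe_id=f"{name}:{spec}",
                peptide=pep,
                role=ROLE_PTM,
                partner_id=control_id,
            )
        )
    return ProbeLibrary(probes, name=name)
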