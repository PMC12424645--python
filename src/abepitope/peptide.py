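"""Sequence and coordinate model for amyloid-beta (Abeta) peptides.

Abeta is numbered 1..42 for the canonical peptide released from the amyloid
precursor protein (APP).  N-terminally elongated species extend the numbering
to negative positions (-1, -2, ...) and C-terminal APP residues continue past
42; by convention there is no position 0.  The 74-residue APP770 region
649..722 corresponds to Abeta positions -23..51 and is the substrate for the
overlapping peptide libraries and positional scans built by
:mod:`abepitope.library`.

:class:`ModifiedPeptide` is the single peptide container used throughout the
package.  It carries per-residue modification tags (phosphorylation,
N-terminal pyroglutamate cyclization, D-stereo and iso-aspartate forms of
Asp) plus the termini states, which is all the downstream mass, charge and
array modules need.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "AMINO_ACIDS",
    "ABETA_REGION",
    "ABETA_MIN",
    "ABETA_MAX",
    "APP_REGION_START",
    "APP_REGION_END",
    "AB40_SEQUENCE",
    "AB42_SEQUENCE",
    "MOD_NONE",
    "MOD_PHOSPHO",
    "MOD_PYROGLU",
    "MOD_D_STEREO",
    "MOD_ISO_ASP",
    "PeptideError",
    "ModifiedPeptide",
    "parse_peptide",
    "to_canonical",
    "to_array_digit",
    "abeta_to_app",
    "app_to_abeta",
    "abeta_positions",
    "abeta_subsequence",
    "abeta_peptide",
]

#: The 20 proteinogenic amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# APP770 residues 649..722 == Abeta -23..51.  The central 42-mer is the
# canonical Abeta1-42; 23 N-terminal and 9 C-terminal APP residues flank it.
ABETA_REGION = (
    "GLTTRPGSGLTNIKTEEISEVKM"  # Abeta -23..-1  (APP 649..671)
    "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"  # Abeta 1..42 (APP 672..713)
    "TVIVITLVM"  # Abeta 43..51 (APP 714..722)
)
ABETA_MIN = -23
ABETA_MAX = 51
APP_REGION_START = 649
APP_REGION_END = 722

AB42_SEQUENCE = ABETA_REGION[23:65]
AB40_SEQUENCE = AB42_SEQUENCE[:40]

MOD_NONE = "none"
MOD_PHOSPHO = "phospho"
MOD_PYROGLU = "pyroglutamate"
MOD_D_STEREO = "d-stereo"
MOD_ISO_ASP = "iso-aspartate"

_MOD_TAGS = {MOD_NONE, MOD_PHOSPHO, MOD_PYROGLU, MOD_D_STEREO, MOD_ISO_ASP}

# canonical bracket tags <-> modification names
_TAG_TO_MOD = {"p": MOD_PHOSPHO, "pE": MOD_PYROGLU, "d": MOD_D_STEREO, "iso": MOD_ISO_ASP}
_MOD_TO_TAG = {v: k for k, v in _TAG_TO_MOD.items()}

N_TERM_FREE = "free-amine"
N_TERM_PYROGLU = "pyroglutamate-cyclized"
C_TERM_FREE = "free-acid"
C_TERM_AMIDE = "amide"


class PeptideError(ValueError):
    """Raised for malformed peptide definitions or modification grammar errors."""


def _abeta_index(pos: int) -> int:
    """0-based index into :data:`ABETA_REGION` for an Abeta position."""
    if pos == 0:
        raise PeptideError("Abeta numbering has no position 0")
    if not (ABETA_MIN <= pos <= ABETA_MAX):
        raise PeptideError(f"Abeta position {pos} outside {ABETA_MIN}..{ABETA_MAX}")
    return pos + 23 if pos < 0 else pos + 22


def abeta_to_app(pos: int) -> int:
    """Map an Abeta position (-23..51, no 0) to APP770 numbering (649..722)."""
    return APP_REGION_START + _abeta_index(pos)


def app_to_abeta(pos: int) -> int:
    """Map an APP770 position (649..722) back to Abeta numbering."""
    if not (APP_REGION_START <= pos <= APP_REGION_END):
        raise PeptideError(f"APP770 position {pos} outside {APP_REGION_START}..{APP_REGION_END}")
    idx = pos - APP_REGION_START
    return idx - 23 if idx < 23 else idx - 22


def abeta_positions(start: int, length: int) -> list[int]:
    """The ``length`` consecutive Abeta positions beginning at ``start``.

    Position 0 is skipped: ``abeta_positions(-2, 4) == [-2, -1, 1, 2]``.
    """
    out: list[int] = []
    pos = start
    while len(out) < length:
        if pos == 0:
            pos = 1
        if pos > ABETA_MAX:
            raise PeptideError(
                f"peptide of length {length} starting at Abeta {start} runs past {ABETA_MAX}"
            )
        _abeta_index(pos)  # validates
        out.append(pos)
        pos += 1
    return out


def abeta_subsequence(start: int, end: int) -> str:
    """Residue string for the Abeta span ``start..end`` (inclusive, skipping 0)."""
    i0, i1 = _abeta_index(start), _abeta_index(end)
    if i1 < i0:
        raise PeptideError(f"empty Abeta span {start}..{end}")
    return ABETA_REGION[i0 : i1 + 1]


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with per-residue modification tags and termini states.

    Parameters
    ----------
    residues:
        One-letter residue string (upper case, 20 proteinogenic letters).
    mods:
        Per-position tag, one of ``none``, ``phospho``, ``pyroglutamate``,
        ``d-stereo``, ``iso-aspartate``.  Defaults to all-``none``.
    n_term, c_term:
        ``free-amine``/``pyroglutamate-cyclized`` and ``free-acid``/``amide``.
        The N-terminal state is derived from the first residue's tag and is
        validated for consistency.
    abeta_start:
        Abeta coordinate of the first residue (-23..51, never 0), or ``None``
        for peptides without Abeta coordinates.
    """

    residues: str
    mods: tuple[str, ...] = ()
    n_term: str = N_TERM_FREE
    c_term: str = C_TERM_FREE
    abeta_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError("peptide must contain at least one residue")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise PeptideError(f"unknown residue letter(s): {sorted(bad)}")
        mods = tuple(self.mods) if self.mods else (MOD_NONE,) * len(self.residues)
        if len(mods) != len(self.residues):
            raise PeptideError("mods must have one tag per residue")
        for i, (aa, tag) in enumerate(zip(self.residues, mods)):
            if tag not in _MOD_TAGS:
                raise PeptideError(f"unknown modification tag {tag!r}")
            if tag == MOD_PHOSPHO and aa not in "STY":
                raise PeptideError(f"phospho on {aa} at position {i + 1}: only S/T/Y")
            if tag == MOD_PYROGLU:
                if i != 0:
                    raise PeptideError("pyroglutamate only at peptide position 1")
                if aa not in "EQ":
                    raise PeptideError(f"pyroglutamate on {aa}: only E/Q")
            if tag in (MOD_D_STEREO, MOD_ISO_ASP) and aa != "D":
                raise PeptideError(f"{tag} on {aa} at position {i + 1}: only D")
        object.__setattr__(self, "mods", mods)
        # derive/validate the N-terminal state from the first residue's tag
        n_term = N_TERM_PYROGLU if mods[0] == MOD_PYROGLU else self.n_term
        if n_term not in (N_TERM_FREE, N_TERM_PYROGLU):
            raise PeptideError(f"unknown N-terminus state {n_term!r}")
        if (n_term == N_TERM_PYROGLU) != (mods[0] == MOD_PYROGLU):
            raise PeptideError("cyclized N-terminus requires a pyroglutamate tag at position 1")
        object.__setattr__(self, "n_term", n_term)
        if self.c_term not in (C_TERM_FREE, C_TERM_AMIDE):
            raise PeptideError(f"unknown C-terminus state {self.c_term!r}")
        if self.abeta_start is not None:
            abeta_positions(self.abeta_start, len(self.residues))  # validates range

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return self.residues

    @property
    def is_modified(self) -> bool:
        return any(t != MOD_NONE for t in self.mods) or self.c_term == C_TERM_AMIDE

    @property
    def abeta_coords(self) -> Optional[list[int]]:
        if self.abeta_start is None:
            return None
        return abeta_positions(self.abeta_start, len(self))

    @property
    def abeta_end(self) -> Optional[int]:
        coords = self.abeta_coords
        return coords[-1] if coords else None

    def unmodified(self) -> "ModifiedPeptide":
        """The same residue string with all modifications and termini cleared."""
        return ModifiedPeptide(self.residues, abeta_start=self.abeta_start)

    def with_substitution(self, position: int, letter: str) -> "ModifiedPeptide":
        """Replace the residue at 1-based peptide ``position`` by ``letter``."""
        if not (1 <= position <= len(self)):
            raise PeptideError(f"position {position} outside 1..{len(self)}")
        res = self.residues[: position - 1] + letter + self.residues[position :]
        return ModifiedPeptide(res, self.mods, self.n_term, self.c_term, self.abeta_start)


_CANONICAL_TOKEN = re.compile(r"([A-Z])(?:\[([A-Za-z]+)\])?")


def parse_peptide(
    text: str,
    dialect: str = "canonical",
    abeta_start: Optional[int] = None,
) -> ModifiedPeptide:
    """Parse a modified-sequence string.

    Two dialects are supported.  ``canonical`` uses bracket tags --
    ``S[p]`` phosphoserine, ``E[pE]``/``Q[pE]`` N-terminal pyroglutamate,
    ``D[d]`` D-aspartate, ``D[iso]`` iso-aspartate -- and an optional
    ``-NH2`` suffix for an amidated C-terminus.  ``array-digit`` is the
    compact array-export encoding in which the single character ``2``
    denotes a phosphoserine and no other modification is representable.
    """
    if not text:
        raise PeptideError("empty sequence string")
    if dialect == "array-digit":
        residues, mods = [], []
        for ch in text:
            if ch == "2":
                residues.append("S")
                mods.append(MOD_PHOSPHO)
            elif ch in AMINO_ACIDS:
                residues.append(ch)
                mods.append(MOD_NONE)
            else:
                raise PeptideError(f"unknown residue letter {ch!r} in array-digit string")
        return ModifiedPeptide("".join(residues), tuple(mods), abeta_start=abeta_start)
    if dialect != "canonical":
        raise PeptideError(f"unknown dialect {dialect!r}")

    c_term = C_TERM_FREE
    if text.endswith("-NH2"):
        c_term = C_TERM_AMIDE
        text = text[: -len("-NH2")]
    residues, mods = [], []
    pos = 0
    while pos < len(text):
        m = _CANONICAL_TOKEN.match(text, pos)
        if m is None:
            raise PeptideError(f"cannot parse {text[pos:]!r} at position {pos + 1}")
        aa, tag = m.group(1), m.group(2)
        if aa not in AMINO_ACIDS:
            raise PeptideError(f"unknown residue letter {aa!r}")
        if tag is not None and tag not in _TAG_TO_MOD:
            raise PeptideError(f"unknown modification tag [{tag}]")
        residues.append(aa)
        mods.append(_TAG_TO_MOD[tag] if tag else MOD_NONE)
        pos = m.end()
    return ModifiedPeptide("".join(residues), tuple(mods), c_term=c_term, abeta_start=abeta_start)


def to_canonical(p: ModifiedPeptide) -> str:
    """Write a peptide in the canonical bracket-tag dialect (parser inverse)."""
    parts = []
    for aa, tag in zip(p.residues, p.mods):
        parts.append(aa if tag == MOD_NONE else f"{aa}[{_MOD_TO_TAG[tag]}]")
    out = "".join(parts)
    if p.c_term == C_TERM_AMIDE:
        out += "-NH2"
    return out


def to_array_digit(p: ModifiedPeptide) -> str:
    """Write a peptide in the array-digit dialect ('2' = phosphoserine).

    Only phosphoserine is representable; any other modification raises.
    """
    parts = []
    for aa, tag in zip(p.residues, p.mods):
        if tag == MOD_NONE:
            parts.append(aa)
        elif tag == MOD_PHOSPHO and aa == "S":
            parts.append("2")
        else:
            raise PeptideError(f"array-digit dialect cannot encode {tag} on {aa}")
    if p.c_term == C_TERM_AMIDE:
        raise PeptideError("array-digit dialect cannot encode an amidated C-terminus")
    return "".join(parts)


def abeta_peptide(
    start: int,
    end: int,
    *,
    phospho_at: Iterable[int] = (),
    pyroglu: bool = False,
    d_stereo_at: Iterable[int] = (),
    iso_asp_at: Iterable[int] = (),
    c_amide: bool = False,
) -> ModifiedPeptide:
    """Build an Abeta fragment ``start..end`` with modifications at Abeta positions.

    ``phospho_at``/``d_stereo_at``/``iso_asp_at`` are Abeta coordinates;
    ``pyroglu=True`` cyclizes the first residue (which must be E or Q, e.g.
    the pE3 species when ``start == 3``).
    """
    residues = abeta_subsequence(start, end)
    coords = abeta_positions(start, len(residues))
    index = {c: i for i, c in enumerate(coords)}
    mods = [MOD_NONE] * len(residues)

    def _place(positions: Iterable[int], tag: str) -> None:
        for ab_pos in positions:
            if ab_pos not in index:
                raise PeptideError(f"Abeta position {ab_pos} outside span {start}..{end}")
            mods[index[ab_pos]] = tag

    _place(phospho_at, MOD_PHOSPHO)
    _place(d_stereo_at, MOD_D_STEREO)
    _place(iso_asp_at, MOD_ISO_ASP)
    if pyroglu:
        mods[0] = MOD_PYROGLU
    return ModifiedPeptide(
        residues,
        tuple(mods),
        c_term=C_TERM_AMIDE if c_amide else C_TERM_FREE,
        abeta_start=start,
    )
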