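"""Theoretical mass and isoelectric-point calculators for modified peptides.

Masses follow the usual residue-summation convention: the neutral peptide
mass is the sum of residue (water-loss) masses plus one water, plus the
modification deltas.  Phosphorylation adds HPO3 (+79.96633 Da monoisotopic),
pyroglutamate formation loses water from Glu (-18.010565 Da) or ammonia from
Gln (-17.026549 Da), C-terminal amidation replaces the acid -OH by -NH2
(-0.984016 Da), and stereo/isomer forms of Asp are isobaric (delta 0).
Residue masses are taken from pyteomics.

The isoelectric point is the pH at which the Henderson-Hasselbalch net
charge crosses zero.  The default pKa set is the Bjellqvist table (the set
behind the familiar ExPASy "compute pI" values), with first/last-residue
adjustments of the termini pKa.  A phosphate group is treated as diprotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

from .peptide import (
    AMINO_ACIDS,
    C_TERM_AMIDE,
    MOD_D_STEREO,
    MOD_ISO_ASP,
    MOD_NONE,
    MOD_PHOSPHO,
    MOD_PYROGLU,
    N_TERM_FREE,
    ModifiedPeptide,
    PeptideError,
)

__all__ = [
    "MassTable",
    "DEFAULT_MASS_TABLE",
    "PROTON_MASS",
    "peptide_mass",
    "PkaSet",
    "BJELLQVIST",
    "net_charge",
    "isoelectric_point",
    "ChargeError",
]

PROTON_MASS = 1.00727646688


def _avg(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula, average=True)


def _mono(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula)


@dataclass(frozen=True)
class MassTable:
    """Per-residue masses and modification deltas (monoisotopic and average)."""

    residues_mono: dict[str, float]
    residues_avg: dict[str, float]
    mod_deltas_mono: dict[str, float]
    mod_deltas_avg: dict[str, float]
    water_mono: float
    water_avg: float
    amide_delta_mono: float
    amide_delta_avg: float
    proton: float = PROTON_MASS

    def residue(self, aa: str, kind: str) -> float:
        table = self.residues_mono if kind == "monoisotopic" else self.residues_avg
        if aa not in table:
            raise PeptideError(f"residue {aa!r} missing from mass table")
        return table[aa]

    def mod_delta(self, peptide_aa: str, tag: str, kind: str) -> float:
        key = tag
        if tag == MOD_PYROGLU:
            # the delta depends on which residue cyclized: water loss from E,
            # ammonia loss from Q
            key = f"{MOD_PYROGLU}-{peptide_aa}"
        table = self.mod_deltas_mono if kind == "monoisotopic" else self.mod_deltas_avg
        return table[key]


def _default_mass_table() -> MassTable:
    mono = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}
    water_avg = _avg("H2O")
    avg = {
        aa: _pmass.calculate_mass(sequence=aa, average=True) - water_avg for aa in AMINO_ACIDS
    }
    deltas = {
        MOD_PHOSPHO: ("HPO3", 1),
        f"{MOD_PYROGLU}-E": ("H2O", -1),
        f"{MOD_PYROGLU}-Q": ("NH3", -1),
    }
    d_mono = {k: sign * _mono(f) for k, (f, sign) in deltas.items()}
    d_avg = {k: sign * _avg(f) for k, (f, sign) in deltas.items()}
    # stereo and isomer forms of Asp are isobaric with the L-form
    for tag in (MOD_D_STEREO, MOD_ISO_ASP):
        d_mono[tag] = 0.0
        d_avg[tag] = 0.0
    d_mono[MOD_NONE] = d_avg[MOD_NONE] = 0.0
    # C-terminal amide: -OH -> -NH2, i.e. +NH -O +... net N + H - O
    amide_mono = _mono("NH3") - _mono("H2O")
    amide_avg = _avg("NH3") - _avg("H2O")
    return MassTable(
        residues_mono=mono,
        residues_avg=avg,
        mod_deltas_mono=d_mono,
        mod_deltas_avg=d_avg,
        water_mono=_mono("H2O"),
        water_avg=water_avg,
        amide_delta_mono=amide_mono,
        amide_delta_avg=amide_avg,
    )


DEFAULT_MASS_TABLE = _default_mass_table()


def peptide_mass(
    p: ModifiedPeptide,
    kind: str = "monoisotopic",
    adduct: str = "neutral",
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Theoretical mass of a modified peptide in Da.

    ``kind`` is ``monoisotopic`` or ``average``; ``adduct`` is ``neutral`` or
    ``MH+`` (singly protonated ion mass).
    """
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass kind {kind!r}")
    if adduct not in ("neutral", "MH+"):
        raise ValueError(f"unknown adduct {adduct!r}")
    total = table.water_mono if kind == "monoisotopic" else table.water_avg
    for aa, tag in zip(p.residues, p.mods):
        total += table.residue(aa, kind)
        total += table.mod_delta(aa, tag, kind)
    if p.c_term == C_TERM_AMIDE:
        total += table.amide_delta_mono if kind == "monoisotopic" else table.amide_delta_avg
    if adduct == "MH+":
        total += table.proton
    return total


class ChargeError(ValueError):
    """Raised when a peptide has no ionizable group (no defined pI)."""


@dataclass(frozen=True)
class PkaSet:
    """Named pKa table for side chains and termini.

    ``n_term_by_residue``/``c_term_by_residue`` override the generic termini
    pKa depending on the first/last residue.  ``phospho`` holds the two pKa
    values of the diprotic phosphate monoester.
    """

    name: str = "bjellqvist"
    positive: dict[str, float] = field(
        default_factory=lambda: {"K": 10.0, "R": 12.0, "H": 5.98}
    )
    negative: dict[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    n_term: float = 7.5
    c_term: float = 3.55
    n_term_by_residue: dict[str, float] = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
        }
    )
    c_term_by_residue: dict[str, float] = field(
        default_factory=lambda: {"D": 4.55, "E": 4.75}
    )
    phospho: tuple[float, float] = (1.2, 6.5)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("PkaSet must have a name")
        values = (
            list(self.positive.values())
            + list(self.negative.values())
            + [self.n_term, self.c_term]
            + list(self.n_term_by_residue.values())
            + list(self.c_term_by_residue.values())
            + list(self.phospho)
        )
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")


BJELLQVIST = PkaSet()

PKA_SETS = {"bjellqvist": BJELLQVIST}


def _ionizable_groups(p: ModifiedPeptide, pka: PkaSet) -> tuple[list[float], list[float]]:
    """(positive pKas, negative pKas) of every ionizable group of ``p``."""
    pos: list[float] = []
    neg: list[float] = []
    if p.n_term == N_TERM_FREE:
        pos.append(pka.n_term_by_residue.get(p.residues[0], pka.n_term))
    if p.c_term != C_TERM_AMIDE:
        neg.append(pka.c_term_by_residue.get(p.residues[-1], pka.c_term))
    for aa, tag in zip(p.residues, p.mods):
        if tag == MOD_PYROGLU and aa == "E":
            continue  # the Glu side-chain carboxyl is consumed by the lactam ring
        if aa in pka.positive:
            pos.append(pka.positive[aa])
        if aa in pka.negative:
            neg.append(pka.negative[aa])
        if tag == MOD_PHOSPHO:
            neg.extend(pka.phospho)
    return pos, neg


def net_charge(p: ModifiedPeptide, pH: float, pka: PkaSet = BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge of ``p`` at the given pH."""
    pos, neg = _ionizable_groups(p, pka)
    q = sum(1.0 / (1.0 + 10.0 ** (pH - pk)) for pk in pos)
    q -= sum(1.0 / (1.0 + 10.0 ** (pk - pH)) for pk in neg)
    return q


def isoelectric_point(
    p: ModifiedPeptide,
    pka: PkaSet = BJELLQVIST,
    tol: float = 1e-6,
) -> float:
    """pH at which the net charge crosses zero, found by bisection.

    Raises :class:`ChargeError` if the peptide carries no ionizable group or
    its charge never crosses zero within pH 0..14 (e.g. an amidated,
    pyroglutamate-cyclized glycine peptide).
    """
    pos, neg = _ionizable_groups(p, pka)
    if not pos or not neg:
        raise ChargeError("net charge never crosses zero: peptide lacks ionizable groups")
    lo, hi = 0.0, 14.0
    q_lo, q_hi = net_charge(p, lo, pka), net_charge(p, hi, pka)
    if q_lo <= 0.0 or q_hi >= 0.0:
        raise ChargeError("net charge does not change sign over pH 0..14")
    while True:
        mid = 0.5 * (lo + hi)
        q = net_charge(p, mid, pka)
        if abs(q) < tol or (hi - lo) < 1e-12:
            return mid
        if q > 0.0:
            lo = mid
        else:
            hi = mid
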