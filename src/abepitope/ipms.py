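"""Theoretical mass panel for Abeta variants and spectrum peak assignment.

An immunoprecipitation/MALDI-TOF readout is interpreted against a panel of
candidate Abeta species with known theoretical [M+H]+ masses.  The built-in
ten-member panel covers the canonical peptides (Abeta1-40, 1-42),
N-terminally truncated species (2-40, 3-40, pE3-40, 4-40, 5-40, 11-40), the
N-terminally elongated Abeta(-3)-40, and C-terminally amidated
pSer8-Abeta1-40.

Matching uses average masses by default (singly protonated 3-5 kDa peptides
in linear/reflector MALDI), with a configurable tolerance in Da.  Relative
per-variant intensities are reported as peak-height fractions of the summed
assigned heights and are semi-quantitative only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem import isoelectric_point, peptide_mass
from .peptide import ModifiedPeptide, abeta_peptide

__all__ = [
    "PanelEntry",
    "VariantPanel",
    "build_panel",
    "DEFAULT_PANEL_SPECS",
    "PeakAssignment",
    "AssignmentResult",
    "pick_peaks",
    "assign_peaks",
]


@dataclass(frozen=True)
class PanelEntry:
    """One named Abeta variant with its four theoretical mass values."""

    name: str
    peptide: ModifiedPeptide
    mono: float
    avg: float
    mh_mono: float
    mh_avg: float

    def mh(self, kind: str) -> float:
        return self.mh_mono if kind == "monoisotopic" else self.mh_avg


# (name, span start, span end, modification kwargs) for the default
# ten-member synthetic peptide mixture.
DEFAULT_PANEL_SPECS: list[tuple[str, int, int, dict]] = [
    ("Abeta1-40", 1, 40, {}),
    ("Abeta1-42", 1, 42, {}),
    ("Abeta2-40", 2, 40, {}),
    ("Abeta3-40", 3, 40, {}),
    ("AbetapE3-40", 3, 40, {"pyroglu": True}),
    ("Abeta4-40", 4, 40, {}),
    ("Abeta5-40", 5, 40, {}),
    ("Abeta11-40", 11, 40, {}),
    ("Abeta-3-40", -3, 40, {}),
    ("pSer8-Abeta1-40-amide", 1, 40, {"phospho_at": (8,), "c_amide": True}),
]


class VariantPanel:
    """Named Abeta variants with theoretical neutral and [M+H]+ masses."""

    def __init__(self, entries: Sequence[PanelEntry]):
        self.entries = list(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("variant names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "sequence": [e.peptide.residues for e in self.entries],
                "mono": [e.mono for e in self.entries],
                "avg": [e.avg for e in self.entries],
                "mh_mono": [e.mh_mono for e in self.entries],
                "mh_avg": [e.mh_avg for e in self.entries],
            }
        )

    def to_json(self, path: Union[str, Path]) -> None:
        """JSON export of the variant annotations (masses and theoretical pI)."""
        records = []
        for e in self.entries:
            records.append(
                {
                    "name": e.name,
                    "sequence": e.peptide.residues,
                    "abeta_start": e.peptide.abeta_start,
                    "monoisotopic": round(e.mono, 4),
                    "average": round(e.avg, 4),
                    "mh_monoisotopic": round(e.mh_mono, 4),
                    "mh_average": round(e.mh_avg, 4),
                    "pi": round(isoelectric_point(e.peptide), 2),
                }
            )
        Path(path).write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")


def build_panel(
    specs: Optional[Sequence[tuple[str, int, int, dict]]] = None
) -> VariantPanel:
    """Build a variant panel from (name, start, end, mods) specs.

    With no argument the default ten-member mixture is built.
    """
    specs = DEFAULT_PANEL_SPECS if specs is None else specs
    entries = []
    for name, start, end, kwargs in specs:
        pep = abeta_peptide(start, end, **kwargs)
        mono = peptide_mass(pep, "monoisotopic", "neutral")
        avg = peptide_mass(pep, "average", "neutral")
        entries.append(
            PanelEntry(
                name=name,
                peptide=pep,
                mono=mono,
                avg=avg,
                mh_mono=peptide_mass(pep, "monoisotopic", "MH+"),
                mh_avg=peptide_mass(pep, "average", "MH+"),
            )
        )
    return VariantPanel(entries)


@dataclass(frozen=True)
class PeakAssignment:
    """One detected peak matched (or not) to a panel variant."""

    mz: float
    intensity: float
    variant: str  # variant name or "unassigned"
    mass_error: Optional[float]  # observed - theoretical, Da
    ambiguous: bool


@dataclass
class AssignmentResult:
    assignments: list[PeakAssignment]
    variant_fractions: dict[str, float]  # semi-quantitative height fractions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": [a.mz for a in self.assignments],
                "intensity": [a.intensity for a in self.assignments],
                "variant": [a.variant for a in self.assignments],
                "mass_error": [a.mass_error for a in self.assignments],
                "ambiguous": [a.ambiguous for a in self.assignments],
            }
        )


def pick_peaks(
    mz: np.ndarray, intensity: np.ndarray, min_snr: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum peak picking above ``min_snr`` times the median intensity.

    Works both on profile spectra and on already-centroided peak lists (every
    point that dominates its immediate neighbours counts).
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    if mz.size == 1:
        keep = np.array([True])
    else:
        left = np.r_[True, intensity[1:] > intensity[:-1]]
        right = np.r_[intensity[:-1] >= intensity[1:], True]
        keep = left & right
    floor = min_snr * float(np.median(intensity))
    keep &= intensity > floor
    return mz[keep], intensity[keep]


def assign_peaks(
    spectrum: Union[pd.DataFrame, tuple[np.ndarray, np.ndarray]],
    panel: VariantPanel,
    tolerance: float = 1.0,
    min_snr: float = 3.0,
    mass_kind: str = "average",
) -> AssignmentResult:
    """Assign detected peaks to the nearest panel [M+H]+ mass within tolerance.

    Each peak is matched to at most one variant (smallest absolute mass
    error); it is flagged ambiguous when two or more variants lie within the
    tolerance.  An empty spectrum yields an empty assignment list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(spectrum, pd.DataFrame):
        mz = spectrum.iloc[:, 0].to_numpy(float)
        inten = spectrum.iloc[:, 1].to_numpy(float)
    else:
        mz, inten = (np.asarray(a, dtype=float) for a in spectrum)
    if mz.size == 0:
        return AssignmentResult(assignments=[], variant_fractions={})

    peak_mz, peak_int = pick_peaks(mz, inten, min_snr=min_snr)
    targets = np.array([e.mh(mass_kind) for e in panel])
    names = panel.names

    assignments: list[PeakAssignment] = []
    heights: dict[str, float] = {}
    for m, h in zip(peak_mz, peak_int):
        err = m - targets
        within = np.abs(err) <= tolerance
        if not within.any():
            assignments.append(PeakAssignment(float(m), float(h), "unassigned", None, False))
            continue
        best = int(np.argmin(np.abs(err)))
        assignments.append(
            PeakAssignment(
                mz=float(m),
                intensity=float(h),
                variant=names[best],
                mass_error=float(err[best]),
                ambiguous=int(within.sum()) > 1,
            )
        )
        heights[names[best]] = heights.get(names[best], 0.0) + float(h)
    total = sum(heights.values())
    fractions = {k: v / total for k, v in heights.items()} if total > 0 else {}
    return AssignmentResult(assignments=assignments, variant_fractions=fractions)
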