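"""From raw probe intensities to epitope calls.

This implements the array-analysis procedure at the heart of the package:

1. replicate intensities are averaged per probe and the substitution matrix
   is normalized against the wildtype probe of the same scan
   (``r = mean(variant) / mean(wildtype)``);
2. a substitution is *dominant negative* when it reduces binding by more
   than 50% (``r < 0.5``, strictly -- a gain of binding is never flagged);
3. a scanned position belongs to the *core motif* when at least 10 of its 19
   substitutions are dominant negative (the smallest integer count exceeding
   50% of 19); non-core positions are written as ``X`` in the motif string;
4. named single-residue variants (familial Alzheimer's disease mutations,
   rodent sequence differences) are classified against the same ratio rule;
5. antibody titrations are fitted with a Boltzmann sigmoid on
   log10(concentration) to report an EC50.

All thresholds are explicit keyword arguments with the defaults above.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lmfit import Model

from .library import ProbeLibrary, ROLE_SUBSTITUTION
from .peptide import AMINO_ACIDS, abeta_positions

__all__ = [
    "read_intensity_table",
    "DmsMatrix",
    "normalize_to_wildtype",
    "call_dominant_negative",
    "call_core_motif",
    "CoreMotif",
    "variant_impact_report",
    "FAD_VARIANTS",
    "RODENT_VARIANTS",
    "DoseResponseFit",
    "fit_titration",
    "selectivity_ratio",
    "heatmap_matrix",
]

REQUIRED_COLUMNS = ("probe_id", "antibody", "replicate", "intensity")


def read_intensity_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate an intensity table CSV.

    Required columns: probe_id, antibody, replicate, intensity; optional:
    concentration, background.  Intensities must be non-negative.
    """
    df = pd.read_csv(path)
    return validate_intensity_table(df)


def validate_intensity_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing column(s) {missing}")
    if (df["intensity"] < 0).any():
        raise ValueError("raw intensities must be non-negative")
    if "background" in df.columns and (df["background"] < 0).any():
        raise ValueError("background values must be non-negative")
    return df


@dataclass
class DmsMatrix:
    """Position x substitution matrix of wildtype-normalized binding ratios.

    ``ratios`` is indexed by 1-based peptide position with one column per
    substitution letter; the wildtype letter at each position is NaN (its
    implied ratio is 1 by construction).
    """

    antibody: str
    wt_sequence: str
    ratios: pd.DataFrame
    wt_mean: float
    abeta_start: Optional[int] = None

    @property
    def positions(self) -> list[int]:
        return list(self.ratios.index)

    @property
    def abeta_coords(self) -> Optional[list[int]]:
        if self.abeta_start is None:
            return None
        return abeta_positions(self.abeta_start, len(self.wt_sequence))

    def ratio(self, position: int, letter: str) -> float:
        """Normalized ratio for a (1-based peptide position, letter) pair."""
        return float(self.ratios.at[position, letter])

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f"# antibody={self.antibody}\n")
            fh.write(f"# wt_sequence={self.wt_sequence}\n")
            fh.write(f"# wt_mean={self.wt_mean!r}\n")
            fh.write(f"# abeta_start={self.abeta_start}\n")
            self.ratios.to_csv(fh, index_label="position")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DmsMatrix":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# "):
                key, _, value = line[2:].strip().partition("=")
                meta[key] = value
                body_start = i + 1
            else:
                break
        from io import StringIO

        ratios = pd.read_csv(StringIO("".join(lines[body_start:])), index_col="position")
        start = None if meta.get("abeta_start") in (None, "None") else int(meta["abeta_start"])
        return cls(
            antibody=meta["antibody"],
            wt_sequence=meta["wt_sequence"],
            ratios=ratios,
            wt_mean=float(meta["wt_mean"]),
            abeta_start=start,
        )


def normalize_to_wildtype(
    table: pd.DataFrame,
    library: ProbeLibrary,
    antibody: str,
    *,
    floor_frac: float = 0.01,
) -> DmsMatrix:
    """Build the wildtype-normalized substitution matrix for one antibody.

    Replicates are aggregated by the arithmetic mean of raw intensities (a
    ``background`` column, when present, is subtracted first).  The wildtype
    mean must exceed a floor of ``floor_frac`` times the antibody's maximum
    probe mean, otherwise the ratios would be numerically meaningless and a
    ValueError is raised.
    """
    validate_intensity_table(table)
    sub = table[table["antibody"] == antibody].copy()
    if sub.empty:
        raise ValueError(f"no intensities for antibody {antibody!r}")
    if "background" in sub.columns:
        sub["intensity"] = sub["intensity"] - sub["background"]
    means = sub.groupby("probe_id")["intensity"].mean()

    wt_probe = library.wildtype
    if wt_probe is None:
        raise ValueError("library has no wildtype reference probe")
    if wt_probe.probe_id not in means.index:
        raise ValueError(f"wildtype probe {wt_probe.probe_id!r} absent from intensity table")
    wt_mean = float(means[wt_probe.probe_id])
    floor = floor_frac * float(means.max())
    if wt_mean <= floor:
        raise ValueError(
            f"wildtype signal below floor ({wt_mean:.4g} <= {floor:.4g}); "
            "matrix not computable for this antibody/exposure"
        )

    wt_seq = wt_probe.peptide.residues
    letters = sorted(AMINO_ACIDS)
    ratios = pd.DataFrame(
        np.nan, index=pd.RangeIndex(1, len(wt_seq) + 1, name="position"), columns=letters
    )
    for probe in library:
        if probe.role != ROLE_SUBSTITUTION:
            continue
        if probe.probe_id not in means.index:
            raise ValueError(f"substitution probe {probe.probe_id!r} missing from table")
        ratios.at[probe.wt_position, probe.substitution] = means[probe.probe_id] / wt_mean
    return DmsMatrix(
        antibody=antibody,
        wt_sequence=wt_seq,
        ratios=ratios,
        wt_mean=wt_mean,
        abeta_start=wt_probe.peptide.abeta_start,
    )


def call_dominant_negative(m: DmsMatrix, threshold: float = 0.5) -> pd.DataFrame:
    """Boolean flags: True where a substitution reduces binding by more than
    ``1 - threshold`` (i.e. ``r < threshold``, strict).  Wildtype cells and
    gains of binding are never flagged."""
    flags = m.ratios < threshold  # NaN comparisons yield False
    return flags


@dataclass
class CoreMotif:
    """Core binding positions of one antibody plus the wildcarded motif string."""

    antibody: str
    core_positions: list[int]  # Abeta coordinates when available, else peptide positions
    motif: str  # wildtype letter at core positions, 'X' elsewhere
    counts: list[int]  # dominant-negative count per scanned position
    min_count: int
    coordinates: str = "abeta"  # or "peptide"

    def to_dict(self) -> dict:
        return {
            "antibody": self.antibody,
            "core_positions": self.core_positions,
            "motif": self.motif,
            "dominant_negative_counts": self.counts,
            "min_count": self.min_count,
            "coordinates": self.coordinates,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def call_core_motif(
    m: DmsMatrix,
    min_count: int = 10,
    threshold: float = 0.5,
) -> CoreMotif:
    """Call the core motif from dominant-negative counts.

    A position is core when its dominant-negative count is at least
    ``min_count`` (default 10 of the 19 possible substitutions, the smallest
    integer exceeding half of them).
    """
    flags = call_dominant_negative(m, threshold=threshold)
    counts = flags.sum(axis=1).astype(int)
    coords = m.abeta_coords
    use_abeta = coords is not None
    core: list[int] = []
    motif = []
    for i, pos in enumerate(m.positions):
        label = coords[i] if use_abeta else pos
        if counts.loc[pos] >= min_count:
            core.append(label)
            motif.append(m.wt_sequence[i])
        else:
            motif.append("X")
    return CoreMotif(
        antibody=m.antibody,
        core_positions=core,
        motif="".join(motif),
        counts=[int(c) for c in counts],
        min_count=min_count,
        coordinates="abeta" if use_abeta else "peptide",
    )


# Familial Alzheimer's disease substitutions within Abeta, and the rodent
# (mouse/rat) sequence differences, in Abeta coordinates.
FAD_VARIANTS = {
    "A2V": (2, "V"),
    "A2T": (2, "T"),
    "H6R": (6, "R"),
    "D7H": (7, "H"),
    "D7N": (7, "N"),
    "K16Q": (16, "Q"),
    "L17V": (17, "V"),
}
RODENT_VARIANTS = {"R5G": (5, "G"), "Y10F": (10, "F")}


def variant_impact_report(
    m: DmsMatrix,
    motif: Optional[CoreMotif] = None,
    variants: Optional[dict[str, tuple[int, str]]] = None,
    threshold: float = 0.5,
) -> list[dict]:
    """Classify named single-residue variants against the scan.

    Each variant (position in Abeta coordinates when the matrix carries them,
    else peptide coordinates) is classified ``binding-reducing`` when
    ``r < threshold``, ``tolerated`` when ``r >= threshold``, or
    ``not covered`` when outside the scanned span.
    """
    if variants is None:
        variants = {**FAD_VARIANTS, **RODENT_VARIANTS}
    coords = m.abeta_coords
    lookup = (
        {c: p for c, p in zip(coords, m.positions)}
        if coords is not None
        else {p: p for p in m.positions}
    )
    core = set(motif.core_positions) if motif is not None else None
    report = []
    for name, (pos, letter) in sorted(variants.items()):
        entry: dict = {"variant": name, "position": pos, "substitution": letter}
        if pos not in lookup:
            entry.update({"ratio": None, "classification": "not covered"})
        else:
            row = lookup[pos]
            wt_letter = m.wt_sequence[m.positions.index(row)]
            if letter == wt_letter:
                entry.update({"ratio": 1.0, "classification": "tolerated"})
            else:
                r = m.ratio(row, letter)
                entry.update(
                    {
                        "ratio": float(r),
                        "classification": "binding-reducing" if r < threshold else "tolerated",
                    }
                )
        if core is not None:
            entry["in_core_motif"] = pos in core
        report.append(entry)
    return report


@dataclass
class DoseResponseFit:
    """Boltzmann sigmoid fit of a titration on log10(concentration)."""

    bottom: float
    top: float
    x50: float  # log10 concentration at the half transition
    slope: float
    r_squared: float
    converged: bool
    no_transition: bool = False

    @property
    def ec50(self) -> Optional[float]:
        if self.no_transition:
            return None
        return 10.0 ** self.x50

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(concentration, dtype=float))
        return _boltzmann(x, self.bottom, self.top, self.x50, self.slope)

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "x50": self.x50,
            "slope": self.slope,
            "ec50": self.ec50,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "no_transition": self.no_transition,
        }


def _boltzmann(x, bottom, top, x50, slope):
    return bottom + (top - bottom) / (1.0 + np.exp((x50 - x) / slope))


def fit_titration(
    concentration: Sequence[float],
    response: Sequence[float],
) -> DoseResponseFit:
    """Least-squares Boltzmann fit of a concentration-response series.

    Requires at least five points spanning more than one decade of
    concentration.  A flat series is returned with ``no_transition`` set and
    no EC50 rather than a spurious midpoint.
    """
    c = np.asarray(concentration, dtype=float)
    y = np.asarray(response, dtype=float)
    if c.size != y.size:
        raise ValueError("concentration and response must have equal length")
    if c.size < 5:
        raise ValueError("titration fit needs at least 5 points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.log10(c.max() / c.min()) <= 1.0:
        raise ValueError("titration must span more than one decade of concentration")

    scale = max(np.max(np.abs(y)), 1.0)
    if np.ptp(y) <= 1e-9 * scale:
        return DoseResponseFit(
            bottom=float(y.mean()),
            top=float(y.mean()),
            x50=float("nan"),
            slope=float("nan"),
            r_squared=float("nan"),
            converged=True,
            no_transition=True,
        )

    x = np.log10(c)
    model = Model(_boltzmann)
    half = 0.5 * (y.min() + y.max())
    x50_guess = float(x[np.argmin(np.abs(y - half))])
    params = model.make_params(
        bottom=float(y.min()), top=float(y.max()), x50=x50_guess, slope=0.5
    )
    params["slope"].set(min=1e-3)
    result = model.fit(y, params, x=x)
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    bottom = float(result.params["bottom"].value)
    top = float(result.params["top"].value)
    # normalize so top >= bottom (the Boltzmann form is symmetric under
    # swapping the plateaus with a sign change of the slope)
    if top < bottom:
        bottom, top = top, bottom
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        x50=float(result.params["x50"].value),
        slope=float(result.params["slope"].value),
        r_squared=r2,
        converged=bool(result.success),
    )


def selectivity_ratio(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> Optional[float]:
    """EC50_a / EC50_b, reported only when both fits converged with a transition."""
    if not (fit_a.converged and fit_b.converged):
        return None
    if fit_a.no_transition or fit_b.no_transition:
        return None
    return fit_a.ec50 / fit_b.ec50


def heatmap_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-antibody min-max scaling of probe intensity vectors to [0, 1].

    ``profiles`` has one column per antibody and one row per probe; each
    column is scaled independently (no cross-antibody coupling) and probe
    order is preserved.  An all-equal column is returned as zeros with a
    "flat profile" warning.
    """
    scaled = profiles.astype(float).copy()
    for col in scaled.columns:
        v = scaled[col].to_numpy()
        span = v.max() - v.min()
        if span == 0:
            warnings.warn(f"flat profile for antibody {col!r}; scaled to zeros")
            scaled[col] = 0.0
        else:
            scaled[col] = (v - v.min()) / span
    return scaled
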