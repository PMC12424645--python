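"""End-to-end orchestration: config, staged execution, provenance.

``run_pipeline`` ties the array-analysis stages together for one or more
antibodies: read the probe library and intensity table, build the
wildtype-normalized substitution matrix, call the core motif, classify the
built-in variant sets, and write every result (plus the verbatim config and
a provenance record) into the output directory.  Identical config and seeds
give byte-identical result JSONs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .analysis import (
    call_core_motif,
    normalize_to_wildtype,
    read_intensity_table,
    variant_impact_report,
)
from .chem import PKA_SETS
from .library import ProbeLibrary

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("abepitope")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    intensity_csv: str
    library_csv: str
    out_dir: str
    antibodies: Optional[list[str]] = None  # default: every antibody in the table
    dominant_negative_threshold: float = 0.5
    core_min_count: int = 10
    wt_floor_frac: float = 0.01
    mass_tolerance: float = 1.0
    pka_set: str = "bjellqvist"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.dominant_negative_threshold < 1.0):
            raise ValueError(
                f"dominant-negative threshold {self.dominant_negative_threshold} "
                "outside (0, 1)"
            )
        if not (1 <= self.core_min_count <= 19):
            raise ValueError(f"core min count {self.core_min_count} outside 1..19")
        if not (0.0 < self.wt_floor_frac < 1.0):
            raise ValueError(f"wildtype floor fraction {self.wt_floor_frac} outside (0, 1)")
        if self.mass_tolerance <= 0:
            raise ValueError("mass tolerance must be positive")
        if self.pka_set not in PKA_SETS:
            raise ValueError(f"unknown pKa set {self.pka_set!r}; known: {sorted(PKA_SETS)}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the analysis stages in dependency order; return output paths.

    Every output lands inside ``config.out_dir``.  Hard errors surface the
    failing stage name via :class:`PipelineError`.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    outputs: dict[str, str] = {}
    try:
        t0 = time.perf_counter()
        try:
            library = ProbeLibrary.from_csv(config.library_csv)
            table = read_intensity_table(config.intensity_csv)
        except Exception as exc:
            raise PipelineError(f"stage 'load-inputs' failed: {exc}") from exc
        log.info(
            "load-inputs: %d probes, %d intensity rows (%.2fs)",
            len(library),
            len(table),
            time.perf_counter() - t0,
        )

        antibodies = config.antibodies or sorted(table["antibody"].unique())
        for antibody in antibodies:
            t0 = time.perf_counter()
            try:
                matrix = normalize_to_wildtype(
                    table, library, antibody, floor_frac=config.wt_floor_frac
                )
                motif = call_core_motif(
                    matrix,
                    min_count=config.core_min_count,
                    threshold=config.dominant_negative_threshold,
                )
                impact = variant_impact_report(
                    matrix, motif, threshold=config.dominant_negative_threshold
                )
            except Exception as exc:
                raise PipelineError(f"stage 'analyze:{antibody}' failed: {exc}") from exc

            safe = antibody.replace("/", "_")
            matrix_path = out_dir / f"dms_matrix_{safe}.csv"
            motif_path = out_dir / f"core_motif_{safe}.json"
            impact_path = out_dir / f"impact_{safe}.json"
            matrix.to_csv(matrix_path)
            motif.to_json(motif_path)
            _write_json(impact_path, impact)
            outputs[f"matrix:{antibody}"] = str(matrix_path)
            outputs[f"motif:{antibody}"] = str(motif_path)
            outputs[f"impact:{antibody}"] = str(impact_path)
            log.info(
                "analyze:%s: motif=%s core=%s (%.2fs)",
                antibody,
                motif.motif,
                motif.core_positions,
                time.perf_counter() - t0,
            )

        config_path = out_dir / "config.yaml"
        config.to_yaml(config_path)
        provenance = {
            "package": "abepitope",
            "version": __version__,
            "config_sha256": config.digest(),
            "seed": config.seed,
            "antibodies": antibodies,
        }
        _write_json(out_dir / "provenance.json", provenance)
        outputs["config"] = str(config_path)
        outputs["provenance"] = str(out_dir / "provenance.json")
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()
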