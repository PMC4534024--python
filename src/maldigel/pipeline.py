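"""End-to-end pipeline: calibrate -> search per spot -> quantify -> differential.

A single PipelineConfig drives the run; the report echoes the resolved
configuration verbatim so every number it contains is reproducible from the
report alone. Runs are deterministic under a fixed config: no randomness is
drawn anywhere in the pipeline itself.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

from . import io
from .calibration import DEFAULT_STANDARDS, CalibrationError, ReferenceStandard, calibrate
from .diagnostics import validate_marker
from .digestion import TRYPSIN, DigestParams, digest_database
from .gel_diff import differential_report, presence_matrix, specificity_filter
from .pmf import SearchParams, search


class DigestConfig(BaseModel):
    max_missed_cleavages: int = 1
    min_mass: float = 500.0
    max_mass: float = 4000.0

    def to_params(self) -> DigestParams:
        return DigestParams(
            max_missed_cleavages=self.max_missed_cleavages,
            min_mass=self.min_mass,
            max_mass=self.max_mass,
        )


class SearchConfig(BaseModel):
    relative_tolerance: float = 2.5e-5
    mass_convention: str = "protonated"
    min_matched: int = 1

    def to_params(self) -> SearchParams:
        return SearchParams(
            relative_tolerance=self.relative_tolerance,
            mass_convention=self.mass_convention,  # type: ignore[arg-type]
            min_matched=self.min_matched,
        )


class StandardConfig(BaseModel):
    name: str
    sequence: str | None = None
    mz: float | None = None


class PipelineConfig(BaseModel):
    """Everything a run needs; fully serialisable."""

    fasta: str
    peak_lists: list[str] = Field(default_factory=list)  # TSV paths
    spot_table: str | None = None
    densitometry_table: str | None = None
    digest: DigestConfig = Field(default_factory=DigestConfig)
    search: SearchConfig = Field(default_factory=SearchConfig)
    standards: list[StandardConfig] = Field(
        default_factory=lambda: [
            StandardConfig(name=s.name, sequence=s.sequence) for s in DEFAULT_STANDARDS
        ]
    )
    calibration_coarse_tol: float = 1.0
    fold_threshold: float = 1.5
    presence_threshold: float = 0.0
    diagnostic_threshold: float = 0.0
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the machine-readable report."""
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "warnings": [],
        "stages": {},
    }
    records = io.parse_fasta(config.fasta)
    index = digest_database(records, TRYPSIN, config.digest.to_params())
    report["stages"]["digest"] = {
        "n_proteins": len(records),
        "n_peptides": len(index),
    }

    standards = tuple(
        ReferenceStandard(name=s.name, sequence=s.sequence, mz=s.mz)
        for s in config.standards
    )
    params = config.search.to_params()
    identifications = []
    for path in config.peak_lists:
        raw = io.parse_peaklist_tsv(path)
        try:
            peaks, model = calibrate(raw, standards, config.calibration_coarse_tol)
            cal = model.to_dict()
        except CalibrationError as err:
            report["warnings"].append(f"{path}: {err}; searching uncalibrated")
            peaks, cal = raw, None
        result = search(
            peaks, index, params, allow_uncalibrated=True
        )
        identifications.append(
            {
                "peak_list": str(path),
                "calibration": cal,
                "result": result.to_dict(),
            }
        )
    if config.peak_lists:
        report["stages"]["identification"] = identifications

    if config.spot_table:
        table = io.parse_spot_csv(config.spot_table)
        frame, summary = differential_report(
            table, config.fold_threshold, config.presence_threshold
        )
        presence = presence_matrix(table, config.presence_threshold)
        design = dict(
            zip(table["gel_id"], table["group"])
        )
        specific = specificity_filter(presence, design)
        flagged = frame[frame["differential"] | frame["case_specific"] | frame["control_specific"]]
        report["stages"]["differential"] = {
            "n_spots": summary.n_spots,
            "n_differential": summary.n_differential,
            "n_case_specific": summary.n_case_specific,
            "n_control_specific": summary.n_control_specific,
            "tumour_specific": specific,
            "flagged_spots": sorted(flagged["spot_id"].tolist()),
        }

    if config.densitometry_table:
        dens = io.parse_densitometry_csv(config.densitometry_table)
        summary, cm, _ = validate_marker(dens, config.diagnostic_threshold)
        report["stages"]["diagnostics"] = {
            "summary": summary.to_dict(),
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
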