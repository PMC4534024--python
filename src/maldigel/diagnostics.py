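"""Binary-marker validation on Western-blot densitometry.

Band intensities are normalised to a loading control (beta-actin), called
positive above a threshold, and summarised as a confusion matrix with
sensitivity and specificity. Metric arithmetic is exact (Fraction) before any
display rounding; a metric whose denominator is empty (no cases, or no
controls) is reported as absent rather than as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

DENSITOMETRY_COLUMNS = ["sample_id", "group", "marker_intensity", "actin_intensity"]


def normalize_band(marker_intensity: float, loading_intensity: float) -> float:
    """Marker band divided by its loading-control band."""
    if loading_intensity <= 0:
        raise ValueError(
            f"loading-control intensity must be positive, got {loading_intensity}"
        )
    if marker_intensity < 0:
        raise ValueError(f"marker intensity must be >= 0, got {marker_intensity}")
    return marker_intensity / loading_intensity


def call_marker(ratios: dict[str, float], threshold: float) -> dict[str, bool]:
    """Positive iff normalised ratio is strictly above the threshold.

    Ties at the threshold call negative, which makes threshold sweeps
    deterministic and the positive count non-increasing in the threshold.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return {sample: ratio > threshold for sample, ratio in ratios.items()}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity of a marker call set; None when undefined."""

    sensitivity: Fraction | None
    specificity: Fraction | None
    threshold: float
    n: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": None if self.sensitivity is None else float(self.sensitivity),
            "specificity": None if self.specificity is None else float(self.specificity),
            "threshold": self.threshold,
            "n": self.n,
        }


def diagnostic_summary(
    calls: dict[str, bool],
    truth: dict[str, str],
    threshold: float = 0.0,
) -> tuple[DiagnosticSummary, ConfusionMatrix]:
    """Confusion matrix and sensitivity/specificity of binary marker calls.

    ``truth`` maps each sample to 'case' or 'control'; a positive call on a
    case is a TP, on a control an FP. Every called sample must be labelled.
    """
    missing = sorted(set(calls) - set(truth))
    if missing:
        raise ValueError(f"no group label for sample(s): {missing}")
    bad = sorted(set(truth.values()) - {"case", "control"})
    if bad:
        raise ValueError(f"unknown group label(s): {bad}")
    tp = fp = tn = fn = 0
    for sample, positive in calls.items():
        is_case = truth[sample] == "case"
        if positive and is_case:
            tp += 1
        elif positive:
            fp += 1
        elif is_case:
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = Fraction(tp, tp + fn) if tp + fn else None
    spec = Fraction(tn, tn + fp) if tn + fp else None
    return DiagnosticSummary(sensitivity=sens, specificity=spec, threshold=threshold, n=cm.n), cm


def validate_marker(
    table: pd.DataFrame, threshold: float
) -> tuple[DiagnosticSummary, ConfusionMatrix, pd.DataFrame]:
    """End-to-end densitometry validation from a tidy table.

    The table follows the densitometry CSV schema (sample_id, group,
    marker_intensity, actin_intensity). Returns the summary, the confusion
    matrix, and the per-sample frame with normalised ratios and calls.
    """
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"densitometry table missing column(s): {', '.join(missing)}")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in densitometry table")
    ratios = {
        str(r.sample_id): normalize_band(r.marker_intensity, r.actin_intensity)
        for r in table.itertuples()
    }
    calls = call_marker(ratios, threshold)
    truth = dict(zip(table["sample_id"].astype(str), table["group"]))
    summary, cm = diagnostic_summary(calls, truth, threshold)
    out = table.copy()
    out["ratio"] = out["sample_id"].astype(str).map(ratios)
    out["positive"] = out["sample_id"].astype(str).map(calls)
    return summary, cm, out
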