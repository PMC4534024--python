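"""Percent-volume quantification of 2-D gel spots and differential filters.

Spots arrive pre-matched across gels (shared spot IDs); image processing is
upstream and out of scope. Each spot's raw volume is normalised to the
percentage of the total volume on its gel, making gels with different total
protein loads comparable. Two filters mirror the study design:

* fold change — ratio of group mean percent volumes, flagged when it departs
  from 1 by at least the threshold (default 1.5) in either direction;
* tumour specificity — detected on every case gel and on no control gel.

Fractions (A = epithelial cell debris, B = supernatant) are analysed
separately: each gel belongs to exactly one fraction and spot IDs are only
comparable within a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("case", "control")

SPOT_COLUMNS = ["gel_id", "group", "fraction", "spot_id", "protein", "raw_volume"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table missing column(s): {', '.join(missing)}")
    if (table["raw_volume"] < 0).any():
        raise ValueError("raw volumes must be >= 0")
    bad = set(table["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    dup = table.duplicated(subset=["gel_id", "spot_id"])
    if dup.any():
        pair = table.loc[dup.idxmax(), ["gel_id", "spot_id"]].tolist()
        raise ValueError(f"duplicate (gel, spot) measurement: {pair}")


def percent_volume(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``percent_volume`` column: 100 x volume / total volume per gel.

    Percent volumes on each gel sum to exactly 100 (up to float rounding),
    and are invariant to rescaling all raw volumes of a gel by any c > 0.
    """
    _check_table(table)
    totals = table.groupby("gel_id")["raw_volume"].transform("sum")
    zero = totals <= 0
    if zero.any():
        gel = table.loc[zero.idxmax(), "gel_id"]
        raise ValueError(f"gel {gel!r} has zero total volume; cannot normalise")
    out = table.copy()
    out["percent_volume"] = 100.0 * table["raw_volume"] / totals
    return out


@dataclass(frozen=True)
class DifferentialEntry:
    spot_id: str
    protein: str
    fraction: str
    case_mean: float
    control_mean: float
    fold_change: float  # case/control; inf or 0 when one side is absent
    differential: bool
    case_specific: bool
    control_specific: bool


def fold_change(
    case_mean: float, control_mean: float, threshold: float = 1.5
) -> tuple[float, bool, bool, bool]:
    """(FC, differential, case_specific, control_specific) for one spot.

    FC = case mean / control mean. A zero mean on one side yields a
    specificity flag instead of a finite fold change; the three flags are
    mutually exclusive.
    """
    if case_mean < 0 or control_mean < 0:
        raise ValueError("group mean percent volumes must be >= 0")
    if case_mean == 0 and control_mean == 0:
        raise ValueError("spot absent from both groups")
    if control_mean == 0:
        return float("inf"), False, True, False
    if case_mean == 0:
        return 0.0, False, False, True
    fc = case_mean / control_mean
    differential = fc >= threshold or fc <= 1.0 / threshold
    return fc, differential, False, False


def specificity_filter(
    presence: pd.DataFrame, design: dict[str, str]
) -> list[str]:
    """Proteins detected on every case gel and on no control gel.

    ``presence`` is a boolean matrix (rows: protein/spot, columns: gel IDs);
    ``design`` maps each gel ID to 'case' or 'control'. Returns row labels
    sorted lexicographically.
    """
    if not design:
        raise ValueError("empty gel design")
    unknown = set(design.values()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) in design: {sorted(unknown)}")
    case_gels = [g for g in presence.columns if design.get(g) == "case"]
    control_gels = [g for g in presence.columns if design.get(g) == "control"]
    mask = presence[case_gels].all(axis=1) & ~presence[control_gels].any(axis=1)
    return sorted(presence.index[mask].astype(str))


def presence_matrix(
    table: pd.DataFrame, presence_threshold: float = 0.0
) -> pd.DataFrame:
    """Spot x gel detection matrix: percent volume > threshold.

    The default threshold 0 counts any positive percent volume as detected —
    the convention under which an entirely absent control column means a
    tumour-specific protein.
    """
    if "percent_volume" not in table.columns:
        table = percent_volume(table)
    pv = table.pivot_table(
        index="spot_id", columns="gel_id", values="percent_volume", fill_value=0.0
    )
    return pv > presence_threshold


@dataclass(frozen=True)
class DifferentialSummary:
    n_spots: int
    n_differential: int
    n_case_specific: int
    n_control_specific: int


def differential_report(
    table: pd.DataFrame,
    fold_threshold: float = 1.5,
    presence_threshold: float = 0.0,
) -> tuple[pd.DataFrame, DifferentialSummary]:
    """Full differential analysis of a spot table, per fraction.

    The table must follow the spot CSV schema (gel_id, group, fraction,
    spot_id, protein, raw_volume); group and fraction memberships are read
    from it directly. A measurement missing for a gel is treated as volume 0
    on that gel. Group aggregation uses arithmetic means of percent volumes.

    Returns a tidy result frame (one row per fraction x spot) and summary
    counts. ``case_specific`` rows additionally satisfy the strict
    tumour-specificity rule (detected on all case gels, no control gel) when
    their control mean is zero and every case gel shows the spot; the
    specific flags from the fold-change rules are based on group means.
    """
    table = percent_volume(table)
    rows = []
    for fraction, sub in table.groupby("fraction", sort=True):
        gels = sub[["gel_id", "group"]].drop_duplicates()
        n_by_group = gels.groupby("group")["gel_id"].nunique()
        for group in GROUPS:
            if n_by_group.get(group, 0) == 0:
                raise ValueError(f"fraction {fraction!r} has no {group} gels")
        pv = sub.pivot_table(
            index="spot_id", columns="gel_id", values="percent_volume", fill_value=0.0
        )
        proteins = sub.groupby("spot_id")["protein"].first()
        design = dict(zip(gels["gel_id"], gels["group"]))
        case_cols = [g for g in pv.columns if design[g] == "case"]
        ctrl_cols = [g for g in pv.columns if design[g] == "control"]
        case_means = pv[case_cols].to_numpy().mean(axis=1)
        ctrl_means = pv[ctrl_cols].to_numpy().mean(axis=1)
        for spot, case_mean, ctrl_mean in zip(pv.index, case_means, ctrl_means):
            if case_mean == 0 and ctrl_mean == 0:
                continue  # spot absent from both groups in this fraction
            fc, diff, case_sp, ctrl_sp = fold_change(
                float(case_mean), float(ctrl_mean), fold_threshold
            )
            rows.append(
                DifferentialEntry(
                    spot_id=str(spot),
                    protein=str(proteins.get(spot, "")),
                    fraction=str(fraction),
                    case_mean=float(case_mean),
                    control_mean=float(ctrl_mean),
                    fold_change=fc,
                    differential=diff,
                    case_specific=case_sp,
                    control_specific=ctrl_sp,
                )
            )
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if frame.empty:
        frame = pd.DataFrame(
            columns=[
                "spot_id", "protein", "fraction", "case_mean", "control_mean",
                "fold_change", "differential", "case_specific", "control_specific",
            ]
        )
    summary = DifferentialSummary(
        n_spots=len(frame),
        n_differential=int(frame["differential"].sum()) if len(frame) else 0,
        n_case_specific=int(frame["case_specific"].sum()) if len(frame) else 0,
        n_control_specific=int(frame["control_specific"].sum()) if len(frame) else 0,
    )
    return frame, summary
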