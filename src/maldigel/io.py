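"""Readers and writers for the pipeline's text formats.

FASTA goes through Biopython; peak lists are two-column TSV (m/z, intensity)
or a minimal MGF dialect (BEGIN IONS / TITLE= / ion lines / END IONS); spot
and densitometry tables are strict-schema CSV. All parse errors name the file
and, where meaningful, the line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .calibration import PeakList, peak_list
from .diagnostics import DENSITOMETRY_COLUMNS
from .gel_diff import SPOT_COLUMNS


class ParseError(ValueError):
    pass


def parse_fasta(path) -> list[tuple[str, str]]:
    """(accession, sequence) records; the accession is the first header word."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ParseError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        records.append((acc, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    from .synthetic import records_to_fasta

    Path(path).write_text(records_to_fasta(records, width=width))


def parse_peaklist_tsv(path, spot_id: str | None = None, calibrated: bool = False) -> PeakList:
    """Two-column TSV peak list: m/z <TAB> intensity, '#' comments allowed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    pairs = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            mz, intensity = float(fields[0]), float(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from None
        if mz <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive m/z {mz}")
        if intensity < 0:
            raise ParseError(f"{path}:{lineno}: negative intensity {intensity}")
        pairs.append((mz, intensity))
    return peak_list(spot_id or path.stem, pairs, calibrated=calibrated)


def write_peaklist_tsv(peaks: PeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spot: {peaks.spot_id}\n")
        for p in peaks.peaks:
            fh.write(f"{p.mz:.5f}\t{p.intensity:.5f}\n")


def parse_mgf(path, calibrated: bool = False) -> list[PeakList]:
    """Minimal MGF dialect: BEGIN IONS / TITLE=... / 'm/z intensity' / END IONS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MGF file not found: {path}")
    out: list[PeakList] = []
    title = None
    pairs: list[tuple[float, float]] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if pairs is not None:
                raise ParseError(f"{path}:{lineno}: nested BEGIN IONS")
            pairs, title = [], None
        elif line == "END IONS":
            if pairs is None:
                raise ParseError(f"{path}:{lineno}: END IONS without BEGIN IONS")
            out.append(peak_list(title or f"scan{len(out) + 1}", pairs, calibrated=calibrated))
            pairs = None
        elif pairs is None:
            raise ParseError(f"{path}:{lineno}: data outside BEGIN/END IONS block")
        elif line.startswith("TITLE="):
            title = line[len("TITLE=") :]
        elif "=" in line and not line[0].isdigit():
            continue  # tolerate other KEY=VALUE headers
        else:
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'm/z intensity'")
            try:
                mz, intensity = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric ion line") from None
            if mz <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive m/z {mz}")
            pairs.append((mz, intensity))
    if pairs is not None:
        raise ParseError(f"{path}: unterminated BEGIN IONS block")
    if not out:
        raise ParseError(f"{path}: no spectra found")
    return out


def write_mgf(peak_lists: list[PeakList], path) -> None:
    with open(path, "w") as fh:
        for peaks in peak_lists:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={peaks.spot_id}\n")
            for p in peaks.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.5f}\n")
            fh.write("END IONS\n")


def _parse_csv(path, required: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s): {', '.join(missing)}")
    return table


def parse_spot_csv(path) -> pd.DataFrame:
    """Spot table CSV: gel_id,group,fraction,spot_id,protein,raw_volume."""
    table = _parse_csv(path, SPOT_COLUMNS, "spot")
    bad = table["raw_volume"] < 0
    if bad.any():
        # +2: one for the header, one for 1-based line numbers
        raise ParseError(f"{path}:{int(bad.idxmax()) + 2}: negative raw volume")
    return table


def parse_densitometry_csv(path) -> pd.DataFrame:
    """Densitometry CSV: sample_id,group,marker_intensity,actin_intensity."""
    table = _parse_csv(path, DENSITOMETRY_COLUMNS, "densitometry")
    bad = table["actin_intensity"] <= 0
    if bad.any():
        raise ParseError(f"{path}:{int(bad.idxmax()) + 2}: non-positive loading control")
    return table
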