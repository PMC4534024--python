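"""Synthetic study inputs: protein databases, MALDI peak lists, spot tables.

No raw spectra or gel images accompany the study this pipeline models, so
these generators stand in for them, with ground truth returned alongside
every output:

* random protein databases (uniform residue usage) in place of a sequence
  repository;
* fingerprint spectra built from a chosen protein's tryptic digest, with
  peptide dropout, multiplicative (ppm-scaled) mass error, uniform noise
  peaks, optional spiked calibration standards, and affine calibration drift;
* two-group (5 case / 5 control by default) spot-volume tables with
  log-normal biological noise, planted fold changes and dropout, 800 spots
  per gel by default — the scale of the modelled gels.

Every generator is a pure function of its spec including the mandatory seed:
identical inputs give byte-identical serialised outputs. The printed
identification tables of the modelled study (Tables 1 and 2) ship as CSV
fixtures and load through ``table1_fixture``/``table2_fixture``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import chem
from .calibration import DEFAULT_STANDARDS, PeakList, peak_list
from .digestion import TRYPSIN, DigestParams, digest

RESIDUES = sorted(chem.STANDARD_RESIDUES)


def simulate_protein_db(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 400),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random protein records with unique accessions SYN0001, SYN0002, ...

    Sequences are uniform over the 20 standard residues; lengths uniform on
    the inclusive range.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(RESIDUES, size=length))
        records.append((f"SYN{i + 1:04d}", seq))
    return records


def records_to_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    """Serialise records as wrapped FASTA text (deterministic bytes)."""
    lines = []
    for acc, seq in records:
        lines.append(f">{acc}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Acquisition model for one synthetic fingerprint spectrum.

    ``drift`` (a, b) is expressed in calibration orientation: a peptide with
    true m/z m appears at (m - b) / a, so that fitting the internal
    calibration model recovers exactly (a, b).
    """

    accession: str
    seed: int
    detection_prob: float = 0.8
    mass_error_ppm_sd: float = 10.0
    n_noise_peaks: int = 5
    noise_mz_range: tuple[float, float] = (500.0, 4000.0)
    drift: tuple[float, float] = (1.0, 0.0)
    include_standards: bool = False

    def __post_init__(self):
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.mass_error_ppm_sd < 0 or self.n_noise_peaks < 0:
            raise ValueError("mass_error_ppm_sd and n_noise_peaks must be >= 0")


@dataclass(frozen=True)
class SpectrumTruth:
    accession: str
    true_peptides: tuple[tuple[str, float], ...]  # (sequence, true [M+H]+)
    n_noise: int
    n_standards: int


def simulate_pmf_spectrum(
    db: list[tuple[str, str]],
    spec: SpectrumSimSpec,
    digest_params: DigestParams = DigestParams(),
) -> tuple[PeakList, SpectrumTruth]:
    """One fingerprint peak list from a database protein, plus ground truth.

    The source protein's tryptic peptides are retained i.i.d. with the
    detection probability, rendered as [M+H]+, perturbed by Gaussian
    relative mass error, mixed with uniform noise peaks (and the calibration
    standards if requested), and finally passed through the drift map.
    """
    seqs = dict(db)
    if spec.accession not in seqs:
        raise ValueError(f"accession {spec.accession!r} not in database")
    rng = np.random.default_rng(spec.seed)
    peptides = digest(seqs[spec.accession], TRYPSIN, digest_params)
    # distinct masses: repeated tryptic products yield one peak
    uniq: dict[float, str] = {}
    for p in peptides:
        mz = chem.mz_from_mass(p.mass, 1)
        uniq.setdefault(round(mz, 9), p.sequence)

    kept: list[tuple[str, float]] = []
    raw: list[tuple[float, float]] = []
    for mz, seq in sorted(uniq.items()):
        if rng.random() <= spec.detection_prob:
            observed = mz * (1.0 + rng.normal(0.0, spec.mass_error_ppm_sd * 1e-6))
            kept.append((seq, mz))
            raw.append((observed, float(rng.uniform(10.0, 100.0))))

    lo, hi = spec.noise_mz_range
    for _ in range(spec.n_noise_peaks):
        raw.append((float(rng.uniform(lo, hi)), float(rng.uniform(1.0, 20.0))))

    n_std = 0
    if spec.include_standards:
        for std in DEFAULT_STANDARDS:
            raw.append((std.reference_mz(), 200.0))
            n_std += 1

    a, b = spec.drift
    drifted = [((mz - b) / a, inten) for mz, inten in raw]
    peaks = peak_list(f"sim:{spec.accession}:{spec.seed}", drifted, calibrated=False)
    truth = SpectrumTruth(
        accession=spec.accession,
        true_peptides=tuple(kept),
        n_noise=spec.n_noise_peaks,
        n_standards=n_std,
    )
    return peaks, truth


def simulate_fragment_spectrum(
    peptide: str,
    seed: int,
    deletion_prob: float = 0.0,
) -> tuple[PeakList, int]:
    """b/y fragment ladder of a peptide with ions deleted i.i.d.

    Returns the fragment peak list and the number of surviving ladder ions.
    """
    rng = np.random.default_rng(seed)
    ladder = chem.fragment_ions(peptide, "b") + chem.fragment_ions(peptide, "y")
    kept = [mz for mz in ladder if rng.random() >= deletion_prob]
    return peak_list(f"frag:{peptide}", [(mz, 50.0) for mz in kept], calibrated=True), len(kept)


@dataclass(frozen=True)
class SpotSimSpec:
    """Two-group spot-volume experiment with planted effects.

    ``planted`` maps spot IDs to the fold by which their volume is multiplied
    on case gels. ``dropout_prob`` zeroes any single measurement i.i.d.
    Defaults follow the modelled study: 5 case and 5 control gels, 800 spots
    per gel.
    """

    seed: int
    n_case: int = 5
    n_control: int = 5
    n_spots: int = 800
    planted: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    dropout_prob: float = 0.0
    fraction: str = "B"

    def __post_init__(self):
        if self.n_case < 1 or self.n_control < 1 or self.n_spots < 1:
            raise ValueError("gel and spot counts must be >= 1")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        bad = set(self.planted) - set(self.spot_ids())
        if bad:
            raise ValueError(f"planted spot(s) outside the spot set: {sorted(bad)}")

    def spot_ids(self) -> list[str]:
        return [f"spot{i + 1:04d}" for i in range(self.n_spots)]


def simulate_spot_tables(
    spec: SpotSimSpec,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, float]]:
    """Spot-volume table, gel design, and planted-effect truth.

    Baseline spot volumes are log-normal across spots (median 100 units,
    log-sd 1); each measurement multiplies the baseline by log-normal
    biological noise of the configured sd, by the planted fold on case gels,
    and is zeroed with the dropout probability.
    """
    rng = np.random.default_rng(spec.seed)
    spots = spec.spot_ids()
    baseline = 100.0 * np.exp(rng.normal(0.0, 1.0, size=spec.n_spots))
    gels = [(f"case{i + 1:02d}", "case") for i in range(spec.n_case)] + [
        (f"ctrl{i + 1:02d}", "control") for i in range(spec.n_control)
    ]
    rows = []
    for gel_id, group in gels:
        noise = (
            np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n_spots))
            if spec.noise_sd > 0
            else np.ones(spec.n_spots)
        )
        drop = (
            rng.random(spec.n_spots) < spec.dropout_prob
            if spec.dropout_prob > 0
            else np.zeros(spec.n_spots, dtype=bool)
        )
        for j, spot in enumerate(spots):
            vol = baseline[j] * noise[j]
            if group == "case" and spot in spec.planted:
                vol *= spec.planted[spot]
            if drop[j]:
                vol = 0.0
            rows.append(
                (gel_id, group, spec.fraction, spot, f"prot_{spot}", float(vol))
            )
    table = pd.DataFrame(
        rows, columns=["gel_id", "group", "fraction", "spot_id", "protein", "raw_volume"]
    )
    design = dict(gels)
    return table, design, dict(spec.planted)


def spot_table_to_csv(table: pd.DataFrame) -> str:
    """Serialise a spot table deterministically (fixed column order, 6 d.p.)."""
    out = table.copy()
    out["raw_volume"] = out["raw_volume"].map(lambda v: f"{v:.6f}")
    return out.to_csv(index=False, lineterminator="\n")


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("maldigel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def table1_fixture() -> pd.DataFrame:
    """The study's printed identification list (fraction, accession, matched
    count, score annotation, protein name), transcribed row-for-row.

    Duplicate gene products appearing on multiple rows are preserved as
    printed; deduplicate explicitly if needed (``drop_duplicates`` on the
    accession column).
    """
    return _load_fixture("table1.csv")


def table2_fixture() -> pd.DataFrame:
    """The study's printed tumour-specific protein list: per-protein spot
    counts in controls (all zero) and cases, transcribed row-for-row."""
    return _load_fixture("table2.csv")


def table2_detection_matrix() -> tuple[pd.DataFrame, dict[str, str]]:
    """Render the tumour-specific table as a presence matrix + design.

    The printed table aggregates detection per group (spot counts over all
    control gels and all case gels), so the matrix has one column per group
    aggregate; presence = count > 0.
    """
    t2 = table2_fixture()
    presence = pd.DataFrame(
        {
            "control_gels": t2["control_count"] > 0,
            "case_gels": t2["case_count"] > 0,
        },
        index=t2["accession"],
    )
    design = {"control_gels": "control", "case_gels": "case"}
    return presence, design
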