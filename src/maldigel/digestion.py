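"""Rule-based in-silico protease digestion and a mass-indexed peptide store.

The digest emulates the wet-lab tryptic digestion of gel spots: cleavage
C-terminal to K or R, suppressed before proline, with a configurable number
of missed cleavages. Digesting a whole FASTA database yields a mass-sorted
index supporting O(log N) tolerance-window queries, the lookup structure a
peptide-mass-fingerprint search runs against.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from . import chem


@dataclass(frozen=True)
class CleavageRule:
    """Cleave after any residue in ``cleave_after`` unless the next residue
    is in ``suppress_before``."""

    name: str
    cleave_after: frozenset[str]
    suppress_before: frozenset[str]

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError("cleave_after set must be non-empty")
        if self.cleave_after & self.suppress_before:
            raise ValueError("cleave_after and suppress_before must be disjoint")

    def cleavage_sites(self, sequence: str) -> list[int]:
        """0-based positions i such that the bond after sequence[i] is cut."""
        n = len(sequence)
        return [
            i
            for i in range(n - 1)
            if sequence[i] in self.cleave_after
            and sequence[i + 1] not in self.suppress_before
        ]


TRYPSIN = CleavageRule(
    name="trypsin",
    cleave_after=frozenset("KR"),
    suppress_before=frozenset("P"),
)


@dataclass(frozen=True)
class DigestParams:
    """Digest filters: missed cleavages and peptide length/mass windows.

    Defaults: one missed cleavage (the conventional fingerprint-search
    setting) and a 500-4000 Da window (typical MALDI reflector range).
    """

    max_missed_cleavages: int = 1
    min_length: int = 1
    max_length: int = 100
    min_mass: float = 500.0
    max_mass: float = 4000.0

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass > max_mass")


#: unbounded parameters, useful for reconstruction checks and tiny examples
UNBOUNDED = DigestParams(
    max_missed_cleavages=0, min_length=1, max_length=10**9, min_mass=0.0, max_mass=float("inf")
)


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A digest product with provenance into its parent protein.

    Coordinates are 1-based inclusive residue positions in the parent.
    """

    accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    mass: float  # neutral monoisotopic, Da


def digest(
    sequence: str,
    rule: CleavageRule = TRYPSIN,
    params: DigestParams = DigestParams(),
    accession: str = "",
) -> list[TheoreticalPeptide]:
    """All peptides of one protein under a cleavage rule and digest filters.

    Deterministic order: by start position, then by peptide length.
    """
    chem.validate_sequence(sequence)
    sites = rule.cleavage_sites(sequence)
    # fragment boundaries: [start, end) over 0-based indices
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for m in range(params.max_missed_cleavages + 1):
            j = i + m + 1
            if j > nfrag:
                break
            start, end = bounds[i], bounds[j]
            pep = sequence[start:end]
            if not (params.min_length <= len(pep) <= params.max_length):
                continue
            mass = chem.peptide_mass(pep)
            if not (params.min_mass <= mass <= params.max_mass):
                continue
            peptides.append(
                TheoreticalPeptide(
                    accession=accession,
                    start=start + 1,
                    end=end,
                    sequence=pep,
                    missed_cleavages=m,
                    mass=mass,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


@dataclass
class PeptideIndex:
    """Mass-sorted index of theoretical peptides from a protein database.

    Supports O(log N) mass-window range queries via binary search on the
    sorted mass array.
    """

    peptides: list[TheoreticalPeptide]
    protein_lengths: dict[str, int]
    _masses: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.peptides = sorted(self.peptides, key=lambda p: (p.mass, p.accession, p.start, p.end))
        self._masses = np.array([p.mass for p in self.peptides], dtype=float)

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    def range_query(self, lo: float, hi: float) -> list[TheoreticalPeptide]:
        """All peptides with lo <= mass <= hi."""
        i = bisect.bisect_left(self._masses, lo)
        j = bisect.bisect_right(self._masses, hi)
        return self.peptides[i:j]


def digest_database(
    records: list[tuple[str, str]],
    rule: CleavageRule = TRYPSIN,
    params: DigestParams = DigestParams(),
) -> PeptideIndex:
    """Digest every (accession, sequence) record into one mass-sorted index."""
    seen: set[str] = set()
    peptides: list[TheoreticalPeptide] = []
    lengths: dict[str, int] = {}
    for accession, sequence in records:
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r}")
        seen.add(accession)
        lengths[accession] = len(sequence)
        peptides.extend(digest(sequence, rule, params, accession=accession))
    return PeptideIndex(peptides=peptides, protein_lengths=lengths)


def digest_to_tsv(peptides: list[TheoreticalPeptide], path) -> None:
    """Export a digest as TSV (coordinates are 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive residue positions\n")
        fh.write("accession\tstart\tend\tsequence\tmissed_cleavages\tmass\n")
        for p in peptides:
            fh.write(
                f"{p.accession}\t{p.start}\t{p.end}\t{p.sequence}\t"
                f"{p.missed_cleavages}\t{p.mass:.5f}\n"
            )
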