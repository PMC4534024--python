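"""Peptide mass fingerprinting: tolerance matching, scoring, confirmation.

Observed (calibrated) peptide masses are matched against a theoretical digest
index at a *relative* tolerance — the default of 2.5e-5 (0.0025% of the
theoretical mass) reproduces the acquisition-matched settings this pipeline
models. Candidates are ranked by a binomial-tail chance score: the
probability that a protein unrelated to the spectrum would collect at least
as many peak matches by chance, given how many of its peptides fall in the
observed mass range.

Ambiguous identifications can be confirmed in tandem mode by counting how
much of a candidate peptide's b/y fragment ladder is present in a fragment
peak list (`fragment_confirm`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from . import chem
from .calibration import PeakList
from .digestion import (
    TRYPSIN,
    CleavageRule,
    DigestParams,
    PeptideIndex,
    TheoreticalPeptide,
    digest_database,
)

SCHEMA_VERSION = "1"


class UncalibratedPeaksError(ValueError):
    """Search refused on an uncalibrated peak list without explicit override."""


@dataclass(frozen=True)
class SearchParams:
    """Fingerprint search settings.

    ``relative_tolerance`` is a fraction of the theoretical mass (default
    2.5e-5, i.e. 0.0025%). ``mass_convention`` chooses whether observed
    values are compared to neutral masses M or to [M+H]+ ions; MALDI peak
    lists report protonated ions, so 'protonated' is the default, but both
    conventions are supported because either may appear in exported lists.
    """

    relative_tolerance: float = 2.5e-5
    mass_convention: Literal["neutral", "protonated"] = "protonated"
    mass_type: Literal["monoisotopic", "average"] = "monoisotopic"
    min_matched: int = 1

    def __post_init__(self):
        if self.relative_tolerance <= 0:
            raise ValueError("relative_tolerance must be positive")
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")

    def theoretical_value(self, peptide_mass: float) -> float:
        """Render a neutral theoretical mass in the configured convention."""
        if self.mass_convention == "protonated":
            return chem.mz_from_mass(peptide_mass, charge=1)
        return peptide_mass

    def to_dict(self) -> dict:
        return {
            "relative_tolerance": self.relative_tolerance,
            "mass_convention": self.mass_convention,
            "mass_type": self.mass_type,
            "min_matched": self.min_matched,
        }


@dataclass(frozen=True)
class PeakMatch:
    peak_index: int
    observed: float
    peptide: TheoreticalPeptide
    error: float  # observed - theoretical, Da, in the search convention


def match_peaks(
    peaks: PeakList,
    index: PeptideIndex,
    params: SearchParams = SearchParams(),
    allow_uncalibrated: bool = False,
) -> list[PeakMatch]:
    """All (peak, theoretical peptide) pairs within the relative tolerance.

    A peak may match several peptides; all matches are retained — candidate
    scoring operates on per-protein tallies, not on a greedy assignment.
    """
    if not peaks.calibrated and not allow_uncalibrated:
        raise UncalibratedPeaksError(
            f"peak list {peaks.spot_id!r} is not calibrated; "
            "pass allow_uncalibrated=True to search anyway"
        )
    tol = params.relative_tolerance
    offset = chem.PROTON_MASS if params.mass_convention == "protonated" else 0.0
    matches: list[PeakMatch] = []
    for i, peak in enumerate(peaks.peaks):
        obs = peak.mz
        # |obs - t| <= tol * t  <=>  t in [obs/(1+tol), obs/(1-tol)]
        lo = obs / (1.0 + tol) - offset
        hi = obs / (1.0 - tol) - offset
        for pep in index.range_query(lo, hi):
            theo = pep.mass + offset
            if abs(obs - theo) <= tol * theo:
                matches.append(
                    PeakMatch(peak_index=i, observed=obs, peptide=pep, error=obs - theo)
                )
    return matches


@dataclass(frozen=True)
class CandidateScore:
    """Per-protein tally of a fingerprint search."""

    accession: str
    matched_peaks: int
    matched_peptides: tuple[tuple[str, float], ...]  # (sequence, mass error Da)
    coverage: float
    chance_score: float  # -log10 binomial tail probability

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "matched_peaks": self.matched_peaks,
            "matched_peptides": [
                {"sequence": s, "error_da": round(e, 5)} for s, e in self.matched_peptides
            ],
            "coverage": round(self.coverage, 5),
            "chance_score": round(self.chance_score, 5),
        }


def _chance_score(k: int, n: int, p: float) -> float:
    """-log10 P(X >= k), X ~ Binomial(n, p)."""
    p = min(max(p, 1e-300), 1.0 - 1e-12)
    tail = stats.binom.sf(k - 1, n, p)
    return float(-np.log10(max(tail, 1e-300)))


def score_candidates(
    matches: list[PeakMatch],
    index: PeptideIndex,
    peaks: PeakList,
    params: SearchParams = SearchParams(),
) -> list[CandidateScore]:
    """Rank candidate proteins by chance of their match tally.

    The null model: each of the n observed peaks independently matches a
    given candidate with probability p = (number of the candidate's peptides
    inside the observed mass range x mean tolerance-window width) / (width of
    the observed mass range). The chance score is -log10 of the binomial
    upper tail P(X >= k) at the candidate's matched-peak count k. Ranking is
    total and deterministic: score desc, matched count desc, coverage desc,
    accession asc.
    """
    n = len(peaks)
    if n == 0 or not matches:
        return []
    obs = peaks.mz
    mz_lo, mz_hi = float(obs.min()), float(obs.max())
    offset = chem.PROTON_MASS if params.mass_convention == "protonated" else 0.0
    tol = params.relative_tolerance

    by_acc: dict[str, list[PeakMatch]] = {}
    for m in matches:
        by_acc.setdefault(m.peptide.accession, []).append(m)

    # candidate peptides whose rendered value falls in the observed range
    theo_vals = index.masses + offset
    in_range = (theo_vals >= mz_lo) & (theo_vals <= mz_hi)
    acc_in_range: dict[str, list[float]] = {}
    for pep, ok in zip(index.peptides, in_range):
        if ok:
            acc_in_range.setdefault(pep.accession, []).append(pep.mass + offset)

    span = mz_hi - mz_lo
    scores = []
    for acc, ms in by_acc.items():
        k = len({m.peak_index for m in ms})  # a peak counts once per candidate
        vals = acc_in_range.get(acc, [])
        if span > 0 and vals:
            # distinct masses only: repeated peptides must not inflate p
            uniq = sorted(set(round(v, 9) for v in vals))
            mean_window = float(np.mean([2.0 * tol * v for v in uniq]))
            p = min(1.0, len(uniq) * mean_window / span)
        else:
            p = 1.0  # degenerate range: no evidence against chance
        score = _chance_score(k, n, p)

        length = index.protein_lengths.get(acc, 0)
        covered: set[int] = set()
        seen_pep: set[tuple[str, float]] = set()
        peptide_list = []
        for m in sorted(ms, key=lambda m: (m.peptide.start, m.peptide.end)):
            covered.update(range(m.peptide.start, m.peptide.end + 1))
            key = (m.peptide.sequence, round(m.error, 9))
            if key not in seen_pep:
                seen_pep.add(key)
                peptide_list.append((m.peptide.sequence, m.error))
        coverage = len(covered) / length if length else 0.0

        scores.append(
            CandidateScore(
                accession=acc,
                matched_peaks=k,
                matched_peptides=tuple(peptide_list),
                coverage=coverage,
                chance_score=score,
            )
        )
    scores = [s for s in scores if s.matched_peaks >= params.min_matched]
    scores.sort(
        key=lambda s: (-s.chance_score, -s.matched_peaks, -s.coverage, s.accession)
    )
    return scores


@dataclass(frozen=True)
class PMFResult:
    """Ranked fingerprint identifications for one spot."""

    spot_id: str
    candidates: tuple[CandidateScore, ...]
    params: SearchParams
    unmatched_peaks: int
    schema_version: str = SCHEMA_VERSION

    @property
    def top(self) -> CandidateScore | None:
        return self.candidates[0] if self.candidates else None

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "spot_id": self.spot_id,
            "params": self.params.to_dict(),
            "unmatched_peaks": self.unmatched_peaks,
            "candidates": [c.to_dict() for c in self.candidates],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def search(
    peaks: PeakList,
    records: list[tuple[str, str]] | PeptideIndex,
    params: SearchParams = SearchParams(),
    rule: CleavageRule = TRYPSIN,
    digest_params: DigestParams = DigestParams(),
    allow_uncalibrated: bool = False,
) -> PMFResult:
    """Digest -> match -> score, for one spot's peak list.

    ``records`` may be raw (accession, sequence) pairs or a pre-built
    PeptideIndex (reuse the index when searching many spots against the same
    database). The result is invariant to input peak order.
    """
    index = (
        records
        if isinstance(records, PeptideIndex)
        else digest_database(records, rule, digest_params)
    )
    matches = match_peaks(peaks, index, params, allow_uncalibrated=allow_uncalibrated)
    candidates = score_candidates(matches, index, peaks, params)
    matched_idx = {m.peak_index for m in matches}
    return PMFResult(
        spot_id=peaks.spot_id,
        candidates=tuple(candidates),
        params=params,
        unmatched_peaks=len(peaks) - len(matched_idx),
    )


@dataclass(frozen=True)
class FragmentConfirmation:
    peptide: str
    matched_ions: int
    total_ions: int

    @property
    def fraction(self) -> float:
        return self.matched_ions / self.total_ions


def fragment_confirm(
    peptide: str,
    fragment_peaks: PeakList,
    relative_tolerance: float = 2.5e-5,
) -> FragmentConfirmation:
    """Count b/y ladder ions of a candidate peptide found in a fragment list.

    An ion counts as matched when at least one fragment peak lies within the
    relative tolerance of its theoretical m/z. The fraction is over the full
    ladder of 2(n-1) ions for an n-residue peptide.
    """
    if len(peptide) < 2:
        raise ValueError("fragment confirmation requires a peptide of length >= 2")
    ladder = chem.fragment_ions(peptide, "b") + chem.fragment_ions(peptide, "y")
    obs = fragment_peaks.mz
    matched = 0
    for ion in ladder:
        if len(obs) and np.min(np.abs(obs - ion)) <= relative_tolerance * ion:
            matched += 1
    return FragmentConfirmation(
        peptide=peptide, matched_ions=matched, total_ions=len(ladder)
    )
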