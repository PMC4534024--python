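"""Fingerprint search: tolerance windows, brute-force parity, ranking, LIFT."""

import numpy as np
import pytest

from maldigel import chem
from maldigel.calibration import peak_list
from maldigel.digestion import digest_database
from maldigel.pmf import (
    SearchParams,
    UncalibratedPeaksError,
    _chance_score,
    fragment_confirm,
    match_peaks,
    score_candidates,
    search,
)
from maldigel.synthetic import (
    SpectrumSimSpec,
    simulate_fragment_spectrum,
    simulate_pmf_spectrum,
    simulate_protein_db,
)

PARAMS = SearchParams()  # 0.0025% relative tolerance, protonated, monoisotopic


def brute_force_matches(peaks, index, params):
    """Quadratic all-pairs oracle for the tolerance matcher."""
    offset = chem.PROTON_MASS if params.mass_convention == "protonated" else 0.0
    out = set()
    for i, p in enumerate(peaks.peaks):
        for j, t in enumerate(index.peptides):
            theo = t.mass + offset
            if abs(p.mz - theo) <= params.relative_tolerance * theo:
                out.add((i, j))
    return out


class TestMatchPeaks:
    def test_relative_window_arithmetic(self):
        """Peaks just inside the relative window match; just outside do not."""
        from maldigel.digestion import DigestParams

        params = SearchParams(mass_convention="neutral")
        db = [("P1", "ACDEFGHIK")]  # single tryptic peptide
        index = digest_database(db, params=DigestParams(min_mass=0, max_mass=1e9))
        m = index.peptides[0].mass
        half = params.relative_tolerance * m
        inside = peak_list("s", [(m + 0.99 * half, 1.0)], calibrated=True)
        outside = peak_list("s", [(m + 1.01 * half, 1.0)], calibrated=True)
        assert len(match_peaks(inside, index, params)) == 1
        assert len(match_peaks(outside, index, params)) == 0

    def test_stated_tolerance_example(self):
        # theoretical 2000.00: observed 2000.05 matches, 2000.06 does not
        tol = 2.5e-5
        assert abs(2000.05 - 2000.00) <= tol * 2000.00
        assert abs(2000.06 - 2000.00) > tol * 2000.00

    def test_empty_peak_list_gives_empty_matches(self, small_index):
        peaks = peak_list("empty", [], calibrated=True)
        assert match_peaks(peaks, small_index, PARAMS) == []

    def test_uncalibrated_requires_override(self, small_index):
        peaks = peak_list("raw", [(1000.0, 1.0)], calibrated=False)
        with pytest.raises(UncalibratedPeaksError):
            match_peaks(peaks, small_index, PARAMS)
        match_peaks(peaks, small_index, PARAMS, allow_uncalibrated=True)

    def test_window_scales_with_mass(self):
        assert PARAMS.relative_tolerance * 2000 == pytest.approx(
            2 * PARAMS.relative_tolerance * 1000
        )

    def test_equals_brute_force_all_pairs(self, small_db, small_index):
        """Indexed matcher vs the quadratic oracle on simulated spectra."""
        for seed in range(10):
            acc = f"SYN{(seed % 50) + 1:04d}"
            peaks, _ = simulate_pmf_spectrum(
                small_db, SpectrumSimSpec(accession=acc, seed=seed)
            )
            peaks = peak_list(peaks.spot_id, [(p.mz, p.intensity) for p in peaks.peaks], calibrated=True)
            got = {
                (m.peak_index, small_index.peptides.index(m.peptide))
                for m in match_peaks(peaks, small_index, PARAMS)
            }
            assert got == brute_force_matches(peaks, small_index, PARAMS)


class TestScoring:
    def test_zero_noise_spectrum_ranks_source_first(self, small_db):
        spec = SpectrumSimSpec(
            accession="SYN0005", seed=1, detection_prob=1.0,
            mass_error_ppm_sd=0.0, n_noise_peaks=0,
        )
        peaks, truth = simulate_pmf_spectrum(small_db, spec)
        peaks = peak_list(peaks.spot_id, [(p.mz, p.intensity) for p in peaks.peaks], calibrated=True)
        result = search(peaks, small_db)
        assert result.top.accession == "SYN0005"
        assert result.top.matched_peaks == len(truth.true_peptides)

    def test_chance_score_increases_with_matches(self):
        scores = [_chance_score(k, 20, 0.01) for k in range(1, 10)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_candidate_without_matches_absent(self, small_db, small_index):
        peaks = peak_list("s", [(750.4, 1.0)], calibrated=True)
        matches = match_peaks(peaks, small_index, PARAMS)
        cands = score_candidates(matches, small_index, peaks, PARAMS)
        accs_with_match = {m.peptide.accession for m in matches}
        assert {c.accession for c in cands} <= accs_with_match

    def test_coverage_bounded(self, small_db):
        peaks, _ = simulate_pmf_spectrum(
            small_db, SpectrumSimSpec(accession="SYN0010", seed=2)
        )
        peaks = peak_list(peaks.spot_id, [(p.mz, p.intensity) for p in peaks.peaks], calibrated=True)
        for c in search(peaks, small_db).candidates:
            assert 0.0 <= c.coverage <= 1.0
            assert c.matched_peaks <= len(peaks)


class TestSearch:
    def test_peak_order_invariance(self, small_db):
        peaks, _ = simulate_pmf_spectrum(
            small_db, SpectrumSimSpec(accession="SYN0020", seed=5)
        )
        pairs = [(p.mz, p.intensity) for p in peaks.peaks]
        fwd = search(peak_list("s", pairs, calibrated=True), small_db)
        rev = search(peak_list("s", pairs[::-1], calibrated=True), small_db)
        assert fwd.to_json() == rev.to_json()

    def test_determinism_byte_identical(self, small_db):
        peaks, _ = simulate_pmf_spectrum(
            small_db, SpectrumSimSpec(accession="SYN0021", seed=6)
        )
        pairs = [(p.mz, p.intensity) for p in peaks.peaks]
        a = search(peak_list("s", pairs, calibrated=True), small_db).to_json()
        b = search(peak_list("s", pairs, calibrated=True), small_db).to_json()
        assert a == b

    def test_absent_protein_never_reported(self, small_db):
        peaks, _ = simulate_pmf_spectrum(
            small_db, SpectrumSimSpec(accession="SYN0001", seed=7)
        )
        pairs = [(p.mz, p.intensity) for p in peaks.peaks]
        others = [r for r in small_db if r[0] != "SYN0001"]
        result = search(peak_list("s", pairs, calibrated=True), others)
        assert all(c.accession != "SYN0001" for c in result.candidates)

    def test_recovery_degrades_with_noise(self, small_db, small_index):
        """Rank-1 rate is non-increasing as noise peaks are added."""
        rates = []
        for n_noise in (0, 10, 60):
            hits = 0
            for seed in range(30):
                acc = f"SYN{(seed % 50) + 1:04d}"
                peaks, _ = simulate_pmf_spectrum(
                    small_db,
                    SpectrumSimSpec(
                        accession=acc, seed=1000 + seed, detection_prob=0.5,
                        mass_error_ppm_sd=10.0, n_noise_peaks=n_noise,
                    ),
                )
                pairs = [(p.mz, p.intensity) for p in peaks.peaks]
                res = search(peak_list("s", pairs, calibrated=True), small_index)
                if res.top and res.top.accession == acc:
                    hits += 1
            rates.append(hits / 30)
        assert rates[0] >= rates[1] >= rates[2]


class TestFragmentConfirm:
    def test_exact_ladder_fully_matched(self):
        frag, _ = simulate_fragment_spectrum("ACDEFGHIK", seed=1, deletion_prob=0.0)
        conf = fragment_confirm("ACDEFGHIK", frag)
        assert conf.fraction == 1.0
        assert conf.total_ions == 2 * (len("ACDEFGHIK") - 1)

    def test_empty_fragment_list(self):
        conf = fragment_confirm("ACDEFGHIK", peak_list("f", [], calibrated=True))
        assert conf.matched_ions == 0

    def test_deleted_ions_lower_fraction_proportionally(self):
        """Seeded 20% deletion -> matched fraction equals the survival count."""
        pep = "ACDEFGHIKLMNPQRSTVWY"
        frag, n_kept = simulate_fragment_spectrum(pep, seed=12, deletion_prob=0.2)
        conf = fragment_confirm(pep, frag)
        assert conf.matched_ions == n_kept
        # binomial sampling error around the 80% survival rate
        assert conf.fraction == pytest.approx(0.8, abs=0.25)

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            fragment_confirm("K", peak_list("f", [], calibrated=True))
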