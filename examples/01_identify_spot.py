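"""Identify one gel spot by peptide mass fingerprinting.

Builds a small synthetic protein database, simulates a MALDI peak list from
one protein (peptide dropout, 10 ppm mass error, noise peaks, spiked
calibration standards, mass-axis drift), internally calibrates it, and
searches it against the database.
"""

from maldigel import SpectrumSimSpec, calibrate, search, simulate_pmf_spectrum, simulate_protein_db

db = simulate_protein_db(50, length_range=(100, 400), seed=42)

spec = SpectrumSimSpec(
    accession="SYN0013",
    seed=7,
    detection_prob=0.8,        # each tryptic peptide observed with p = 0.8
    mass_error_ppm_sd=10.0,    # relative mass error, ppm
    n_noise_peaks=5,
    drift=(1.00003, 0.25),     # affine mass-axis drift to be calibrated away
    include_standards=True,    # des-Arg1-bradykinin + ACTH 18-39 spiked in
)
raw, truth = simulate_pmf_spectrum(db, spec)
print(f"simulated spectrum: {len(raw)} peaks "
      f"({len(truth.true_peptides)} true peptides, {truth.n_noise} noise, "
      f"{truth.n_standards} standards)")

peaks, model = calibrate(raw)
print(f"internal calibration: a = {model.a:.8f}, b = {model.b:.5f} Da "
      f"(true drift a = {spec.drift[0]}, b = {spec.drift[1]})")

result = search(peaks, db)  # 0.0025% relative tolerance, [M+H]+, monoisotopic
top = result.top
print(f"\ntop candidate: {top.accession} (truth: {truth.accession})")
print(f"  matched peaks : {top.matched_peaks} / {len(peaks)}")
print(f"  coverage      : {top.coverage:.1%}")
print(f"  chance score  : {top.chance_score:.1f}  (-log10 P of >= k chance matches)")
# A chance score above ~5 means the match pattern is essentially impossible
# to produce by random mass coincidences in a database of this size.
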