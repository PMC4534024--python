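# maldigel

Peptide-mass-fingerprint identification and 2-D gel differential analysis
for body-fluid proteomics.

`maldigel` re-implements, as a tested and reusable library, the desk half of
a classic gel-based biomarker workflow on saliva: proteins separated on
two-dimensional gels are excised, digested with trypsin, and identified by
MALDI-TOF peptide mass fingerprinting (PMF); matched spots are quantified as
percent volumes and screened with fold-change and tumour-specificity filters;
candidate markers are finally validated as binary diagnostic calls on
Western-blot densitometry. It is aimed at anyone who needs a transparent,
scriptable version of that pipeline — for teaching, for method comparisons,
or for re-analysing legacy spot tables and peak lists that still live in
lab notebooks as CSV/TSV files.

## The method in brief

**Identification.** A protein database is digested in silico with the trypsin
rule (cleave after K or R, not before P, ≤ 1 missed cleavage by default). An
observed, internally calibrated peak *m* matches a theoretical peptide of
mass *m*ₜ (rendered as [M+H]⁺ by default) when

&nbsp;&nbsp;&nbsp;&nbsp;|m − mₜ| ≤ τ·mₜ,  with relative tolerance τ = 2.5×10⁻⁵ (0.0025%).

Candidates are ranked by a binomial chance score. For a candidate with *k*
matched peaks among *n* observed peaks, and *q* of its theoretical peptides
inside the observed mass range [m_min, m_max],

&nbsp;&nbsp;&nbsp;&nbsp;p̂ = q·w̄ / (m_max − m_min),  w̄ = mean window width 2τ·mₜ,
&nbsp;&nbsp;&nbsp;&nbsp;score = −log₁₀ P(X ≥ k),  X ~ Binomial(n, p̂),

i.e. the score is the number of orders of magnitude by which the match tally
beats random mass coincidence. Internal calibration fits
`reference = a·observed + b` to two spiked standards (des-Arg1-bradykinin and
the ACTH 18–39 clip, reference masses computed from sequence). Ambiguous
candidates can be confirmed by the matched fraction of their b/y fragment
ladder in a tandem spectrum.

**Quantification.** On each gel, a spot's percent volume is
100·v / Σv(gel). A spot is *differential* when the ratio of group-mean
percent volumes departs from 1 by at least 1.5-fold in either direction, and
*tumour-specific* when it is detected on every case gel and on no control
gel. Marker validation computes sensitivity TP/(TP+FN) and specificity
TN/(TN+FP) from actin-normalised band intensities thresholded with a strict
`>`.

Because no raw spectra or gel images accompany the modelled study, the
`synthetic` module generates all of these inputs with known ground truth
(seeded, byte-reproducible), and the study's printed identification tables
ship as CSV fixtures.

## Worked example

```bash
python examples/01_identify_spot.py
```

```
simulated spectrum: 50 peaks (43 true peptides, 5 noise, 2 standards)
internal calibration: a = 1.00003000, b = 0.25000 Da (true drift a = 1.00003, b = 0.25)

top candidate: SYN0013 (truth: SYN0013)
  matched peaks : 43 / 50
  coverage      : 59.4%
  chance score  : 119.9  (-log10 P of >= k chance matches)
```

The calibration recovered the injected mass-axis drift exactly (two noiseless
standards determine the affine map), the source protein ranks first, 43 of 50
peaks are explained by its digest, and the chance score says a random
50-protein database would produce this tally with probability 10⁻¹²⁰ — an
unambiguous identification. The other examples cover differential gel
analysis (`02`), marker validation (`03`), the packaged identification
tables and the tumour-specificity filter (`04`), and fragment-ion
confirmation (`05`); each prints the numbers it computes and a line on what
they mean.

A thin CLI mirrors the stages (`maldigel digest|calibrate|search|diffspots|
validate|simulate|run`); run `maldigel --help`.

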