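# Methods

This note records the models, parameter choices and numerical conventions
behind `maldigel`, and what the synthetic generators do and do not emulate.

## Mass arithmetic (`chem`)

All masses derive from elemental tables pinned in one source file
(monoisotopic: CODATA 2018 / AME2020; average: IUPAC 2021 conventional
atomic weights), so residue masses, peptide masses, [M+H]⁺ values and
fragment ladders are bit-reproducible and auditable against the elemental
source (`chem.export_constants` dumps everything as JSON). A neutral peptide
mass is the sum of its residue (post-condensation) masses plus one water;
an ion's m/z is (M + z·1.007276466621)/z.

Residues are unmodified by default: the digestion protocol modelled here
includes no cysteine alkylation step. A per-residue fixed-modification
offset (`fixed_modifications={"C": 57.02146}` for carbamidomethyl, say) is
accepted as configuration. Only the b/y fragment series at charge 1 are
produced — the ions a MALDI LIFT tandem spectrum is read for; a/c/x/z series,
neutral losses and isotope envelopes are out of scope.

## Digestion (`digestion`)

Trypsin is the default rule: cleave C-terminal to K or R unless the next
residue is P. Defaults where the modelled protocol is silent, chosen as the
conventional PMF settings: **max missed cleavages = 1**, **peptide mass
window 500–4000 Da** (typical MALDI reflector range), no length bounds in
practice, and no N-terminal methionine stripping (a documented switch could
be added; the generators and the search use the same digest parameters, so
the choice cancels in all closed-loop experiments). The database digest is
held in a mass-sorted array; tolerance windows are answered by binary search
(O(log N) per query) and verified in tests against a linear-scan oracle.

## Internal calibration (`calibration`)

The calibration family is affine: `calibrated = a·observed + b`. Rationale:
the modelled acquisition spikes exactly two standards into each sample
(des-Arg1-bradykinin, PPGFSPFR, [M+H]⁺ ≈ 904.4676; and the ACTH 18–39 clip,
RPVKVYPNGAEDESAEAFPLEF, [M+H]⁺ ≈ 2465.1983), and two points determine an
affine map exactly. Reference masses are computed from sequence via `chem`
rather than hard-coded. Standards are located by nearest-peak matching
within a coarse window of **1.0 Da** (pre-calibration MALDI error is far
below inter-peptide spacing at these masses); equidistant ties break to the
lower m/z. The fit is ordinary least squares (exact with two pairs); fitted
slopes outside (0.9, 1.1) are rejected as physically implausible. Applying a
model never changes peak count or intensities. Fewer than two matched
standards raises `CalibrationError` — calibration is never silently skipped;
the pipeline downgrades this to a warning and searches uncalibrated only
because the search itself demands an explicit override for uncalibrated
input. Quadratic/TOF-physics calibration is out of scope.

Drift in the spectrum generator is parameterised in calibration orientation
(a true m/z m appears at (m − b)/a) so the fitted model recovers exactly the
(a, b) that was injected — the round-trip contract the tests assert.

## Fingerprint search (`pmf`)

Matching is relative: |m − mₜ| ≤ τ·mₜ with τ = 2.5×10⁻⁵ by default (0.0025%
of the theoretical mass), so the absolute window scales linearly with mass.
The mass convention is **protonated** by default ([M+H]⁺ is what a MALDI
peak list reports); neutral mode is available because exported lists are
ambiguous in the wild. All peak↔peptide matches are retained — no greedy
assignment — since scoring operates on per-candidate tallies; within a
candidate, a peak counts once toward the matched count and repeated peptide
masses count once toward the null probability, preventing trivially inflated
scores.

The chance score is a binomial tail: with n observed peaks and a candidate
whose q distinct theoretical masses lie inside the observed range of width W,
each peak is taken to match the candidate independently with
p̂ = q·w̄/W (w̄ = mean window width 2τ·mₜ over those masses), and the score is
−log₁₀ P(X ≥ k) for the candidate's k matched peaks. Degenerate ranges
(single peak, W = 0) set p̂ = 1, i.e. no evidence against chance. The tail is
floored at 10⁻³⁰⁰ before the log. Ranking is a total order: score desc,
matched count desc, coverage desc, accession asc — identical inputs give
byte-identical serialised results. The score is a reproducibility device for
this pipeline, not a re-implementation of any published scoring service, and
the score annotations in the packaged fixture tables are treated as opaque.

Fragment confirmation counts the b/y ladder ions of a named candidate
peptide that appear in a fragment peak list within the same relative
tolerance; the reported fraction is over the full ladder of 2(n−1) ions.
Full tandem database search and target–decoy FDR are out of scope: the LIFT
step here confirms a candidate, as in the modelled workflow.

## Gel differential analysis (`gel_diff`)

Spots arrive pre-matched across gels by shared IDs (image registration is
upstream software's job; this artifact consumes spot tables). Percent volume
is 100·v/Σv per gel; per-gel sums are asserted to 100 ± 1e-9 throughout.
Group aggregation uses arithmetic means of percent volumes (medians would be
a one-line configuration; means are the default because the filters operate
on two small balanced groups). Fractions — A (epithelial cell debris) and B
(supernatant) — are analysed separately, since each gel belongs to one
fraction.

Filters: fold change FC = mean(case)/mean(control), flagged when FC ≥ 1.5 or
FC ≤ 1/1.5 (the threshold at which the modelled study considered a
difference reproducibly detectable); a zero mean on one side yields a
case-/control-specific flag instead of a finite FC, and the three flags are
mutually exclusive. The strict tumour-specificity rule — detected on **all**
case gels and **no** control gel, presence meaning percent volume > 0 —
is a separate operation on a presence matrix, because the packaged
tumour-specific table records exactly that pattern (every control count 0).
Whether the original 1.5-fold rule was applied to raw or percent volumes is
not recorded; percent volumes are scale-invariant per gel, so the two agree
whenever the same spot sets are compared, and percent volumes are used here.
No formal statistical test is applied — the filters are threshold rules by
design.

A frozen property bound: under a null simulation (5+5 gels, 800 spots,
log-normal noise sd 0.2, no effects), the fraction of spots crossing the
1.5-fold line was measured over 400 independent replicates (max 0.00625,
mean 0.0015); the suite asserts ≤ 0.0125, the observed maximum plus margin,
frozen before being wired into the tests.

## Diagnostics (`diagnostics`)

Ratios are marker/loading-control (loading must be positive); calls are
strict `>` at the threshold so ties are negative and threshold sweeps are
monotone and deterministic. Sensitivity and specificity are computed in
exact rational arithmetic (`Fraction`) and reported as absent — not 0 —
when their denominator is empty. The threshold itself is a required user
parameter: the modelled study reports headline sensitivity/specificity but
not per-sample intensities or its positivity criterion, so those headline
numbers are context, not a reproduction target; the module is instead
verified by exhaustive enumeration against direct confusion counting.

## Synthetic data (`synthetic`)

Generators are pure functions of (spec, seed); serialised outputs are
byte-identical under the same seed.

* **Protein databases**: uniform random sequences over the 20 residues,
  lengths uniform on 100–400 by default. Real proteomes have biased residue
  usage and homologous families; uniform sequences make chance matching
  *harder* than reality in one way (no near-duplicate proteins) and easier
  in another (no compositional bias), so recovery rates measured here
  characterise the machinery, not any real database.
* **Fingerprint spectra**: the source protein's digest rendered as [M+H]⁺,
  peptides retained i.i.d. with detection probability 0.8 by default, masses
  perturbed multiplicatively with Gaussian sd 10 ppm (matching the relative
  tolerance regime), 5 uniform noise peaks on 500–4000 Da, optional spiked
  standards, then affine drift. Peak intensities are arbitrary uniform draws
  — PMF scoring here does not use intensity. No isotope envelopes, peak
  shapes, detector saturation or chemical noise structure.
* **Spot tables**: per-spot baselines log-normal (median 100, log-sd 1),
  per-measurement log-normal noise (sd 0.2 default), planted folds applied
  in case gels only, i.i.d. dropout zeroing single measurements. Defaults
  5 case + 5 control gels and 800 spots per gel — the scale of the modelled
  experiment. Real gels have spatially correlated noise, saturation and
  mis-matching; passing recovery tests on these tables shows the filters are
  implemented correctly, not that the thresholds are optimal for real gels.
* **Fixtures**: the study's two printed identification tables transcribed
  row-for-row (148 and 25 rows). Duplicate gene-product rows in the first
  table are preserved verbatim so the transcription stays auditable;
  deduplication is the caller's explicit step. The matched-count and score
  annotations are stored but never interpreted.

## Numerical conventions

Digest-export coordinates are 1-based inclusive. Masses print at 5 decimals
(1e-5 Da, below every tolerance used). Reports serialise with sorted keys;
reruns of identical configs are byte-identical. Everything is
single-threaded: determinism outranks speed at this scale (the full test
suite runs in seconds).

## Known limitations

Peak picking from raw spectra, gel image processing, PTM/semi-tryptic
search, FDR estimation, ROC machinery and pathway analysis are all out of
scope. The chance score's independence assumption between peaks is the usual
fingerprint-scoring simplification; it is calibrated only in the sense that
the binomial tail is exact under the stated null.
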