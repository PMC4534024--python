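"""Confirm an ambiguous candidate peptide with tandem fragment ions.

When the fingerprint alone is ambiguous, a candidate peptide can be checked
against a fragment spectrum: the fraction of its theoretical b/y ladder found
in the observed fragment list quantifies the confirmation.
"""

from maldigel import fragment_confirm
from maldigel.synthetic import simulate_fragment_spectrum

peptide = "LVNELTEFAK"  # a tryptic peptide to confirm

full, _ = simulate_fragment_spectrum(peptide, seed=1, deletion_prob=0.0)
partial, kept = simulate_fragment_spectrum(peptide, seed=2, deletion_prob=0.3)

for name, spectrum in [("complete ladder", full), ("30% ions missing", partial)]:
    conf = fragment_confirm(peptide, spectrum)
    print(f"{name}: {conf.matched_ions}/{conf.total_ions} b/y ions matched "
          f"({conf.fraction:.0%})")
# 2(n-1) ladder ions exist for an n-residue peptide; a high matched fraction
# confirms the candidate, a near-zero one rejects it.
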