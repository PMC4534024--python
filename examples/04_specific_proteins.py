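"""Tumour-specificity filter on the packaged identification tables.

Loads the transcribed identification lists that ship with the package and
applies the strict presence/absence rule: a protein is tumour-specific when
it is detected in the case material and never in controls.
"""

from maldigel import specificity_filter, table1_fixture, table2_fixture
from maldigel.synthetic import table2_detection_matrix

t1 = table1_fixture()
print(f"identification list: {len(t1)} rows "
      f"(fractions A = cell debris, B = supernatant, A+B = both)")
print(t1["fraction"].value_counts().to_string())

t2 = table2_fixture()
presence, design = table2_detection_matrix()
specific = specificity_filter(presence, design)
print(f"\ntumour-specific proteins (all-case / no-control): {len(specific)}")
top5 = t2.nlargest(5, "case_count")[["accession", "case_count", "full_name"]]
for row in top5.itertuples():
    name = row.full_name.split(" (")[0]
    print(f"  {row.accession:24s} {row.case_count:3d} case spots  {name}")
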