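"""Binary-marker validation from Western-blot densitometry.

Normalises marker band intensities to the beta-actin loading control, calls
samples positive above a threshold, and reports sensitivity/specificity with
the confusion matrix.
"""

import pandas as pd

from maldigel import validate_marker

table = pd.DataFrame(
    {
        "sample_id": [f"s{i + 1}" for i in range(10)],
        "group": ["case"] * 5 + ["control"] * 5,
        "marker_intensity": [8.2, 6.1, 5.0, 0.9, 7.7, 0.6, 0.3, 2.6, 0.5, 0.4],
        "actin_intensity": [4.0, 3.1, 2.4, 2.1, 3.8, 2.0, 1.8, 2.2, 2.1, 1.9],
    }
)

summary, cm, frame = validate_marker(table, threshold=1.0)
print(frame[["sample_id", "group", "ratio", "positive"]].to_string(index=False))
print(f"\nconfusion matrix: TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn}")
print(f"sensitivity = {float(summary.sensitivity):.0%}   "
      f"specificity = {float(summary.specificity):.0%}   (n = {summary.n})")
# Sensitivity is the fraction of cases called positive; specificity the
# fraction of controls called negative. Calls use a strict '>' so a sweep
# over thresholds is monotone and deterministic.
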