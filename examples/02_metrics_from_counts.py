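"""Diagnostic metrics from confusion counts.

Feeds the two published confusion matrices through the metric layer: the
case-control evaluation (84 of 97 PHPT patients detected, 12 of 96 controls
false-alarmed at Ca/P >= 2.71) and the laboratory-database evaluation (441 of
590 PHPT-like records detected, 1762 of 19,857 controls false-alarmed).
"""

from caphos import ConfusionCounts, metrics

for name, counts in (
    ("case-control", ConfusionCounts(tp=84, fn=13, fp=12, tn=84)),
    ("lab-database", ConfusionCounts(tp=441, fn=149, fp=1762, tn=18095)),
):
    m = metrics(counts)
    raw = m.raw()
    ints = m.rounded()
    print(f"{name}: n = {counts.total}")
    for key in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        print(f"  {key:>11}: {raw[key]:6.2f}%  (reported {ints[key]:.0f})")
# Sensitivity/specificity describe case recovery and control rejection; PPV
# and NPV fold in the prevalence, which is why they collapse in the
# low-prevalence database despite similar sensitivity.
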