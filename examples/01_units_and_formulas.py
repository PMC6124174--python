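"""Clinical-chemistry formulas: unit conversion, corrected calcium, MDRD GFR.

Converts the Ca/P diagnostic cutoff and the calcium/phosphorous reference
limits between SI (mmol/L) and conventional (mg/dL) units, corrects total
calcium for albumin, and estimates GFR from creatinine.
"""

from caphos import Sex, UnitSystem, convert_ratio_cutoff, convert_units, corrected_calcium, mdrd_gfr
from caphos.biochem import round_half_away

cutoff_si = 2.71
cutoff_cu = convert_ratio_cutoff(cutoff_si)
print(f"Ca/P cutoff {cutoff_si} (SI) -> {cutoff_cu:.4f} -> reported {round_half_away(cutoff_cu, 1)} (CU)")
# The same ratio rescales by 4.008/3.097 because Ca and P carry different
# molar-mass conversion factors.

for analyte, lo, hi in (("ca", 2.12, 2.65), ("p", 0.81, 1.65)):
    lo_cu = convert_units(lo, analyte, UnitSystem.SI, UnitSystem.CU)
    hi_cu = convert_units(hi, analyte, UnitSystem.SI, UnitSystem.CU)
    print(f"{analyte}: reference {lo}-{hi} mmol/L = {round_half_away(lo_cu, 1)}-{round_half_away(hi_cu, 1)} mg/dL")

# Albumin-corrected calcium: +0.02 mmol/L per g/L of albumin below 40.
print(f"corrected Ca(2.40, albumin 30 g/L) = {corrected_calcium(2.40, 30.0):.2f} mmol/L")

# MDRD GFR at creatinine 88.4 umol/L (= 1.0 mg/dL), age 40.
for sex in (Sex.MALE, Sex.FEMALE):
    print(f"MDRD GFR (creatinine 88.4 umol/L, age 40, {sex.value}): "
          f"{mdrd_gfr(88.4, 40, sex):.1f} mL/min/1.73m2")
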