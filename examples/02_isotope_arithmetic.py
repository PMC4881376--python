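"""Isotope bookkeeping: delta conversions, calibration and label recipes.

Walks through the arithmetic used around the pipeline: converting EA-IRMS
delta values of a spore calibration standard into raw ratios, correcting
instrumental fractionation, and planning an isotope-labeling recipe by
mass balance.
"""

import pandas as pd

import isophene as ip
from isophene.isotope import CalibrationStandard, MixRecipe, labeled_amount_fraction

# The spore standard, measured independently by EA-IRMS:
R13 = ip.ratio_from_delta(-21.86, ip.REFERENCE.R_VPDB_13C)
R15 = ip.ratio_from_delta(7.94, ip.REFERENCE.R_AIR_15N)
print(f"spore standard: delta13C = -21.86 permil -> 13C/12C = {R13:.5f}")
print(f"                delta15N =  +7.94 permil -> 15N/14N = {R15:.5f}")
print(f"natural 13C abundance: {100 * ip.atom_fraction_from_ratio(R13):.3f} at.%\n")

# Correcting a measured sample ratio against the standard: if the instrument
# reports the spores at 0.01050 instead of their true 0.01099, every sample
# 13C/12C is scaled by the same factor.
std = CalibrationStandard(measured={"r13C": 0.01050}, true={"r13C": R13})
sample = pd.DataFrame({"r13C": [0.0500], "r33S": [0.0080]})
corrected = ip.fractionation_correct(sample, std)
print(f"fractionation correction: 0.0500 -> {corrected['r13C'].iloc[0]:.5f} "
      "(33S/32S passes through uncorrected)\n")

# Planning a ~10 at.% 15N ammonium amendment from a 98 at.% stock:
x = labeled_amount_fraction(F_unlabeled=0.00364, F_labeled=0.98, F_target=0.10)
F = ip.mass_balance_mix(MixRecipe(0.00364, 1 - x, 0.98, x))
print(f"label recipe: {100 * x:.2f}% of the ammonium amount from the 98 at.% "
      f"stock gives {100 * F:.1f} at.% 15N in the incubation")
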