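"""Fit a gallic-acid standard curve and convert a sample absorbance.

Builds the blank-corrected standard series of a Folin-Ciocalteu plate,
fits the calibration line, and inverts a sample reading back to the
undiluted-extract concentration scale.
"""

from phytoscreen import absorbance_to_concentration, fit_standard_curve

# (concentration mg/L, blank-corrected absorbance AU) triplicate means
points = [(0, 0.002), (100, 0.201), (200, 0.399), (300, 0.602), (400, 0.799), (500, 1.001)]

curve = fit_standard_curve(points, analyte="gallic_acid", blank_mean=0.040)
print(f"slope     {curve.slope:.6f} AU per mg/L")
print(f"intercept {curve.intercept:.6f} AU")
print(f"r^2       {curve.r_squared:.6f}")

# a sample well read 0.462 AU above blank, extract diluted 1:17 in the assay
conc = absorbance_to_concentration(curve, 0.462, dilution_factor=17.0)
print(f"sample    {conc:.1f} mg GAE/L (undiluted extract)")

# The slope says one mg/L of gallic-acid equivalents adds ~0.002 AU at
# 750 nm; the sample's 0.462 AU therefore corresponds to ~231 mg/L in the
# well, i.e. ~3900 mg GAE/L of undiluted extract after the 1:17 dilution.
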