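"""Overlay Enceladus ocean condition intervals on fitted response curves.

Fits an envelope model to synthetic methanogen-like occurrences, extracts
the per-variable response curves, and intersects each with the published
interval for Enceladus' ocean (salinity 5-40 PSU, ascending currents
0.01-0.05 m/s, the 0-50 degC ambient-to-vent temperature gradient, and up
to 2500 uM dissolved silica).
"""

import enceladus_niche as en

stack = en.generate_layers(en.SimConfig(shape=(80, 80), seed=5))
truth = en.default_true_envelope(stack)
occ = en.generate_occurrences(stack, truth, n=500, seed=6)
occ_set = en.clean_and_split(occ, stack, seed=7)
model = en.fit_bioclim(occ_set, stack)

curves = [en.response_curve(model, v) for v in model.variables]
report = en.overlay(curves, en.default_enceladus_conditions())
print(report.to_table())
print()
print("'compatible' means the whole Enceladus interval lies inside the "
      "Earth-suitable range; 'partially compatible' means only part of it "
      "does; 'incompatible' means the two ranges do not meet at all. "
      "max suitability is the best envelope score attainable anywhere in "
      "the Enceladus interval.")
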