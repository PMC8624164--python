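"""Fit and evaluate a Bioclim envelope model on a synthetic virtual species.

Generates a four-variable benthic world (temperature, salinity, current
velocity, silicate), samples occurrences from a known environmental
envelope, fits the envelope model on a 75% training split and scores the
prediction with the partial-ROC AUC ratio on the held-out 25%.
"""

import numpy as np

import enceladus_niche as en
from enceladus_niche.model_eval import extract_test_suitability, partial_roc

stack = en.generate_layers(en.SimConfig(shape=(100, 100), seed=42))
truth = en.default_true_envelope(stack)
occ = en.generate_occurrences(stack, truth, n=800, noise=0.0, seed=43)

retained = en.correlation_filter(stack, seed=1)
occ_set = en.clean_and_split(occ, stack, train_frac=0.75, seed=2)
model = en.fit_bioclim(occ_set, stack, variables=retained)
suitability = en.predict_suitability(model, stack)

counts = occ_set.counts()
print(f"occurrences: {counts['raw']} raw -> {counts['cleaned']} unique cells "
      f"({counts['train']} train / {counts['test']} test)")
print(f"retained variables after collinearity filter: {retained}")
for var in model.variables:
    lo, hi = model.limits(var)
    tlo, thi = truth.limits[var]
    print(f"  {var:>16}: fitted [{lo:8.3f}, {hi:8.3f}]  "
          f"truth [{tlo:8.3f}, {thi:8.3f}]")

test_suit = extract_test_suitability(suitability, stack, occ_set)
roc = partial_roc(suitability, test_suit, nodata=stack.nodata,
                  n_boot=1000, seed=3)
print(f"partial ROC: mean AUC ratio = {roc.mean_auc_ratio:.4f}, "
      f"p = {roc.p_value:.3g}")
print("A ratio above 1 means the model concentrates held-out occurrences "
      "into less area than a random ranking.  With noiseless sampling the "
      "fitted limits always sit inside the generating envelope (occurrences "
      "can only narrow it); sampling noise would widen them instead.")
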