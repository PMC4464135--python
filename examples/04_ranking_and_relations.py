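"""Sensitivity ranking and functional-relation detection.

Ranks parameters by orthogonalized sensitivity (collinear columns stay
unranked) and detects the planted theta1*theta2 = c relation from
co-optimized parameter samples with ACE/bootstrap scoring.
"""

import numpy as np
import pandas as pd

from kinid import compute_sensitivities, mota_detect, rank_parameters
from kinid.fixtures import make_model

m = make_model("product_ni")
grid = np.linspace(0.1, 4.0, 40)
Z = compute_sensitivities(m, m.theta_true, grid)
ranking = rank_parameters(Z, threshold=0.004)
print(f"ranked:   {ranking.ranked}")
print(f"unranked: {ranking.unranked}")
print("The two sensitivity columns are exactly collinear (both equal")
print("-theta1*theta2*t after scaling), so only one parameter is rankable.")

rng = np.random.default_rng(0)
th1 = np.exp(rng.uniform(np.log(0.1), np.log(10), 80))
th2 = 1.0 / th1 * (1 + 0.01 * rng.standard_normal(80))
samples = pd.DataFrame({"theta1": th1, "theta2": th2})
relations = mota_detect(samples, seed=1)
for r in relations:
    print(f"relation: {r.response} ~ {r.predictors}, "
          f"r2 = {r.r2_mean:.3f} +- {r.r2_std:.3f}")
print("Bootstrap ACE finds the hyperbolic coupling with r2 ~ 1, even though")
print("the raw Pearson correlation of the pair is far from -1.")
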