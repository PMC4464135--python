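"""Joint state/parameter estimation with the constrained square-root UKF.

Generates one noisy realization of the Michaelis–Menten benchmark and
recovers (Vmax, Km) from random starting values between 0 and 1, using
multi-start annealed filtering sweeps with chi-square selection.
"""

import numpy as np

from kinid import multistart_estimate
from kinid.fixtures import generate_experiment1_style

bundle = generate_experiment1_style(seed=1)
model = bundle["model"]

result = multistart_estimate(
    model, bundle["noisy"], n_starts=5, triage_sweeps=3, polish_sweeps=6,
    seed=42, r_fn=bundle["r_fn"],
)

truth = dict(zip(model.param_names, model.theta_true))
print(f"true parameters:      {truth}")
print(f"estimated parameters: "
      f"{ {k: round(v, 5) for k, v in result.final_theta.items()} }")
for p in model.param_names:
    rel = abs(result.final_theta[p] - truth[p]) / truth[p]
    print(f"  {p}: relative error {100 * rel:.1f}%")
print(f"selection merit (chi2): {result.merit:.1f} over {len(bundle['noisy'])} samples")
print("Errors of a few percent are typical at 20% measurement noise.")
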