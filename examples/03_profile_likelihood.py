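"""Profile-likelihood identifiability analysis.

Profiles both parameters of the structurally degenerate decay model
dx/dt = -theta1*theta2*x (only the product is constrained by data) and,
for contrast, both parameters of the identifiable Michaelis–Menten chain.
"""

import numpy as np

from kinid import NoiseModel, apply_noise, simulate
from kinid.benchmarks import _fit_and_profile, _subsample
from kinid.fixtures import generate_experiment1_style, make_model, proportional_r_fn

print("-- structurally non-identifiable pair --")
m = make_model("product_ni")
grid = np.linspace(0.1, 4.0, 40)
clean = simulate(m, m.theta_true, grid)
noisy = apply_noise(clean, NoiseModel(kind="multiplicative", seed=0))
fit, profiles = _fit_and_profile(m, noisy, proportional_r_fn(0.2))
for name, traj in profiles.items():
    print(f"  {name}: class={traj.klass}, CI={tuple(round(c, 3) for c in traj.ci)}")
print(f"  fitted product theta1*theta2 = "
      f"{fit.final_theta['theta1'] * fit.final_theta['theta2']:.3f} (true 1.0)")
print("  Flat profiles in both directions: any factor pair on the hyperbola")
print("  fits equally well, so each factor alone is structurally NI.")

print("-- identifiable Michaelis-Menten pair --")
b = generate_experiment1_style(seed=0)
data = _subsample(b["noisy"], 4)
fit, profiles = _fit_and_profile(b["model"], data, b["r_fn"])
for name, traj in profiles.items():
    print(f"  {name}: class={traj.klass}, CI={tuple(round(c, 5) for c in traj.ci)}")
print("  Both profiles cross the 3.84 threshold on both sides: finite")
print("  likelihood-based confidence intervals, parameters identifiable.")
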