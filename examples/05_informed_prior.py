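"""Unique estimation of a non-identifiable model via an informed prior.

Repeats estimation of the structurally degenerate pair with (a) uninformed
random initialization and (b) a rank-based informed prior centered on a
first-pass estimate, and compares the spread of the repeated estimates.
"""

from kinid.benchmarks import informed_prior_contrast

out = informed_prior_contrast(n_seeds=10, base_seed=0)
print("spread of repeated estimates (std over 10 runs):")
print(f"  uninformed: {out['uninformed_std'].round(4)}")
print(f"  informed:   {out['informed_std'].round(4)}")
print(f"  ratio informed/uninformed: "
      f"{ {k: round(v, 3) for k, v in out['std_ratio'].items()} }")
print(f"trajectory deviation of informed estimates vs clean data, in units")
print(f"of the noise scale: {out['max_traj_dev_over_noise']:.3f} (<= 2 means")
print("the dynamics are reproduced within twice the measurement noise).")
print("The prior pins one direction of the flat likelihood ridge, so every")
print("repetition lands on the same parameter pair: a unique estimate.")
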