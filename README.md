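# kinid

Joint state/parameter estimation and identifiability analysis for kinetic
ODE models of biochemical networks.

Kinetic models drive their dynamics through ODEs whose parameters (maximal
rates, binding constants, Hill coefficients) are rarely measurable
directly; they must be inferred from noisy, incomplete time-course data of
species concentrations.  Two things routinely go wrong: optimizers get
stuck or scatter across repeated runs, and many parameters are
**non-identifiable** — different parameter sets fit the data equally well,
so no point estimate is trustworthy.  `kinid` addresses both with a single
workflow aimed at systems-biology modellers:

1. **Estimation** by a constrained square-root unscented Kalman filter
   (CSUKF).  The model `ẋ = F(x, θ, t) + w`, `y = H(x, θ, t) + v` is
   augmented with `θ̇ = 0`, so parameters become hidden states estimated
   jointly with the trajectory.  Sigma points are propagated through the
   numerically integrated dynamics; the estimation covariance is carried
   as its Cholesky factor `S` (P = S·Sᵀ, updated by QR and rank-1
   up/downdates) which keeps it positive definite, and box constraints
   `L ≤ x ≤ U` are enforced by pulling violating sigma points back along
   their ray to the feasible set and re-weighting.
2. **Identifiability analysis**:
   * orthogonal sensitivity ranking from the scaled sensitivity matrix
     `z_ij = (∂x_i/∂θ_j)·(θ̂_j/x̂_i)`, with a residual-norm stop threshold
     (unrankable parameters are flagged);
   * per-parameter profile likelihoods — χ²(ψ) re-optimized over the
     nuisance parameters at each fixed ψ — classified against the χ²
     quantile thresholds Δ(α, m) (3.84 pointwise, 95%): crossings on both
     sides → identifiable with interval [σ⁻, σ⁺]; one side → practically
     non-identifiable; flat → structurally non-identifiable;
   * linear correlations read off the filter's square-root covariance, and
     non-linear functional relations found by alternating conditional
     expectations (ACE) with bootstrap scoring (the MOTA scheme);
   * remedy suggestions (measure the highest-ranked member of a relation,
     fix unrankable parameters, add data where state trajectories vary
     most along a profile).
3. **Informed priors** — when non-identifiability cannot be resolved by
   new data, a rank-based prior (tight standard deviations for influential
   parameters, loose for the rest) or a previous estimation phase's
   mean/covariance makes the Bayesian filter return a *unique* estimate
   that still reproduces the observed dynamics.

Models can be defined in Python (a right-hand side plus an observation
map) or imported from SBML; time series are plain CSV.

## Worked example

Estimate the two parameters of a Michaelis–Menten conversion S → P from
234 samples with 20% multiplicative noise, then profile them
(`examples/02_estimate_parameters.py`, `examples/03_profile_likelihood.py`):

```text
true parameters:      {'Vmax': 0.002, 'Km': 0.3}
estimated parameters: {'Vmax': 0.00204, 'Km': 0.3063}
  Vmax: relative error 2.0%
  Km: relative error 2.1%

  Vmax: class=identifiable, CI=(0.00189, 0.00229)
  Km:   class=identifiable, CI=(0.26345, 0.36955)
```

Both parameters are recovered within ~2% and their 95% likelihood-based
confidence intervals cover the truth.  Contrast the structurally
degenerate model `ẋ = −θ₁θ₂x`, where only the product is constrained:

```text
  theta1: class=structural, CI=(-inf, inf)
  theta2: class=structural, CI=(-inf, inf)
  fitted product theta1*theta2 = 0.999 (true 1.0)

relation: theta1 ~ ('theta2',), r2 = 0.998 +- 0.002
```

The profiles are flat (any pair on the hyperbola fits), MOTA names the
functional relation, and a rank-based informed prior then collapses the
spread of repeated estimates by ~40× while the fitted dynamics stay within
a hundredth of the noise scale (`examples/05_informed_prior.py`):

```text
  uninformed: [0.1601 0.2366]
  informed:   [0.0041 0.0058]
  ratio informed/uninformed: {'theta1': 0.026, 'theta2': 0.024}
```

Each script in `examples/` is a short, self-contained narrative:
simulation + noise, estimation, profiling, ranking + relations, informed
priors, and the full orchestrated workflow (also available as the `kinid`
command-line tool: `kinid run --config config.yaml`).

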