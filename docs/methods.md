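# Methods

## State-space formulation

A kinetic model is the continuous system

    ẋ = F(x, θ, t) + w,   x(t₀) = x(0)
    y = H(x, θ, t) + v

with states x (concentrations, mM), parameters θ, process noise
w ~ N(0, Q) and measurement noise v ~ N(0, R).  For joint estimation the
parameters are appended to the state with zero dynamics (θ̇ = 0), giving
the augmented vector x_aug = [x | θ_est] ordered states-first.  Between
measurement instants the state block is advanced by numerical integration
of F with the parameter block held fixed (LSODA, stiff-capable; default
rtol 1e−8 / atol 1e−10 for simulation, relaxed to 1e−6 / 1e−9 inside
filtering loops where integration error is far below measurement noise).
Time grids are measurement instants; the initial state is not a
measurement, so the [0, 2340] s grid at Δt = 10 s carries 234 samples.
A grid that explicitly contains t = 0 (as in the gene-network bundle,
t = 0…20 s) is honoured: the filter skips the time update for a
measurement coinciding with the current time.

## The constrained square-root unscented Kalman filter

The filter approximates the posterior p(x(k) | y(1..k)) by propagating
2n+1 sigma points {x̂, x̂ ± √(n+λ)·S·e_i} through the discretized
dynamics.  Numerical stability comes from never forming the covariance
P: its Cholesky factor S (P = S·Sᵀ) is propagated directly via QR
factorizations of weighted deviation stacks and rank-1 Cholesky
up/downdates.  A downdate that would lose positive definiteness raises an
error rather than being silently patched — the square-root form exists
precisely to prevent this, so a failure indicates a real modelling
problem (e.g. a collapsed innovation covariance).

**Unscented-transform scalars.** α = 1, β = 2, κ = max(0, 3−n).  The
classical κ = 3−n gives fourth-order Gaussian moment matching but makes
the central mean-weight negative for n > 3; combined with the constraint
re-weighting below, boundary contact could then drive the weight sum
non-positive.  Flooring κ at 0 keeps all mean weights non-negative.  All
three scalars are configurable.

**Box constraints.** Default bounds: states ≥ 0, parameters in
[1e−8, 100].  A sigma point outside the box is pulled back toward the
mean along its ray to the nearest feasible point; its mean and covariance
weights are multiplied by the applied scale factor and all weights are
renormalized so Σ W^m = 1 (the same constant applied to W^c).  With no
active constraint this reduces exactly to the standard square-root UKF.
Posterior and predicted means are clipped into the box.  Note that active
constraints legitimately shift the predicted parameter mean (probability
mass outside the box is removed), so the "θ̇ = 0 ⇒ predicted θ mean
unchanged" identity holds only while the parameter sigma points stay
interior.

**Noise covariances.** Q is diagonal over the augmented vector: a small
state block (the synthetic data are generated from deterministic
dynamics) and a parameter block that acts as the filter's learning rate.
R may be constant or rebuilt per step; for signal-proportional noise
(std = c·y) the per-step R is diag((c·ŷ⁻(k))²) with ŷ⁻ the *predicted*
observation — using the noisy measurement itself in the weights biases
the estimate upward by several percent (verified on the benchmark), while
the predicted observation is the filter's estimate of the clean signal.

**Estimation driver.** A single filtering sweep is a Bayesian pass, not
an optimizer, so the package converges point estimates by *iterated
filtering*: repeated sweeps that restart at the previous sweep's final
parameter mean while shrinking both the initial parameter uncertainty and
the parameter process noise geometrically (default decay 0.6 per sweep,
p₀ = 1.0 and q = 1e−3 on the log scale).  Estimated parameters are
optionally log-transformed (recommended and used by the benchmarks:
kinetic parameters span orders of magnitude, and multiplicative steps
with automatic positivity suit them).  `multistart_estimate` draws
several random initializations in (0, 1), triages them with a few sweeps,
scores each by the predict-only χ² merit and polishes the best — the
defaults (5 starts, 3 triage + 6 polish sweeps) recover the
Michaelis–Menten pair with ~2% median error at 20% noise.

**Merit.** χ² = Σ_k r(k)ᵀ R(k)⁻¹ r(k) over the innovations
r(k) = y(k) − ŷ⁻(k).  Two evaluations exist: the *filter form* uses the
filter's own innovations (what `estimate` reports), and the *predict-only
form* uses the noise-free trajectory at a candidate θ (`simulation_chi2`).
The predict-only form is a deterministic function of θ and is the one
used for model comparison, start selection and profiling — filter-form
residuals absorb parameter misfit through state corrections and would
flatten every profile.

## Profile-likelihood identifiability analysis

For each parameter ψ the profile is χ²(ψ) = min_η χ²(ψ, η): ψ is stepped
multiplicatively away from its optimum in both directions (default ×1.1,
halved toward 1 when Δχ² jumps by > 1 between points, doubled after 5
smooth points, max 200 steps per direction) and the nuisance parameters η
are re-optimized by short warm-started annealed CSUKF runs.  The
likelihood-ratio threshold Δ(α, m) is the α-quantile of χ²_m: 3.84
pointwise (m = 1) and, e.g., 21.03 simultaneous for m = 12 at 95%.
Confidence bounds are interpolated linearly in ψ at Δχ² = 3.84.

**Objective.** When the measurement variance follows the signal
(σ² = a² + (c·y_model)²), the profile objective is the full −2
log-likelihood *including* Σ log σ²(θ).  Dropping the log-determinant
(plain weighted least squares with model-based weights) systematically
rewards inflating the predicted signal; on the benchmark this biased the
optimum by +2–5% — comparable to the confidence-interval half-width — and
destroyed interval coverage.  With the log-det term, 95% intervals cover
the truth in ≈ 95% of replicates.

**Reference value.** The χ² reference for Δχ² is the minimum over the
fit *and* every explored profile point: the re-optimization may discover
a better optimum along the way, and likelihood-ratio geometry must be
anchored at the global minimum.

**Stopping and flatness.** Exploration stops on crossing the
simultaneous threshold, on reaching the ψ bounds, after the step budget,
when the profile has stayed within ε_flat = 0.1 χ² units over at least
one decade of ψ per direction (two decades overall — a 100-fold range),
or when a *nuisance* parameter pins at its box bound: past that point a
rising profile is a constraint artifact, not a likelihood feature.

**Classification.**  Crossings on both sides → identifiable; exactly one
side → practically non-identifiable (open side ±∞); no crossing and flat
→ structurally non-identifiable; no crossing but rising → practical
(rising too slowly to cross in the explored range).  Classification is a
pure function of the stored trajectory and can be recomputed from
serialized profiles.  Points whose re-optimization fails are flagged and
skipped; a trajectory with > 30% failures is marked unreliable.

**Measurement targeting.**  For practically non-identifiable parameters
the model is simulated at every profile point's full parameter vector;
the per-state, per-time envelope width (max − min) locates where new
measurements would most efficiently pin the parameter down.

## Sensitivity ranking

The scaled sensitivity z_ij = (∂x_i/∂θ_j)·(θ̂_j/x̂_i) is computed by
central finite differences on the simulated outputs (relative step 1e−6;
outputs are floored at 1e−12 in magnitude for the scaling), rows spanning
all (time, output) pairs.  Ranking is greedy orthogonalization: rank 1 is
the largest-norm column; each next rank maximizes the residual norm after
projection onto the span of the selected columns (pseudo-inverse, robust
to rank deficiency); ranking stops when the best residual norm falls
below the threshold (default 0.004) and the remainder is reported
unranked.  Aggregation over repeated runs averages rank positions
(unranked counted as worst + 1); a parameter unranked in more than half
the runs stays unranked; ties break lexicographically.

## Relations

Linear: the parameter-block correlation matrix is read off P = S·Sᵀ from
the filter's final factor; pairs with |corr| ≥ 0.8 are flagged.
Non-linear: ACE alternates smoothing of the response transform θ(y)
against Σ φ_i(x_i) until the maximal correlation stabilizes (tolerance
1e−4, max 100 iterations).  The conditional-expectation smoother is
Nadaraya–Watson with a Silverman bandwidth applied on the *normal-scores*
(rank) scale of each variable — this makes the global bandwidth
appropriate for arbitrary marginals and renders the maximal correlation
exactly invariant under strictly monotone transforms.  MOTA scores
candidate predictor sets (greedy forward selection, up to 3 predictors)
on 50 bootstrap resamples and reports relations with mean r² ≥ 0.9 and
spread ≤ 0.1, preferring minimal subsets.

## Informed priors

Three provenances.  *Uninformed*: V₀ and Q₀ diagonals drawn Uniform(0.001,
0.1), parameter means Uniform(0, 1).  *Rank-based*: parameter standard
deviations interpolate geometrically from σ_min = 0.001 (rank 1) to
σ_max = 1.0 (worst rank and unranked); Q₀ uses the same schedule scaled
by 0.01.  The prior mean carries the first-pass estimate — the analysis
stage hands the informed prior back to the estimator — and repetitions
perturb it multiplicatively by ±1% (configurable); the spread of the
resulting estimates scales directly with this perturbation, which
represents small subjective variation in prior specification.
*Phase carry-over*: the next phase starts at the previous phase's final
mean (±5% multiplicative perturbation) with the previous covariance
factor verbatim and the phase-1 rank-based Q₀ — the mechanism for
chaining multiple datasets (e.g. wild-type after mutant) without building
parallel models.

On the structurally degenerate product fixture the rank-based prior
reduces the spread of repeated estimates by more than an order of
magnitude relative to uninformed runs, while the fitted trajectories stay
within a few percent of the noise scale of the data-generating dynamics:
the estimate is unique and behaviourally faithful even though individual
parameters need not equal the generating values — exactly what a prior
can and cannot buy when p(X|Θ₁) = p(X|Θ₂).

## Synthetic fixtures — what they emulate and what they do not

* `mm_chain` — S → P Michaelis–Menten (Vmax = 0.002 mM/s, Km = 0.3 mM,
  x₀ = (1, 1) mM).  Km is set so S(0)/Km ≈ 3: the transient traverses the
  saturated and first-order regimes inside the [0, 2340] s window, which
  is what makes both parameters identifiable.
* `product_ni` — ẋ = −θ₁θ₂x: a minimal structural degeneracy (only the
  product enters the likelihood).
* `practical_ni` — the MM chain at S ≪ Km (x₀ = 0.1, Km = 10): data
  constrain mainly Vmax/Km, producing one-sided profiles.
* `grn_small` — a 3-gene cascade: constitutive gene 1, protein-1-activated
  gene 2, protein-2-repressed gene 3; Hill transcription, linear mRNA
  degradation (rate fixed to 1) and protein synthesis/degradation; the
  mutant doubles the gene-2 translation rate.  A deliberately small
  stand-in for published gene-network benchmarks whose full equations are
  not redistributable.
* Noise: multiplicative y·(1 + 0.2·r) and mixed y + 0.1·r₁ + 0.2·r₂·y,
  both clamped at zero, per-element independent draws from a seeded
  generator.

These fixtures share the features the method targets — stiff-ish
saturable kinetics, signal-proportional noise, structural and practical
degeneracies — but they are small (1–6 states, 1–11 parameters), their
data-generating process has zero process noise, and their noise model is
exactly the one assumed by the estimator.  Passing tests therefore
demonstrate correctness of the machinery and calibration under matched
assumptions, not robustness to model misspecification, unmodelled
process noise, or the dimensionality of full published networks.

## Benchmark problem sizes

Replicated benchmarks are sized to complete in minutes: recovery runs use
the full 234-sample grid over 50 noise replicates; the repeated
fit-plus-profile coverage benchmark subsamples that grid at 40 s (58
samples, 50 replicates), which widens the confidence intervals but leaves
their coverage properties intact; MOTA null replicates use 40-sample
matrices.  Numbers quoted in the README come from the example scripts and
the acceptance script at these sizes.

## Known limitations

* The re-weighting rule for constrained sigma points is this package's
  own (ray scaling + weight renormalization); other constrained-UKF
  formulations exist and may differ near active bounds — the main
  fidelity risk of the filter module.
* Nuisance re-optimization inside profiles uses short annealed filter
  runs; on flat profiles the re-optimized χ² carries jitter of order
  1e−3–1e−2, which is why flatness is judged against ε_flat = 0.1.
* The SBML importer covers the ODE-compatible subset (kinetic laws,
  constant/boundary species, local parameters); events, rules and
  algebraic constraints raise errors rather than being approximated.
* Process noise w enters only at the discrete filter step; continuous
  SDE simulation is out of scope.
* MOTA detects relations among up to 3 predictors; higher-order or
  partially observed couplings (e.g. a response explained only through an
  unmeasured intermediate) can evade detection.
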