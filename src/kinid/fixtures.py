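"""Synthetic kinetic-model fixtures and study-style dataset generators.

Every test model and dataset in the package is generated programmatically
here: an identifiable Michaelis–Menten chain, deliberately non-identifiable
constructions (a structurally non-identifiable parameter product and a
practically non-identifiable low-substrate regime), a small gene-regulatory
cascade with a wild-type/mutant pair, and the two measurement-noise models
used throughout (20% multiplicative; additive+proportional mixed noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    ConfigError,
    KineticModel,
    NoiseModel,
    TimeSeries,
    apply_noise,
    simulate,
)

__all__ = [
    "FixtureSpec",
    "make_model",
    "make_fixture",
    "generate_experiment1_style",
    "generate_experiment2_style",
    "proportional_r_fn",
    "mixed_r_fn",
]

FIXTURE_IDS = ("mm_chain", "product_ni", "practical_ni", "grn_small", "constant")


@dataclass
class FixtureSpec:
    model_id: str = "mm_chain"
    overrides: dict = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(kind="none"))
    grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model_id not in FIXTURE_IDS:
            raise ConfigError(
                f"unknown fixture {self.model_id!r}; known: {FIXTURE_IDS}"
            )


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _mm_chain(theta_over: dict, *, x0=(1.0, 1.0)) -> KineticModel:
    """Two-state Michaelis–Menten conversion S -> P.

    dS/dt = -Vmax*S/(Km+S),  dP/dt = +Vmax*S/(Km+S); both states observed.
    Defaults are chosen so the benchmark is cleanly identifiable: S(0)/Km
    ≈ 3 puts the early transient in the saturated (zero-order) regime and
    the tail in the first-order regime, so the data constrain Vmax and Km
    separately, and the substrate depletes within the [0, 2340] s window.
    """
    theta = {"Vmax": 0.002, "Km": 0.3}
    theta.update(theta_over)

    def rhs(x, th, t):
        vmax, km = th
        v = vmax * x[0] / (km + x[0])
        return np.array([-v, v])

    return KineticModel(
        name="mm_chain",
        rhs=rhs,
        observe=lambda x, th, t: np.asarray(x),
        state_names=("S", "P"),
        param_names=("Vmax", "Km"),
        observed_names=("S", "P"),
        x0=np.asarray(x0, dtype=float),
        theta_true=np.array([theta["Vmax"], theta["Km"]]),
    )


def _product_ni(theta_over: dict) -> KineticModel:
    """Structurally non-identifiable decay: dx/dt = -theta1*theta2*x.

    Only the product theta1*theta2 enters the likelihood, so any pair on
    the hyperbola theta1*theta2 = c yields the same output distribution:
    the two parameters are structurally non-identifiable while the product
    is identifiable.
    """
    theta = {"theta1": 2.0, "theta2": 0.5}
    theta.update(theta_over)

    def rhs(x, th, t):
        return np.array([-th[0] * th[1] * x[0]])

    return KineticModel(
        name="product_ni",
        rhs=rhs,
        observe=lambda x, th, t: np.asarray(x),
        state_names=("x",),
        param_names=("theta1", "theta2"),
        observed_names=("x",),
        x0=np.array([1.0]),
        theta_true=np.array([theta["theta1"], theta["theta2"]]),
    )


def _practical_ni(theta_over: dict) -> KineticModel:
    """Michaelis–Menten chain operated at S << Km.

    In this regime the rate is ~ (Vmax/Km)*S, so the data constrain only the
    ratio: individual parameters can grow together without bound (profile
    crossing on one side only — practical non-identifiability).
    """
    theta = {"Vmax": 0.02, "Km": 10.0}
    theta.update(theta_over)
    m = _mm_chain(theta, x0=(0.1, 0.0))
    return KineticModel(
        name="practical_ni",
        rhs=m.rhs,
        observe=m.observe,
        state_names=m.state_names,
        param_names=m.param_names,
        observed_names=m.observed_names,
        x0=m.x0,
        theta_true=m.theta_true,
    )


def _grn_small(theta_over: dict, *, mutant: bool = False) -> KineticModel:
    """Three-gene cascade with Hill-type transcription.

    Gene 1 is constitutively transcribed; protein 1 activates gene 2;
    protein 2 represses gene 3.  mRNA synthesis uses Hill kinetics, mRNA
    degradation and protein synthesis/degradation are linear.  The mRNA
    degradation rate is fixed to 1.  The mutant doubles the translation
    rate of gene 2 (``rbs2``), leaving everything else untouched.
    """
    theta = {
        "pro1": 1.0,
        "pro2": 2.0,
        "pro3": 2.0,
        "rbs1": 1.5,
        "rbs2": 1.0,
        "rbs3": 1.5,
        "Kd2": 0.5,
        "Kd3": 0.5,
        "h2": 2.0,
        "h3": 2.0,
        "p_deg": 0.5,
    }
    theta.update(theta_over)
    names = tuple(theta)
    mrna_deg = 1.0
    rbs2_scale = 2.0 if mutant else 1.0

    def rhs(x, th, t):
        m1, p1, m2, p2, m3, p3 = x
        d = dict(zip(names, th))
        # clamp protein levels at 0 inside Hill terms: adaptive integrators
        # may probe infinitesimally negative states, and a negative base
        # with fractional exponent is NaN
        act2 = (max(p1, 0.0) / d["Kd2"]) ** d["h2"]
        act2 = act2 / (1.0 + act2)  # activation of gene 2 by protein 1
        rep3 = 1.0 / (1.0 + (max(p2, 0.0) / d["Kd3"]) ** d["h3"])  # repression of gene 3
        return np.array(
            [
                d["pro1"] - mrna_deg * m1,
                d["rbs1"] * m1 - d["p_deg"] * p1,
                d["pro2"] * act2 - mrna_deg * m2,
                rbs2_scale * d["rbs2"] * m2 - d["p_deg"] * p2,
                d["pro3"] * rep3 - mrna_deg * m3,
                d["rbs3"] * m3 - d["p_deg"] * p3,
            ]
        )

    return KineticModel(
        name="grn_small_mutant" if mutant else "grn_small",
        rhs=rhs,
        observe=lambda x, th, t: np.asarray(x),
        state_names=("m1", "p1", "m2", "p2", "m3", "p3"),
        param_names=names,
        observed_names=("m1", "p1", "m2", "p2", "m3", "p3"),
        x0=np.zeros(6),
        theta_true=np.array([theta[n] for n in names]),
    )


def _constant(theta_over: dict) -> KineticModel:
    """F == 0 sanity model: the state never moves."""

    return KineticModel(
        name="constant",
        rhs=lambda x, th, t: np.zeros_like(x),
        observe=lambda x, th, t: np.asarray(x),
        state_names=("c1", "c2"),
        param_names=(),
        observed_names=("c1", "c2"),
        x0=np.array([1.0, 3.0]),
        theta_true=np.array([]),
    )


def make_model(model_id: str, overrides: dict | None = None, **kwargs) -> KineticModel:
    overrides = overrides or {}
    builders = {
        "mm_chain": _mm_chain,
        "product_ni": _product_ni,
        "practical_ni": _practical_ni,
        "grn_small": _grn_small,
        "constant": _constant,
    }
    if model_id not in builders:
        raise ConfigError(f"unknown fixture {model_id!r}; known: {FIXTURE_IDS}")
    return builders[model_id](overrides, **kwargs)


_DEFAULT_GRIDS = {
    "mm_chain": np.arange(10.0, 2341.0, 10.0),
    "product_ni": np.linspace(0.1, 4.0, 40),
    "practical_ni": np.arange(10.0, 2341.0, 10.0),
    "grn_small": np.arange(0.0, 21.0, 1.0),
    "constant": np.linspace(1.0, 10.0, 10),
}


def make_fixture(spec: FixtureSpec) -> tuple[KineticModel, TimeSeries, TimeSeries]:
    """Build (model, clean series, noisy series) for a fixture spec."""
    model = make_model(spec.model_id, spec.overrides)
    grid = spec.grid if spec.grid is not None else _DEFAULT_GRIDS[spec.model_id]
    clean = simulate(model, model.theta_true, grid)
    noise = spec.noise
    if noise.seed != spec.seed:
        noise = NoiseModel(noise.kind, noise.c_mult, noise.a_add, noise.C, spec.seed)
    noisy = apply_noise(clean, noise)
    return model, clean, noisy


# ---------------------------------------------------------------------------
# study-style dataset bundles
# ---------------------------------------------------------------------------


def proportional_r_fn(c: float = 0.2, floor: float = 1e-3):
    """Per-step sqrt(R) for multiplicative noise: std = c * y (floored).

    The measurement covariance is set from the noise convention
    "c x r x y": the standard deviation of multiplicative noise at signal
    level y is c*y, so R_k = diag((c*y_k)^2).
    """

    def r_fn(k, y):
        return np.diag(np.maximum(c * np.abs(y), floor))

    return r_fn


def mixed_r_fn(a: float = 0.1, C: float = 0.2):
    """Per-step sqrt(R) for mixed noise: var = a^2 + (C*y)^2 per channel."""

    def r_fn(k, y):
        return np.diag(np.sqrt(a**2 + (C * np.abs(y)) ** 2))

    return r_fn


def generate_experiment1_style(
    seed: int,
    model_id: str = "mm_chain",
    overrides: dict | None = None,
) -> dict:
    """Sucrose-accumulation-style bundle: [0, 2340] s grid, step 10 s
    (measurements at t = 10..2340, i.e. 234 samples), initial concentrations
    of 1 mM, 20% multiplicative noise, proportional measurement covariance.
    """
    grid = np.arange(10.0, 2341.0, 10.0)
    spec = FixtureSpec(
        model_id=model_id,
        overrides=overrides or {},
        noise=NoiseModel(kind="multiplicative", c_mult=0.2, seed=seed),
        grid=grid,
        seed=seed,
    )
    model, clean, noisy = make_fixture(spec)
    return {
        "model": model,
        "clean": clean,
        "noisy": noisy,
        "r_fn": proportional_r_fn(0.2),
        "seed": seed,
    }


def generate_experiment2_style(seed: int, overrides: dict | None = None) -> tuple[dict, dict]:
    """GRN-style two-condition bundle on t = 0..20 s, step 1 s.

    Returns (wild-type bundle, mutant bundle); the mutant doubles the rbs2
    translation rate.  Mixed noise y + 0.1 r1 + 0.2 r2 y, clamped at zero.
    Each series has 21 rows (t = 0..20 inclusive) — with additive noise the
    t = 0 snapshot is itself a legitimate noisy measurement.
    """
    grid = np.arange(0.0, 21.0, 1.0)
    out = []
    for i, mutant in enumerate((False, True)):
        model = make_model("grn_small", overrides or {}, mutant=mutant)
        clean = simulate(model, model.theta_true, grid)
        noisy = apply_noise(
            clean, NoiseModel(kind="mixed", a_add=0.1, C=0.2, seed=seed + 7 * i)
        )
        out.append(
            {
                "model": model,
                "clean": clean,
                "noisy": noisy,
                "r_fn": mixed_r_fn(0.1, 0.2),
                "seed": seed,
            }
        )
    return out[0], out[1]


def proportional_R_from_model(model, theta_est, times, c: float = 0.2, floor: float = 1e-3):
    """Per-step measurement covariances from a model trajectory.

    For signal-proportional noise the variance is (c * y_clean)^2; the
    clean signal is estimated by simulating the model at ``theta_est``.
    Weighting by the noisy measurements instead would bias the weighted
    least-squares objective, so profile likelihoods and fit selection use
    this model-based R.
    """
    sim = simulate(model, theta_est, times, full_theta=False, rtol=1e-7, atol=1e-9)
    return [np.diag(np.maximum(c * np.abs(y), floor) ** 2) for y in sim.values]
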