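"""Informed-prior construction for CSUKF estimation.

In a Bayesian filter a non-identifiable likelihood still yields a unique
posterior when the prior carries information.  Three prior modes:

* ``uninformed`` — diagonal V0 and Q0 with small random entries in
  [0.001, 0.1]; parameter means drawn Uniform(0, 1);
* ``rank_based`` — parameter standard deviations follow a geometric
  schedule in the orthogonal rank: rank 1 (most influential, best
  constrained by the data) gets sigma_min, the worst rank and all unranked
  parameters get sigma_max;
* ``phase_carryover`` — the mean and covariance factor of a previous
  estimation phase seed the next one (multi-dataset sequential
  estimation), with a small multiplicative perturbation of the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .filtering import EstimationResult
from .models import ConfigError, KineticModel
from .sensitivity import RankingResult

__all__ = [
    "PriorSpec",
    "prior_from_ranking",
    "prior_from_phase",
    "uninformed_prior",
]


@dataclass
class PriorSpec:
    """Initial augmented mean + covariance factors defining a filter prior."""

    mean0: np.ndarray
    sqrt_V0: np.ndarray
    sqrt_Q0: np.ndarray
    provenance: str = "uninformed"  # uninformed | rank_based | phase_carryover
    schedule: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean0 = np.asarray(self.mean0, dtype=float)
        self.sqrt_V0 = np.atleast_2d(np.asarray(self.sqrt_V0, dtype=float))
        self.sqrt_Q0 = np.atleast_2d(np.asarray(self.sqrt_Q0, dtype=float))
        for f, what in ((self.sqrt_V0, "V0"), (self.sqrt_Q0, "Q0")):
            if np.any(np.diag(f) <= 0):
                raise ConfigError(f"sqrt_{what} must have positive diagonal")

    def to_yaml(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "schedule": {k: float(v) for k, v in self.schedule.items()},
            "mean0": self.mean0.tolist(),
            "sqrt_V0": self.sqrt_V0.tolist(),
            "sqrt_Q0": self.sqrt_Q0.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            mean0=np.array(payload["mean0"], dtype=float),
            sqrt_V0=np.array(payload["sqrt_V0"], dtype=float),
            sqrt_Q0=np.array(payload["sqrt_Q0"], dtype=float),
            provenance=payload.get("provenance", "uninformed"),
            schedule=payload.get("schedule", {}),
        )


def prior_from_ranking(
    model: KineticModel,
    ranking: RankingResult,
    *,
    sigma_min: float = 0.001,
    sigma_max: float = 1.0,
    theta0: np.ndarray | dict | None = None,
    state_sigma: float = 0.01,
    q_scale: float = 0.01,
    seed: int = 0,
) -> PriorSpec:
    """Rank-based informed prior.

    Parameter standard deviations interpolate geometrically from
    ``sigma_min`` at rank 1 to ``sigma_max`` at the worst rank; unranked
    parameters get ``sigma_max``.  High-rank (influential) parameters are
    tightly constrained because the data inform them well; low-rank ones
    are left loose.  Q0 uses the same schedule scaled by ``q_scale``.
    ``theta0`` sets the parameter block of the initial mean (default:
    Uniform(0, 1) draws, the standard random initialization).
    """
    if sigma_min >= sigma_max:
        raise ConfigError(f"sigma_min ({sigma_min}) must be < sigma_max ({sigma_max})")
    params = model.estimated_params
    if not ranking.ranked and not ranking.unranked:
        raise ConfigError("empty ranking")
    n_ranked = len(ranking.ranked)
    stds = np.empty(len(params))
    for i, p in enumerate(params):
        r = ranking.rank_of(p)
        if r is None:
            stds[i] = sigma_max
        elif n_ranked == 1:
            stds[i] = sigma_min
        else:
            frac = (r - 1) / (n_ranked - 1)
            stds[i] = sigma_min * (sigma_max / sigma_min) ** frac
    rng = np.random.default_rng(seed)
    if theta0 is None:
        theta0 = rng.uniform(0.0, 1.0, size=len(params))
    elif isinstance(theta0, dict):
        theta0 = np.array([theta0[p] for p in params])
    mean0 = np.concatenate([model.x0, np.asarray(theta0, dtype=float)])
    d = model.n_states
    v_diag = np.concatenate([np.full(d, state_sigma), stds])
    q_diag = np.concatenate([np.full(d, state_sigma * q_scale), stds * q_scale])
    return PriorSpec(
        mean0=mean0,
        sqrt_V0=np.diag(v_diag),
        sqrt_Q0=np.diag(q_diag),
        provenance="rank_based",
        schedule={"sigma_min": sigma_min, "sigma_max": sigma_max, "q_scale": q_scale},
    )


def prior_from_phase(
    prev: EstimationResult,
    prev_final_S: np.ndarray | None = None,
    *,
    sqrt_Q0: np.ndarray,
    perturb: float = 0.05,
    n_states: int | None = None,
    seed: int = 0,
) -> PriorSpec:
    """Carry a previous phase's estimate over as the next phase's prior.

    The new initial mean is the previous final mean with each parameter
    multiplied by Uniform(1−perturb, 1+perturb); the covariance factor V0
    is the previous final factor verbatim; Q0 is re-used from the
    rank-based matrix of the first phase (passed in as ``sqrt_Q0``).
    """
    S = prev.final_S if prev_final_S is None else prev_final_S
    mean = np.array(prev.means[-1], dtype=float)
    sqrt_Q0 = np.atleast_2d(np.asarray(sqrt_Q0, dtype=float))
    if sqrt_Q0.shape != S.shape:
        raise ConfigError(
            f"phase dimension mismatch: Q0 {sqrt_Q0.shape} vs V {S.shape}"
        )
    if len(mean) != S.shape[0]:
        raise ConfigError("previous mean and covariance dimensions differ")
    rng = np.random.default_rng(seed)
    d = 0 if n_states is None else n_states
    factors = rng.uniform(1.0 - perturb, 1.0 + perturb, size=len(mean) - d)
    mean[d:] = mean[d:] * factors
    return PriorSpec(
        mean0=mean,
        sqrt_V0=np.array(S, dtype=float),
        sqrt_Q0=sqrt_Q0,
        provenance="phase_carryover",
        schedule={"perturb": perturb},
    )


def uninformed_prior(model: KineticModel, *, seed: int = 0) -> PriorSpec:
    """Diffuse prior: V0, Q0 diagonals Uniform(0.001, 0.1), θ0 Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    d, p = model.n_states, model.n_est
    n = d + p
    v_diag = rng.uniform(0.001, 0.1, size=n)
    q_diag = rng.uniform(0.001, 0.1, size=n)
    theta0 = rng.uniform(0.0, 1.0, size=p)
    mean0 = np.concatenate([model.x0, theta0])
    return PriorSpec(
        mean0=mean0,
        sqrt_V0=np.diag(np.sqrt(v_diag)),
        sqrt_Q0=np.diag(np.sqrt(q_diag)),
        provenance="uninformed",
    )
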