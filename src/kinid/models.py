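"""Kinetic models as continuous state-space systems.

A kinetic model is the pair of maps

    dx/dt = F(x, theta, t)        (state dynamics, concentrations in mM)
    y     = H(x, theta, t)        (observation map)

with initial state ``x(0)``.  Joint state/parameter estimation augments the
state with the estimated parameters, ``x_aug = [x | theta_est]`` where the
parameter block has zero dynamics (``dtheta/dt = 0``), so that a Kalman-type
filter can treat parameters as hidden states.

Discretization between observation instants is by numerical integration of F
over ``[t_k, t_{k+1}]`` with the parameter block held fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticModel",
    "NoiseModel",
    "TimeSeries",
    "AugmentedState",
    "IntegrationError",
    "ConfigError",
    "simulate",
    "apply_noise",
    "discretize",
    "propagate_points",
    "log_param_model",
]

#: default integration tolerances; saturable metabolic kinetics are often
#: stiff, so the integrator must be stiff-capable (LSODA switches
#: automatically).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE integration failed (e.g. stiff blow-up); carries context."""


class ConfigError(ValueError):
    """Inconsistent model/filter/noise configuration."""


@dataclass(frozen=True)
class KineticModel:
    """Continuous state-space kinetic model.

    Parameters
    ----------
    name : str
        Identifier for reports.
    rhs : callable ``F(x, theta, t) -> dx/dt``
        Vector field over the full state. ``theta`` is the *full* parameter
        vector ordered by ``param_names``.  Must be a pure function.
    observe : callable ``H(x, theta, t) -> y``
        Observation map returning the observed quantities.
    state_names, param_names, observed_names : sequences of str
        Unique identifiers for states, parameters and observation channels.
    x0 : array
        Initial state (mM) at ``t = 0``.
    theta_true : array, optional
        Reference parameter vector for fixtures and benchmarks.
    fixed_params : mapping, optional
        Parameters held constant during estimation (name -> value).  The
        estimated parameters are ``param_names`` minus the fixed ones.
    """

    name: str
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    observe: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    observed_names: tuple[str, ...]
    x0: np.ndarray
    theta_true: np.ndarray | None = None
    fixed_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "param_names", tuple(self.param_names))
        object.__setattr__(self, "observed_names", tuple(self.observed_names))
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))
        if self.theta_true is not None:
            object.__setattr__(
                self, "theta_true", np.asarray(self.theta_true, dtype=float)
            )
        if len(self.x0) != len(self.state_names):
            raise ConfigError(
                f"x0 has {len(self.x0)} entries for {len(self.state_names)} states"
            )
        for names, what in (
            (self.state_names, "state"),
            (self.param_names, "parameter"),
            (self.observed_names, "observation"),
        ):
            if len(set(names)) != len(names):
                raise ConfigError(f"duplicate {what} names: {names}")
        unknown = set(self.fixed_params) - set(self.param_names)
        if unknown:
            raise ConfigError(f"fixed_params not in param_names: {sorted(unknown)}")

    # -- derived structure -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_obs(self) -> int:
        return len(self.observed_names)

    @property
    def estimated_params(self) -> tuple[str, ...]:
        return tuple(p for p in self.param_names if p not in self.fixed_params)

    @property
    def n_est(self) -> int:
        return len(self.estimated_params)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def full_theta(self, theta_est: np.ndarray | Mapping[str, float]) -> np.ndarray:
        """Assemble the full parameter vector from estimated values + fixed."""
        full = np.empty(len(self.param_names))
        if isinstance(theta_est, Mapping):
            est_map = dict(theta_est)
        else:
            theta_est = np.asarray(theta_est, dtype=float)
            if theta_est.shape != (self.n_est,):
                raise ConfigError(
                    f"expected {self.n_est} estimated parameters, got {theta_est.shape}"
                )
            est_map = dict(zip(self.estimated_params, theta_est))
        for i, p in enumerate(self.param_names):
            if p in self.fixed_params:
                full[i] = self.fixed_params[p]
            else:
                full[i] = est_map[p]
        return full

    def theta_true_est(self) -> np.ndarray:
        """True values of the estimated parameters (fixtures only)."""
        if self.theta_true is None:
            raise ConfigError(f"model {self.name!r} has no theta_true")
        idx = [self.param_index(p) for p in self.estimated_params]
        return self.theta_true[idx]

    def fix(self, **values: float) -> "KineticModel":
        """Return a copy with additional parameters held fixed."""
        unknown = set(values) - set(self.param_names)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        fixed = dict(self.fixed_params)
        fixed.update(values)
        return dataclasses.replace(self, fixed_params=fixed)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise generator.

    ``multiplicative``:  y_noisy = max[0, y * (1 + c_mult * r)]
    ``mixed``:           y_noisy = max[0, y + a_add * r1 + C * r2 * y]
    ``none``:            identity.

    r, r1, r2 are independent standard-normal draws from the seeded stream.
    The clamp at zero guarantees non-negative concentrations.
    """

    kind: str = "multiplicative"
    c_mult: float = 0.2
    a_add: float = 0.1
    C: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative", "mixed", "none"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")


@dataclass
class TimeSeries:
    """Time-stamped observation table: ``values[i, j]`` at ``times[i]``."""

    times: np.ndarray
    values: np.ndarray
    observed_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.observed_names = tuple(self.observed_names)
        if self.values.shape[0] != self.times.shape[0]:
            raise ConfigError(
                f"{self.values.shape[0]} rows of values for {len(self.times)} times"
            )
        if self.values.shape[1] != len(self.observed_names):
            raise ConfigError("values columns do not match observed_names")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ConfigError("non-finite values in time series")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.observed_names))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TimeSeries":
        if "time" not in df.columns:
            raise ConfigError("time-series CSV must have a 'time' column")
        names = [c for c in df.columns if c != "time"]
        return cls(
            times=df["time"].to_numpy(),
            values=df[names].to_numpy(),
            observed_names=tuple(names),
            meta=meta or {},
        )

    @classmethod
    def read_csv(cls, path) -> "TimeSeries":
        return cls.from_frame(pd.read_csv(path), meta={"source": str(path)})


class AugmentedState:
    """Index bookkeeping for the augmented vector ``[states | estimated params]``."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.names: tuple[str, ...] = model.state_names + model.estimated_params
        self._index = {n: i for i, n in enumerate(self.names)}
        self.n_states = model.n_states
        self.n = len(self.names)

    def index(self, name: str) -> int:
        return self._index[name]

    def pack(self, x: np.ndarray, theta_est: np.ndarray) -> np.ndarray:
        return np.concatenate([np.asarray(x, float), np.asarray(theta_est, float)])

    def split(self, x_aug: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x_aug = np.asarray(x_aug, dtype=float)
        return x_aug[: self.n_states], x_aug[self.n_states :]

    @property
    def param_slice(self) -> slice:
        return slice(self.n_states, self.n)


def log_param_model(model: KineticModel) -> KineticModel:
    """Reparameterize the *estimated* parameters on the natural-log scale.

    The returned model's estimated-parameter entries are ``log(theta)``;
    fixed parameters stay on the natural scale.  Useful when estimated
    parameters span orders of magnitude: additive filter steps become
    multiplicative on the original scale and positivity is automatic.
    ``theta_true`` is transformed accordingly.
    """
    idx = np.array([model.param_index(p) for p in model.estimated_params], dtype=int)
    if len(idx) == 0:
        return model

    base_rhs, base_obs = model.rhs, model.observe

    def _nat(theta):
        th = np.array(theta, dtype=float)
        th[idx] = np.exp(th[idx])
        return th

    def rhs(x, theta, t):
        return base_rhs(x, _nat(theta), t)

    def observe(x, theta, t):
        return base_obs(x, _nat(theta), t)

    theta_true = None
    if model.theta_true is not None:
        theta_true = np.array(model.theta_true, dtype=float)
        if np.any(theta_true[idx] <= 0):
            raise ConfigError("log transform requires positive true parameters")
        theta_true[idx] = np.log(theta_true[idx])
    return dataclasses.replace(
        model,
        name=model.name + "_logparams",
        rhs=rhs,
        observe=observe,
        theta_true=theta_true,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate(
    model: KineticModel,
    theta: np.ndarray | Mapping[str, float] | None = None,
    times: Sequence[float] | np.ndarray = (),
    *,
    x0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    full_theta: bool = True,
) -> TimeSeries:
    """Noise-free solve of the model ODEs, observed through H at ``times``.

    ``theta`` is the full parameter vector (default: ``theta_true``); pass
    ``full_theta=False`` to supply only the estimated parameters.  The solve
    always starts at ``t = 0`` with ``x0`` even if ``times[0] > 0`` — time
    grids are measurement instants, the initial state is not a measurement.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ConfigError("times must be a non-empty 1-d grid")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("times must be strictly increasing")
    if theta is None:
        if model.theta_true is None:
            raise ConfigError("no theta given and model has no theta_true")
        theta_full = np.asarray(model.theta_true, dtype=float)
    elif full_theta and not isinstance(theta, Mapping):
        theta_full = np.asarray(theta, dtype=float)
        if theta_full.shape != (len(model.param_names),):
            raise ConfigError(
                f"expected {len(model.param_names)} parameters, got {theta_full.shape}"
            )
    else:
        theta_full = model.full_theta(theta)

    x_init = model.x0 if x0 is None else np.asarray(x0, dtype=float)
    t0 = min(0.0, times[0])
    t_eval = times if times[0] == t0 else np.concatenate([[t0], times])

    sol = solve_ivp(
        lambda t, x: np.asarray(model.rhs(x, theta_full, t), dtype=float),
        (t0, times[-1]),
        x_init,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration of {model.name!r} failed near t={sol.t[-1] if len(sol.t) else t0}: "
            f"{sol.message}"
        )
    X = sol.y.T if times[0] == t0 else sol.y.T[1:]
    obs = np.array(
        [np.atleast_1d(model.observe(x, theta_full, t)) for x, t in zip(X, times)],
        dtype=float,
    )
    return TimeSeries(
        times=times,
        values=obs,
        observed_names=model.observed_names,
        meta={"model": model.name, "noise": "none"},
    )


def apply_noise(series: TimeSeries, noise: NoiseModel) -> TimeSeries:
    """Apply a measurement-noise model elementwise (clamped at zero)."""
    if noise.kind == "none":
        return TimeSeries(
            series.times.copy(),
            series.values.copy(),
            series.observed_names,
            dict(series.meta, noise="none"),
        )
    rng = np.random.default_rng(noise.seed)
    y = series.values
    if noise.kind == "multiplicative":
        r = rng.standard_normal(y.shape)
        noisy = np.maximum(0.0, y * (1.0 + noise.c_mult * r))
    elif noise.kind == "mixed":
        r1 = rng.standard_normal(y.shape)
        r2 = rng.standard_normal(y.shape)
        noisy = np.maximum(0.0, y + noise.a_add * r1 + noise.C * r2 * y)
    else:  # pragma: no cover - guarded in NoiseModel
        raise ConfigError(f"unknown noise kind {noise.kind!r}")
    return TimeSeries(
        series.times.copy(),
        noisy,
        series.observed_names,
        dict(series.meta, noise=noise.kind, noise_seed=noise.seed),
    )


def _aug_rhs(model: KineticModel, aug: AugmentedState):
    """Right-hand side over the augmented vector; parameter block is constant."""

    d = aug.n_states

    def f(t, z):
        x, theta_est = z[:d], z[d:]
        theta_full = model.full_theta(theta_est)
        dx = np.asarray(model.rhs(x, theta_full, t), dtype=float)
        return np.concatenate([dx, np.zeros(len(theta_est))])

    return f


def discretize(
    model: KineticModel,
    x_aug_k: np.ndarray,
    t_k: float,
    t_k1: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Advance the augmented vector from ``t_k`` to ``t_{k+1}``.

    The state block is integrated with the parameter block's values; the
    parameter block itself is returned bit-identically (zero dynamics).
    """
    return propagate_points(
        model, np.atleast_2d(x_aug_k), t_k, t_k1, rtol=rtol, atol=atol
    )[0]


def propagate_points(
    model: KineticModel,
    points: np.ndarray,
    t_k: float,
    t_k1: float,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Propagate several augmented vectors over ``[t_k, t_k1]`` in one solve.

    The points are stacked into a single ODE system so the integrator is
    invoked once per filter step rather than once per sigma point.
    """
    if t_k1 <= t_k:
        raise ConfigError(f"t_k1 ({t_k1}) must exceed t_k ({t_k})")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m, n = points.shape
    aug = AugmentedState(model)
    if n != aug.n:
        raise ConfigError(f"augmented points have dim {n}, expected {aug.n}")
    d = aug.n_states
    thetas = [model.full_theta(p[d:]) for p in points]

    def stacked(t, z):
        out = np.zeros_like(z)
        for i in range(m):
            x = z[i * d : (i + 1) * d]
            out[i * d : (i + 1) * d] = model.rhs(x, thetas[i], t)
        return out

    z0 = np.concatenate([p[:d] for p in points])
    sol = solve_ivp(stacked, (t_k, t_k1), z0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"propagation of {model.name!r} failed on [{t_k}, {t_k1}]: {sol.message}; "
            f"augmented vectors {points!r}"
        )
    zf = sol.y[:, -1]
    out = points.copy()
    for i in range(m):
        out[i, :d] = zf[i * d : (i + 1) * d]
    return out
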