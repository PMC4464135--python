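"""Constrained square-root unscented Kalman filter (CSUKF).

Joint state/parameter estimation for kinetic ODE models.  The filter
propagates a deterministic set of sigma points through the discretized
dynamics and maintains the *square root* S of the estimation covariance
(P = S Sᵀ) via QR factorizations and rank-1 Cholesky updates, which keeps P
positive definite by construction.  Box constraints L ≤ x ≤ U on the
augmented vector are enforced by pulling every violating sigma point back
toward the mean along its ray to the nearest feasible point and re-weighting:
the point's mean/covariance weights are multiplied by the applied scale
factor and all weights renormalized so that Σ W^m = 1 (the same constant is
applied to W^c).  With no active constraint this reduces to the standard
square-root UKF of van der Merwe & Wan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import block_diag, cholesky, qr, solve_triangular

from .models import (
    AugmentedState,
    ConfigError,
    KineticModel,
    TimeSeries,
    propagate_points,
)

__all__ = [
    "BoxConstraints",
    "UTParams",
    "FilterState",
    "SigmaPointSet",
    "EstimationResult",
    "cholupdate",
    "make_sigma_points",
    "predict",
    "update",
    "estimate",
    "merit_chi2",
    "simulation_chi2",
    "proportional_nll",
    "initial_state",
    "FilterDivergenceError",
]


class FilterDivergenceError(RuntimeError):
    """A Cholesky downdate lost positive definiteness; the filter diverged."""


@dataclass(frozen=True)
class BoxConstraints:
    """Elementwise box L ≤ x ≤ U on the augmented vector (±inf = unbounded)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ConfigError("lower/upper bound shape mismatch")
        if np.any(self.lower > self.upper):
            raise ConfigError("lower bound exceeds upper bound")

    @classmethod
    def unbounded(cls, n: int) -> "BoxConstraints":
        return cls(np.full(n, -np.inf), np.full(n, np.inf))

    @classmethod
    def for_model(
        cls,
        model: KineticModel,
        *,
        param_lower: float = 1e-8,
        param_upper: float = 100.0,
        state_lower: float = 0.0,
        state_upper: float = np.inf,
    ) -> "BoxConstraints":
        """Non-negative states, positive bounded parameters (field defaults)."""
        d, p = model.n_states, model.n_est
        lo = np.concatenate([np.full(d, state_lower), np.full(p, param_lower)])
        hi = np.concatenate([np.full(d, state_upper), np.full(p, param_upper)])
        return cls(lo, hi)

    def contains(self, v: np.ndarray, atol: float = 1e-12) -> bool:
        return bool(
            np.all(v >= self.lower - atol) and np.all(v <= self.upper + atol)
        )

    def clip(self, v: np.ndarray) -> np.ndarray:
        return np.clip(v, self.lower, self.upper)


@dataclass(frozen=True)
class UTParams:
    """Unscented-transform scalars.

    Defaults are alpha=1, beta=2 and kappa = max(0, 3-n): the classical
    kappa = 3-n (fourth-order Gaussian moment matching) for n <= 3, floored
    at 0 for larger n so that the central mean-weight lambda/(n+lambda)
    never goes negative — a negative central weight breaks the constraint
    re-weighting normalization whenever boundary contact shrinks the
    positive weights.
    """

    alpha: float = 1.0
    beta: float = 2.0
    kappa: float | None = None  # None -> max(0, 3 - n)

    def resolved_kappa(self, n: int) -> float:
        return max(0.0, 3.0 - n) if self.kappa is None else self.kappa


@dataclass
class FilterState:
    """Everything the CSUKF carries between iterations."""

    mean: np.ndarray
    S: np.ndarray  # lower-triangular sqrt of estimation covariance
    sqrt_Q: np.ndarray  # sqrt of process-noise covariance (augmented)
    sqrt_R: np.ndarray  # sqrt of measurement-noise covariance
    constraints: BoxConstraints
    ut: UTParams = field(default_factory=UTParams)
    k: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.sqrt_Q = np.asarray(self.sqrt_Q, dtype=float)
        self.sqrt_R = np.asarray(self.sqrt_R, dtype=float)
        if np.any(np.diag(self.S) <= 0):
            raise ConfigError("sqrt covariance factor must have positive diagonal")
        if not self.constraints.contains(self.mean):
            raise ConfigError("filter mean violates box constraints")

    @property
    def cov(self) -> np.ndarray:
        return self.S @ self.S.T


@dataclass
class SigmaPointSet:
    points: np.ndarray  # (2n+1, n)
    wm: np.ndarray
    wc: np.ndarray


@dataclass
class EstimationResult:
    """Output of a CSUKF estimation run."""

    means: np.ndarray  # (n_steps+1, n_aug) per-update posterior means
    final_S: np.ndarray
    residuals: np.ndarray  # (n_steps, n_obs) innovations y(k) - yhat-(k)
    R_list: list  # per-step measurement covariance used
    final_theta: dict
    merit: float
    n_iters: int
    converged: bool
    stop_reason: str
    param_names: tuple = ()

    @property
    def final_theta_vector(self) -> np.ndarray:
        return np.array([self.final_theta[p] for p in self.param_names])

    def means_to_csv(self, path, names: Sequence[str] | None = None) -> None:
        """Per-iteration posterior means of the augmented vector as CSV."""
        import pandas as pd

        cols = list(names) if names else [f"z{i}" for i in range(self.means.shape[1])]
        pd.DataFrame(self.means, columns=cols).to_csv(path, index_label="iteration")

    def to_dict(self) -> dict:
        return {
            "final_theta": {k: float(v) for k, v in self.final_theta.items()},
            "merit_chi2": float(self.merit),
            "n_iters": int(self.n_iters),
            "converged": bool(self.converged),
            "stop_reason": self.stop_reason,
        }


# ---------------------------------------------------------------------------
# square-root utilities
# ---------------------------------------------------------------------------


def cholupdate(S: np.ndarray, v: np.ndarray, sign: float = 1.0) -> np.ndarray:
    """Rank-1 update/downdate of a lower-triangular Cholesky factor.

    Returns the factor of ``S Sᵀ + sign · v vᵀ``.  Raises
    :class:`FilterDivergenceError` when the downdate would lose positive
    definiteness — by design this is an error, never silently patched.
    """
    S = np.array(S, dtype=float)
    v = np.array(v, dtype=float)
    n = len(v)
    for k in range(n):
        r2 = S[k, k] ** 2 + sign * v[k] ** 2
        if r2 <= 0.0:
            raise FilterDivergenceError(
                f"Cholesky downdate failed at row {k}: diagonal would be {r2:.3e}"
            )
        r = np.sqrt(r2)
        c = r / S[k, k]
        s = v[k] / S[k, k]
        S[k, k] = r
        if k + 1 < n:
            S[k + 1 :, k] = (S[k + 1 :, k] + sign * s * v[k + 1 :]) / c
            v[k + 1 :] = c * v[k + 1 :] - s * S[k + 1 :, k]
    return S


def _qr_sqrt(rows: np.ndarray) -> np.ndarray:
    """Lower-triangular factor from stacked rows: returns L with LLᵀ = rowsᵀrows."""
    r = qr(rows, mode="economic")[1]
    L = r.T.copy()
    d = np.sign(np.diag(L))
    d[d == 0] = 1.0
    return L * d  # enforce positive diagonal


# ---------------------------------------------------------------------------
# sigma points
# ---------------------------------------------------------------------------


def make_sigma_points(state: FilterState) -> SigmaPointSet:
    """Generate 2n+1 constrained sigma points with adjusted weights."""
    n = len(state.mean)
    alpha, beta = state.ut.alpha, state.ut.beta
    kappa = state.ut.resolved_kappa(n)
    lam = alpha**2 * (n + kappa) - n
    if n + lam <= 0:
        raise ConfigError("UT scalars give non-positive n + lambda")
    gamma = np.sqrt(n + lam)

    pts = np.empty((2 * n + 1, n))
    pts[0] = state.mean
    offset = gamma * state.S  # columns are the spread directions
    pts[1 : n + 1] = state.mean + offset.T
    pts[n + 1 :] = state.mean - offset.T

    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = wm[0] + (1.0 - alpha**2 + beta)

    lo, hi = state.constraints.lower, state.constraints.upper
    if not state.constraints.contains(state.mean):
        raise ConfigError("sigma-point mean violates constraints")
    # interval-constrained scaling: pull violators back along their ray
    for i in range(1, 2 * n + 1):
        p = pts[i]
        if np.all(p >= lo) and np.all(p <= hi):
            continue
        d = p - state.mean
        s = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            for j in range(n):
                if d[j] > 0 and p[j] > hi[j]:
                    s = min(s, (hi[j] - state.mean[j]) / d[j])
                elif d[j] < 0 and p[j] < lo[j]:
                    s = min(s, (lo[j] - state.mean[j]) / d[j])
        s = max(s, 0.0)
        pts[i] = state.mean + s * d
        wm[i] *= s
        wc[i] *= s
    total = wm.sum()
    if total <= 0:
        raise FilterDivergenceError("constrained sigma-point weights sum to <= 0")
    wm /= total
    wc /= total
    return SigmaPointSet(points=pts, wm=wm, wc=wc)


# ---------------------------------------------------------------------------
# predict / update
# ---------------------------------------------------------------------------


def _sqrt_from_deviations(
    devs: np.ndarray, wc: np.ndarray, noise_sqrt: np.ndarray
) -> np.ndarray:
    """Square-root covariance from weighted sigma deviations + additive noise.

    QR over the w>0 deviations stacked with the noise factor, then a rank-1
    update (or downdate when W0^c < 0) for the central point.
    """
    scaled = np.sqrt(np.maximum(wc[1:], 0.0))[:, None] * devs[1:]
    rows = np.vstack([scaled, noise_sqrt.T])
    S = _qr_sqrt(rows)
    w0 = wc[0]
    if w0 != 0.0:
        S = cholupdate(S, np.sqrt(abs(w0)) * devs[0], sign=np.sign(w0))
    return S


def predict(
    state: FilterState,
    model: KineticModel,
    t_k: float,
    t_k1: float,
    *,
    rtol: float | None = None,
    atol: float | None = None,
) -> FilterState:
    """Time update: propagate sigma points through the discretized dynamics."""
    sp = make_sigma_points(state)
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    X = propagate_points(model, sp.points, t_k, t_k1, **kwargs)
    mean = sp.wm @ X
    devs = X - mean
    try:
        S = _sqrt_from_deviations(devs, sp.wc, state.sqrt_Q)
    except FilterDivergenceError as exc:
        raise FilterDivergenceError(f"predict at iteration {state.k}: {exc}") from exc
    mean = state.constraints.clip(mean)
    return replace(state, mean=mean, S=S, k=state.k)


def update(
    state: FilterState,
    y_k: np.ndarray,
    model: KineticModel,
    t_k: float,
    *,
    r_fn: Callable[[int, np.ndarray], np.ndarray] | None = None,
) -> tuple[FilterState, np.ndarray]:
    """Measurement update; returns the posterior state and the innovation.

    ``r_fn(k, y_pred) -> sqrt_R_k`` optionally rebuilds the measurement-noise
    factor from the *predicted* observation (signal-proportional noise uses
    the clean signal level, for which the filter's prediction is the
    estimate; using the noisy measurement itself would bias the weights).
    """
    y_k = np.atleast_1d(np.asarray(y_k, dtype=float))
    if y_k.shape != (model.n_obs,):
        raise ConfigError(f"observation has shape {y_k.shape}, expected ({model.n_obs},)")
    aug = AugmentedState(model)
    sp = make_sigma_points(state)
    Y = np.empty((len(sp.points), model.n_obs))
    for i, p in enumerate(sp.points):
        x, th = aug.split(p)
        Y[i] = np.atleast_1d(model.observe(x, model.full_theta(th), t_k))
    y_pred = sp.wm @ Y
    y_devs = Y - y_pred
    if r_fn is not None:
        state = replace(state, sqrt_R=np.atleast_2d(r_fn(state.k, y_pred)))
    try:
        Sy = _sqrt_from_deviations(y_devs, sp.wc, state.sqrt_R)
    except FilterDivergenceError as exc:
        raise FilterDivergenceError(
            f"innovation factor at iteration {state.k}: {exc}; "
            "consider inflating the measurement covariance R"
        ) from exc
    if np.any(np.abs(np.diag(Sy)) < 1e-300):
        raise FilterDivergenceError(
            f"singular innovation factor at iteration {state.k}; inflate R"
        )
    x_devs = sp.points - state.mean
    Pxy = (sp.wc[:, None] * x_devs).T @ y_devs
    # K = Pxy (Sy Syᵀ)⁻¹ via two triangular solves
    K = solve_triangular(
        Sy, solve_triangular(Sy, Pxy.T, lower=True), lower=True, trans="T"
    ).T
    innovation = y_k - y_pred
    mean = state.constraints.clip(state.mean + K @ innovation)
    U = K @ Sy
    S = state.S
    try:
        for j in range(U.shape[1]):
            S = cholupdate(S, U[:, j], sign=-1.0)
    except FilterDivergenceError as exc:
        raise FilterDivergenceError(f"update at iteration {state.k}: {exc}") from exc
    new_state = replace(state, mean=mean, S=S, k=state.k + 1)
    return new_state, innovation


# ---------------------------------------------------------------------------
# merit function
# ---------------------------------------------------------------------------


def merit_chi2(
    residuals: np.ndarray | Sequence[np.ndarray],
    R: np.ndarray | Sequence[np.ndarray],
) -> float:
    """Weighted sum of squared innovations  χ² = Σ_k r(k)ᵀ R⁻¹ r(k).

    ``R`` may be a single covariance used at every step or one per step.
    """
    residuals = [np.atleast_1d(np.asarray(r, dtype=float)) for r in residuals]
    if isinstance(R, np.ndarray) and R.ndim <= 2:
        R_list = [np.atleast_2d(np.asarray(R, dtype=float))] * len(residuals)
    else:
        R_list = [np.atleast_2d(np.asarray(Rk, dtype=float)) for Rk in R]
    if len(R_list) != len(residuals):
        raise ConfigError("R list length does not match residuals")
    total = 0.0
    for r, Rk in zip(residuals, R_list):
        if Rk.shape[0] != r.shape[0]:
            raise ConfigError("residual/R dimension mismatch")
        det = np.linalg.det(Rk)
        if det == 0 or not np.isfinite(det):
            raise ConfigError("singular measurement covariance R")
        total += float(r @ np.linalg.solve(Rk, r))
    return total


def proportional_nll(
    model: KineticModel,
    theta_est: np.ndarray | dict,
    data: TimeSeries,
    *,
    c: float = 0.2,
    floor: float = 1e-3,
    a_add: float = 0.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """−2 log-likelihood under signal-dependent Gaussian noise.

    The variance at each point is a_add² + (c · y_model)², floored at
    ``floor``²; because the variance depends on the parameters, the
    Gaussian normalization term Σ log σ² must be kept — dropping it (plain
    weighted least squares with model-based weights) systematically rewards
    inflating the predicted signal.  Additive constants are dropped.
    ``a_add > 0`` gives the mixed additive + proportional model.
    """
    from .models import simulate

    if isinstance(theta_est, dict):
        theta_est = np.array([theta_est[p] for p in model.estimated_params])
    sim = simulate(model, theta_est, data.times, full_theta=False, rtol=rtol, atol=atol)
    var = np.maximum(
        a_add**2 + (c * np.abs(sim.values)) ** 2, floor**2
    )
    r = data.values - sim.values
    return float(np.sum(r * r / var) + np.sum(np.log(var)))


def simulation_chi2(
    model: KineticModel,
    theta_est: np.ndarray | dict,
    data: TimeSeries,
    R: np.ndarray | Sequence[np.ndarray],
    *,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> float:
    """The χ² merit evaluated in predict-only form.

    The predicted observations ŷ⁻(k) are taken from the noise-free model
    trajectory at ``theta`` (a filter pass with no measurement corrections),
    so the merit is a deterministic function of the parameters — the form
    used as the profile-likelihood objective.
    """
    from .models import simulate

    sim = simulate(model, theta_est, data.times, full_theta=False, rtol=rtol, atol=atol)
    residuals = data.values - sim.values
    return merit_chi2(list(residuals), R)


# ---------------------------------------------------------------------------
# estimation driver
# ---------------------------------------------------------------------------


def initial_state(
    model: KineticModel,
    theta0: np.ndarray | dict,
    *,
    constraints: BoxConstraints | None = None,
    p0_state: float | np.ndarray = 0.01,
    p0_param: float | np.ndarray = 0.25,
    q_state: float | np.ndarray = 1e-7,
    q_param: float | np.ndarray = 1e-5,
    sqrt_R: np.ndarray | float = 0.1,
    ut: UTParams | None = None,
    sqrt_V0: np.ndarray | None = None,
    sqrt_Q0: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> FilterState:
    """Build a CSUKF initial state for ``model``.

    ``p0_*`` and ``q_*`` are *variances* on the diagonal of the initial
    estimation covariance and the process-noise covariance; full factors can
    be supplied instead via ``sqrt_V0`` / ``sqrt_Q0`` (e.g. from a
    :class:`~kinid.priors.PriorSpec`).
    """
    d, p = model.n_states, model.n_est
    if isinstance(theta0, dict):
        theta0 = np.array([theta0[name] for name in model.estimated_params])
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.shape != (p,):
        raise ConfigError(f"theta0 has shape {theta0.shape}, expected ({p},)")
    x_init = model.x0 if x0 is None else np.asarray(x0, dtype=float)
    mean = np.concatenate([x_init, theta0])
    if constraints is None:
        constraints = BoxConstraints.for_model(model)
    if sqrt_V0 is None:
        v = np.concatenate(
            [np.broadcast_to(p0_state, (d,)), np.broadcast_to(p0_param, (p,))]
        )
        sqrt_V0 = np.diag(np.sqrt(v))
    if sqrt_Q0 is None:
        q = np.concatenate(
            [np.broadcast_to(q_state, (d,)), np.broadcast_to(q_param, (p,))]
        )
        sqrt_Q0 = np.diag(np.sqrt(q))
    if np.isscalar(sqrt_R):
        sqrt_R = np.eye(model.n_obs) * float(sqrt_R)
    return FilterState(
        mean=constraints.clip(mean),
        S=np.asarray(sqrt_V0, dtype=float),
        sqrt_Q=np.asarray(sqrt_Q0, dtype=float),
        sqrt_R=np.asarray(sqrt_R, dtype=float),
        constraints=constraints,
        ut=ut or UTParams(),
    )


def _reset_state_block(state: FilterState, model: KineticModel, S0: np.ndarray) -> FilterState:
    """Start a new sweep: re-initialize the state block, keep the parameters."""
    d = model.n_states
    mean = state.mean.copy()
    mean[:d] = model.x0
    P = state.cov
    S_param = cholesky(P[d:, d:] + 1e-14 * np.eye(len(P) - d), lower=True)
    S_new = block_diag(S0[:d, :d], S_param)
    return replace(state, mean=state.constraints.clip(mean), S=S_new)


def estimate(
    model: KineticModel,
    data: TimeSeries,
    init: FilterState,
    *,
    passes: int = 1,
    max_passes: int | None = None,
    chi2_tol: float = 1e-6,
    r_fn: Callable[[int, np.ndarray], np.ndarray] | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> EstimationResult:
    """Run the CSUKF over a time series (optionally multiple sweeps).

    ``r_fn(k, y_pred_k) -> sqrt_R_k`` supplies a per-step measurement-noise
    factor built from the predicted observation (signal-proportional
    noise); otherwise ``init.sqrt_R`` is used
    throughout.  ``passes`` sweeps are always performed; when ``max_passes``
    exceeds ``passes``, further sweeps run until the merit changes by less
    than ``chi2_tol`` (iterated filtering).  Default: exactly ``passes``.
    """
    if tuple(data.observed_names) != tuple(model.observed_names):
        if set(data.observed_names) == set(model.observed_names):
            order = [data.observed_names.index(n) for n in model.observed_names]
            data = TimeSeries(
                data.times, data.values[:, order], model.observed_names, data.meta
            )
        else:
            raise ConfigError(
                f"data observes {data.observed_names}, model observes "
                f"{model.observed_names}"
            )
    S0 = init.S.copy()
    state = init
    prev_chi2 = np.inf
    chi2 = np.inf
    all_means = [init.mean.copy()]
    residuals: list[np.ndarray] = []
    R_list: list[np.ndarray] = []
    n_pass = 0
    max_passes = passes if max_passes is None else max(passes, max_passes)
    while True:
        n_pass += 1
        if n_pass > 1:
            state = _reset_state_block(state, model, S0)
        residuals.clear()
        R_list.clear()
        t_prev = 0.0
        for k, (t, y) in enumerate(zip(data.times, data.values)):
            try:
                if t > t_prev:  # a measurement at t == t_prev needs no predict
                    state = predict(state, model, t_prev, t, rtol=rtol, atol=atol)
                state, resid = update(state, y, model, t, r_fn=r_fn)
            except FilterDivergenceError as exc:
                raise FilterDivergenceError(
                    f"pass {n_pass}, step {k} (t={t}): {exc}"
                ) from exc
            residuals.append(resid)
            R_list.append(state.sqrt_R @ state.sqrt_R.T)
            all_means.append(state.mean.copy())
            t_prev = t
        chi2 = merit_chi2(residuals, R_list)
        if n_pass >= passes and abs(prev_chi2 - chi2) < chi2_tol:
            stop_reason = "chi2_stable"
            break
        if n_pass >= passes == max_passes:
            stop_reason = "requested_passes"
            break
        if n_pass >= max_passes:
            stop_reason = "max_passes"
            break
        prev_chi2 = chi2

    aug = AugmentedState(model)
    theta_final = dict(zip(model.estimated_params, aug.split(state.mean)[1]))
    return EstimationResult(
        means=np.array(all_means),
        final_S=state.S,
        residuals=np.array(residuals),
        R_list=list(R_list),
        final_theta=theta_final,
        merit=float(chi2),
        n_iters=n_pass,
        converged=stop_reason in ("chi2_stable", "requested_passes"),
        stop_reason=stop_reason,
        param_names=model.estimated_params,
    )


def iterated_estimate(
    model: KineticModel,
    data: TimeSeries,
    theta0: np.ndarray | dict,
    *,
    log_params: bool = False,
    n_anneal: int = 8,
    decay: float = 0.6,
    p0_param: float = 1.0,
    q_param: float = 1e-3,
    p0_state: float = 0.01,
    q_state: float = 1e-7,
    param_lower: float = 1e-8,
    param_upper: float = 100.0,
    r_fn: Callable[[int, np.ndarray], np.ndarray] | None = None,
    sqrt_R: np.ndarray | float = 0.1,
    ut: UTParams | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> EstimationResult:
    """Annealed repeated CSUKF sweeps converging on a point estimate.

    Each sweep restarts the filter at the previous sweep's final parameter
    mean while shrinking both the initial parameter uncertainty and the
    parameter process noise by ``decay`` — an iterated-filtering scheme
    whose fixed point is the maximum-likelihood parameter vector.  With
    ``log_params=True`` the sweeps run on the log scale (recommended when
    parameters span orders of magnitude); results are returned on the
    natural scale either way.
    """
    from .models import log_param_model

    work = log_param_model(model) if log_params else model
    p = model.n_est
    if isinstance(theta0, dict):
        theta0 = np.array([theta0[name] for name in model.estimated_params])
    theta0 = np.asarray(theta0, dtype=float)
    if log_params:
        theta0 = np.log(np.clip(theta0, param_lower, None))
        lo_p, hi_p = np.log(param_lower), np.log(param_upper)
    else:
        lo_p, hi_p = param_lower, param_upper
    d = work.n_states
    constraints = BoxConstraints(
        np.concatenate([np.zeros(d), np.full(p, lo_p)]),
        np.concatenate([np.full(d, np.inf), np.full(p, hi_p)]),
    )
    res: EstimationResult | None = None
    theta = theta0
    for sweep in range(max(1, n_anneal)):
        scale = decay**sweep
        init = initial_state(
            work,
            theta,
            constraints=constraints,
            p0_state=p0_state,
            p0_param=p0_param * scale,
            q_state=q_state,
            q_param=q_param * scale,
            sqrt_R=sqrt_R,
            ut=ut,
        )
        res = estimate(work, data, init, r_fn=r_fn, rtol=rtol, atol=atol)
        theta = res.final_theta_vector
    assert res is not None
    if log_params:
        final_nat = {k: float(np.exp(v)) for k, v in res.final_theta.items()}
        res = replace(res, final_theta=final_nat)
    return res


def multistart_estimate(
    model: KineticModel,
    data: TimeSeries,
    *,
    n_starts: int = 5,
    triage_sweeps: int = 4,
    polish_sweeps: int = 6,
    decay: float = 0.5,
    seed: int = 0,
    theta0_low: float = 0.01,
    theta0_high: float = 1.0,
    log_params: bool = True,
    p0_state: float = 1e-4,
    q_state: float = 1e-8,
    r_fn: Callable[[int, np.ndarray], np.ndarray] | None = None,
    sqrt_R: np.ndarray | float = 0.1,
    R_for_selection: Sequence[np.ndarray] | np.ndarray | None = None,
    rtol: float | None = 1e-6,
    atol: float | None = 1e-9,
    **kwargs,
) -> EstimationResult:
    """Multi-start annealed CSUKF estimation with χ²-based selection.

    Each start draws the initial parameter vector from
    Uniform(theta0_low, theta0_high) (the "small random values between 0
    and 1" initialization convention), runs ``triage_sweeps`` annealed
    sweeps, and is scored by the predict-only χ² merit; the best start is
    then annealed for ``polish_sweeps`` further sweeps.  Returns the
    polished estimate with the selection merit in ``merit``.
    """
    rng = np.random.default_rng(seed)
    p = model.n_est
    if R_for_selection is None:
        if r_fn is not None:
            R_for_selection = [
                np.atleast_2d(r_fn(k, y)) @ np.atleast_2d(r_fn(k, y)).T
                for k, y in enumerate(data.values)
            ]
        elif np.isscalar(sqrt_R):
            R_for_selection = np.eye(model.n_obs) * float(sqrt_R) ** 2
        else:
            sR = np.atleast_2d(sqrt_R)
            R_for_selection = sR @ sR.T

    best: EstimationResult | None = None
    best_chi2 = np.inf
    for _ in range(max(1, n_starts)):
        theta0 = rng.uniform(theta0_low, theta0_high, size=p)
        res = iterated_estimate(
            model, data, theta0,
            log_params=log_params, n_anneal=triage_sweeps, decay=decay,
            p0_state=p0_state, q_state=q_state,
            r_fn=r_fn, sqrt_R=sqrt_R, rtol=rtol, atol=atol, **kwargs,
        )
        chi2 = simulation_chi2(
            model, res.final_theta_vector, data, R_for_selection
        )
        if chi2 < best_chi2:
            best_chi2, best = chi2, res
    assert best is not None
    if polish_sweeps > 0:
        scale = decay**triage_sweeps
        res = iterated_estimate(
            model, data, best.final_theta_vector,
            log_params=log_params, n_anneal=polish_sweeps, decay=decay,
            p0_param=kwargs.get("p0_param", 1.0) * scale,
            q_param=kwargs.get("q_param", 1e-3) * scale,
            p0_state=p0_state, q_state=q_state,
            r_fn=r_fn, sqrt_R=sqrt_R, rtol=rtol, atol=atol,
        )
        chi2 = simulation_chi2(model, res.final_theta_vector, data, R_for_selection)
        if chi2 < best_chi2:
            best_chi2, best = chi2, res
    return replace(best, merit=float(best_chi2))
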