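"""Profile-likelihood identifiability analysis.

For each parameter of interest ψ the profile is the curve of the
re-optimized merit χ²(ψ) = min over nuisance parameters η of χ²(ψ, η),
traced by stepping ψ away from its optimum in both directions and
re-optimizing η with the CSUKF at every step (warm-started from the
neighbouring point).  The likelihood-ratio confidence region is the set
where χ²(ψ) − χ²(θ̂) stays below the χ² quantile Δ(α, m):

* crossing on both sides   -> identifiable, finite interval [σ⁻, σ⁺]
* crossing on one side     -> practically non-identifiable (open side ±∞)
* flat in both directions  -> structurally non-identifiable.

The merit is evaluated in predict-only form (the model trajectory at the
candidate parameters against the data, R-weighted) so that it is a
deterministic function of the parameters; the CSUKF supplies the nuisance
re-optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import iterated_estimate, simulation_chi2
from .models import ConfigError, KineticModel, TimeSeries

__all__ = [
    "ProfilePoint",
    "ProfileTrajectory",
    "SteppingPolicy",
    "chi2_threshold",
    "profile_parameter",
    "classify",
    "run_profiles",
    "run_identifiability",
    "trajectory_variability",
    "plot_profile",
]

#: flatness criterion: max Δχ² below this over >= 2 decades of ψ counts as flat
EPS_FLAT = 0.1


def chi2_threshold(alpha: float, df: int) -> float:
    """Likelihood-ratio confidence threshold Δ(α, m).

    The α-quantile of the χ² distribution with ``df`` degrees of freedom:
    Δ(0.95, 1) = 3.84 (pointwise), Δ(0.95, 12) = 21.03 (simultaneous for
    12 parameters).
    """
    if not 0.0 < alpha < 1.0:
        if alpha == 0.0:
            return 0.0
        raise ConfigError(f"confidence level must be in (0, 1), got {alpha}")
    if df < 1:
        raise ConfigError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.ppf(alpha, df))


@dataclass
class ProfilePoint:
    psi_value: float
    chi2: float
    eta_opt: dict  # nuisance parameter name -> re-optimized value
    ok: bool = True


@dataclass
class SteppingPolicy:
    """Adaptive multiplicative stepping in ψ.

    The step factor starts at ``step`` (ψ -> ψ·step upward, ψ/step
    downward); it is shrunk toward 1 when Δχ² jumps by more than
    ``max_jump`` between consecutive points and grown after ``smooth_run``
    consecutive smooth points.  Exploration stops on threshold crossing,
    on reaching a parameter bound, after ``max_steps``, or once the
    explored range spans ``flat_decades`` decades without the profile
    moving by more than the flatness tolerance (a flat profile).
    """

    step: float = 1.1
    max_jump: float = 1.0
    smooth_run: int = 5
    max_steps: int = 200
    #: flat span required per direction, in decades of ψ; one decade on each
    #: side of the optimum is a 100-fold overall range
    flat_decades: float = 1.0
    psi_lower: float = 1e-8
    psi_upper: float = 100.0
    eps_flat: float = EPS_FLAT


@dataclass
class ProfileTrajectory:
    param: str
    points_up: list  # ProfilePoints, increasing psi
    points_down: list  # ProfilePoints, decreasing psi
    chi2_min: float
    psi_hat: float
    threshold_pointwise: float
    threshold_simultaneous: float
    klass: str = ""  # identifiable | structural | practical
    ci: tuple = (-np.inf, np.inf)
    unreliable: bool = False

    def all_points(self) -> list:
        return list(reversed(self.points_down)) + self.points_up

    def to_frame(self) -> pd.DataFrame:
        pts = self.all_points()
        return pd.DataFrame(
            {
                "psi": [p.psi_value for p in pts],
                "chi2": [p.chi2 for p in pts],
                "ok": [p.ok for p in pts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _reoptimize(
    model: KineticModel,
    data: TimeSeries,
    param: str,
    psi: float,
    eta_start: dict,
    R,
    *,
    n_anneal: int,
    r_fn,
    sqrt_R,
    log_params: bool,
    p0_state: float,
    q_state: float,
    objective=None,
) -> tuple[float, dict, bool]:
    """Re-optimize nuisance parameters at fixed ψ; returns (χ², η̂, ok).

    ``objective(model, theta_est) -> χ²`` overrides the default fixed-R
    weighted-residual merit (e.g. the signal-proportional −2 log-likelihood).
    """
    fixed = model.fix(**{param: psi})
    if objective is None:
        objective = lambda mdl, th: simulation_chi2(mdl, th, data, R)  # noqa: E731
    if fixed.n_est == 0:
        chi2 = objective(fixed, np.array([]))
        return chi2, {}, True
    try:
        res = iterated_estimate(
            fixed,
            data,
            eta_start,
            log_params=log_params,
            n_anneal=n_anneal,
            decay=0.4,
            p0_param=0.04,
            q_param=1e-4,
            p0_state=p0_state,
            q_state=q_state,
            r_fn=r_fn,
            sqrt_R=sqrt_R,
            rtol=1e-6,
            atol=1e-9,
        )
        eta = dict(res.final_theta)
        chi2 = objective(fixed, res.final_theta_vector)
        return chi2, eta, True
    except Exception:  # noqa: BLE001 - a failed point is flagged, not fatal
        return np.inf, dict(eta_start), False


def profile_parameter(
    param: str,
    theta_hat: dict,
    model: KineticModel,
    data: TimeSeries,
    R,
    *,
    policy: SteppingPolicy | None = None,
    alpha: float = 0.95,
    n_total_params: int | None = None,
    reopt_anneal: int = 3,
    r_fn=None,
    sqrt_R: float | np.ndarray = 0.1,
    log_params: bool = True,
    p0_state: float = 1e-4,
    q_state: float = 1e-8,
    objective=None,
) -> ProfileTrajectory:
    """Trace the profile likelihood of one parameter in both directions.

    ``theta_hat`` is the fitted parameter dict (all estimated parameters);
    ``R`` the per-step (or constant) measurement covariance defining the
    merit.  The pointwise threshold Δ(α, 1) defines the CI endpoints by
    linear interpolation in ψ at the crossing.
    """
    policy = policy or SteppingPolicy()
    if param not in model.estimated_params:
        raise ConfigError(f"{param!r} is not an estimated parameter of {model.name!r}")
    psi_hat = float(theta_hat[param])
    eta_hat = {k: v for k, v in theta_hat.items() if k != param}
    m = n_total_params or model.n_est
    thr_point = chi2_threshold(alpha, 1)
    thr_simult = chi2_threshold(alpha, m)
    chi2_min, _, _ = _reoptimize(
        model, data, param, psi_hat, eta_hat, R,
        n_anneal=reopt_anneal, r_fn=r_fn, sqrt_R=sqrt_R,
        log_params=log_params, p0_state=p0_state, q_state=q_state,
        objective=objective,
    )

    def explore(direction: int) -> list:
        pts: list[ProfilePoint] = []
        step = policy.step
        psi = psi_hat
        eta = dict(eta_hat)
        prev_chi2 = chi2_min
        smooth = 0
        n_failed = 0
        for _ in range(policy.max_steps):
            psi = psi * step if direction > 0 else psi / step
            if psi > policy.psi_upper or psi < policy.psi_lower:
                break
            chi2, eta_new, ok = _reoptimize(
                model, data, param, psi, eta, R,
                n_anneal=reopt_anneal, r_fn=r_fn, sqrt_R=sqrt_R,
                log_params=log_params, p0_state=p0_state, q_state=q_state,
                objective=objective,
            )
            if not ok:
                n_failed += 1
                pts.append(ProfilePoint(psi, np.nan, dict(eta), ok=False))
                continue
            pts.append(ProfilePoint(psi, chi2, eta_new))
            eta = eta_new
            # a nuisance parameter pinned at its box bound means further
            # compensation is impossible: any rise past here is a
            # constraint artifact, so stop rather than record a false
            # threshold crossing
            if any(
                v <= policy.psi_lower * (1 + 1e-6) or v >= policy.psi_upper * (1 - 1e-6)
                for v in eta_new.values()
            ):
                break
            jump = abs(chi2 - prev_chi2)
            prev_chi2 = chi2
            if jump > policy.max_jump:
                step = 1.0 + (step - 1.0) / 2.0
                smooth = 0
            else:
                smooth += 1
                if smooth >= policy.smooth_run:
                    step = min(1.0 + (step - 1.0) * 2.0, 2.0)
                    smooth = 0
            if chi2 - chi2_min > thr_simult:
                break
            decades = abs(np.log10(psi / psi_hat))
            dchi = [p.chi2 - chi2_min for p in pts if p.ok]
            if decades >= policy.flat_decades and max(dchi, default=0.0) < policy.eps_flat:
                break
        return pts

    points_up = explore(+1)
    points_down = explore(-1)
    # the nuisance re-optimization may find a better optimum along the way;
    # the likelihood-ratio reference is the minimum over everything explored
    explored = [p.chi2 for p in points_up + points_down if p.ok]
    chi2_min = min([chi2_min, *explored])
    n_bad = sum(1 for p in points_up + points_down if not p.ok)
    n_all = max(1, len(points_up) + len(points_down))
    traj = ProfileTrajectory(
        param=param,
        points_up=points_up,
        points_down=points_down,
        chi2_min=chi2_min,
        psi_hat=psi_hat,
        threshold_pointwise=thr_point,
        threshold_simultaneous=thr_simult,
        unreliable=n_bad > 0.3 * n_all,
    )
    traj.klass = classify(traj)
    traj.ci = _confidence_interval(traj)
    return traj


def _crossing(points: list, chi2_min: float, thr: float, psi_hat: float) -> float | None:
    """ψ where Δχ² first crosses thr, linearly interpolated; None if no crossing."""
    prev_psi, prev_d = psi_hat, 0.0
    for p in points:
        if not p.ok:
            continue
        d = p.chi2 - chi2_min
        if d >= thr:
            if d == prev_d:
                return p.psi_value
            w = (thr - prev_d) / (d - prev_d)
            return prev_psi + w * (p.psi_value - prev_psi)
        prev_psi, prev_d = p.psi_value, d
    return None


def _is_flat(points: list, chi2_min: float, psi_hat: float, eps: float, decades: float) -> bool:
    ok_pts = [p for p in points if p.ok]
    if not ok_pts:
        return False
    span = max(abs(np.log10(p.psi_value / psi_hat)) for p in ok_pts)
    dmax = max(p.chi2 - chi2_min for p in ok_pts)
    return span >= decades and dmax < eps


def _confidence_interval(traj: ProfileTrajectory) -> tuple:
    up = _crossing(traj.points_up, traj.chi2_min, traj.threshold_pointwise, traj.psi_hat)
    dn = _crossing(traj.points_down, traj.chi2_min, traj.threshold_pointwise, traj.psi_hat)
    return (dn if dn is not None else -np.inf, up if up is not None else np.inf)


def classify(traj: ProfileTrajectory, *, eps_flat: float = EPS_FLAT, flat_decades: float = 1.0) -> str:
    """Identifiability class from a stored trajectory (pure function).

    Crossing the pointwise threshold on both sides -> ``identifiable``;
    on exactly one side -> ``practical``; on neither side, flat over the
    explored range -> ``structural``, otherwise ``practical`` (rising but
    too slowly to cross within the explored range).
    """
    if not traj.points_up and not traj.points_down:
        raise ConfigError(f"empty profile trajectory for {traj.param!r}")
    thr = traj.threshold_pointwise
    up = _crossing(traj.points_up, traj.chi2_min, thr, traj.psi_hat) is not None
    dn = _crossing(traj.points_down, traj.chi2_min, thr, traj.psi_hat) is not None
    if up and dn:
        return "identifiable"
    if up or dn:
        return "practical"
    flat_up = _is_flat(traj.points_up, traj.chi2_min, traj.psi_hat, eps_flat, flat_decades)
    flat_dn = _is_flat(traj.points_down, traj.chi2_min, traj.psi_hat, eps_flat, flat_decades)
    # tails clipped by a parameter bound before two decades still count as
    # explored; require low rise on whatever range was covered
    if not traj.points_up:
        flat_up = True
    if not traj.points_down:
        flat_dn = True
    if flat_up and flat_dn:
        return "structural"
    ok = [p for p in traj.points_up + traj.points_down if p.ok]
    dmax = max((p.chi2 - traj.chi2_min for p in ok), default=0.0)
    if dmax < eps_flat:
        return "structural"
    return "practical"


def run_profiles(
    model: KineticModel,
    data: TimeSeries,
    theta_hat: dict,
    R,
    params: list | None = None,
    **kwargs,
) -> dict:
    """Profile every requested parameter; returns {name: ProfileTrajectory}."""
    params = list(params or model.estimated_params)
    out = {}
    for p in params:
        out[p] = profile_parameter(p, theta_hat, model, data, R, **kwargs)
    return out


def trajectory_variability(
    model: KineticModel,
    traj: ProfileTrajectory,
    times: np.ndarray,
) -> dict:
    """State-trajectory envelope along a profile (measurement targeting).

    Simulates the model at every profile point's full parameter vector and
    returns, per state, the pointwise envelope width (max − min across
    profile points) over time, plus the (state, time) of largest width —
    the place where a new measurement would most efficiently pin down the
    parameter.
    """
    pts = [p for p in traj.all_points() if p.ok]
    names = model.state_names
    sims = []
    for p in pts:
        theta = dict(p.eta_opt)
        theta[traj.param] = p.psi_value
        try:
            full = model.full_theta(theta)
            # observe() may project; variability diagnosis wants raw states
            sims.append(_raw_states(model, full, times))
        except Exception:  # noqa: BLE001 - drop failing profile points
            continue
    if len(sims) < 2:
        width = np.zeros((len(times), len(names)))
    else:
        arr = np.array(sims)  # (n_pts, n_times, n_states)
        width = arr.max(axis=0) - arr.min(axis=0)
    flat = width.ravel()
    if flat.size and flat.max() > 0:
        i = int(np.argmax(flat))
        t_idx, s_idx = divmod(i, len(names))
        suggestion = {"state": names[s_idx], "time": float(times[t_idx])}
    else:
        suggestion = None
    return {
        "param": traj.param,
        "times": times,
        "state_names": names,
        "width": width,
        "suggestion": suggestion,
    }


def _raw_states(model: KineticModel, theta_full, times) -> np.ndarray:
    from scipy.integrate import solve_ivp

    t0 = min(0.0, times[0])
    t_eval = times if times[0] == t0 else np.concatenate([[t0], times])
    sol = solve_ivp(
        lambda t, x: np.asarray(model.rhs(x, theta_full, t), dtype=float),
        (t0, times[-1]),
        model.x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-7,
        atol=1e-9,
    )
    X = sol.y.T if times[0] == t0 else sol.y.T[1:]
    return X


def plot_profile(traj: ProfileTrajectory, path) -> None:
    """Write a profile-likelihood plot: χ² vs ψ (log axis) with the
    pointwise and simultaneous confidence thresholds as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [p for p in traj.all_points() if p.ok]
    psi = [p.psi_value for p in pts]
    chi2 = [p.chi2 for p in pts]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(psi, chi2, "-", color="C0", lw=1.5)
    ax.axvline(traj.psi_hat, color="0.6", lw=0.8, ls=":")
    for thr, label, style in (
        (traj.threshold_pointwise, "pointwise 95%", "--"),
        (traj.threshold_simultaneous, "simultaneous 95%", "-."),
    ):
        ax.axhline(traj.chi2_min + thr, color="0.3", lw=0.9, ls=style, label=label)
    ax.set_xscale("log")
    ax.set_xlabel(f"{traj.param}")
    ax.set_ylabel(r"$\chi^2$")
    ax.set_title(f"{traj.param}: {traj.klass}")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_identifiability(
    model: KineticModel,
    data: TimeSeries,
    theta_hat: dict,
    R,
    params: list | None = None,
    ranking=None,
    **kwargs,
):
    """Profile + classify every parameter and assemble the report.

    Returns an :class:`~kinid.relations.IdentifiabilityReport` with classes
    and confidence intervals (relations/correlations are filled in by the
    relation detectors or the full pipeline).
    """
    from .relations import IdentifiabilityReport

    profiles = run_profiles(model, data, theta_hat, R, params=params, **kwargs)
    report = IdentifiabilityReport(
        classes={p: t.klass for p, t in profiles.items()},
        cis={p: t.ci for p, t in profiles.items()},
        ranks={
            p: (ranking.rank_of(p) if ranking is not None else None)
            for p in profiles
        },
        chi2_min=min(t.chi2_min for t in profiles.values()),
        thresholds={
            "pointwise": next(iter(profiles.values())).threshold_pointwise,
            "simultaneous": next(iter(profiles.values())).threshold_simultaneous,
        },
    )
    return report, profiles
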