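"""Inter-parameter relationship detection and the identifiability report.

Two complementary detectors:

* linear correlations, read directly off the CSUKF's square-root
  covariance factor (corr_ij = P_ij / sqrt(P_ii P_jj) on the parameter
  block of P = S Sᵀ) — no Jacobian or Fisher-information approximation;
* non-linear functional relations via alternating conditional expectations
  (ACE): for a response parameter y and predictors x_1..x_p, ACE finds
  transformations maximizing the correlation of θ(y) with Σ φ_i(x_i); a
  bootstrap over co-optimized parameter samples (the MOTA scheme) scores
  each candidate predictor set by the mean and spread of the maximal
  correlation r².

The module also assembles the identifiability report: per-parameter class,
confidence interval and rank, detected relations, and ordered remedy
suggestions (measure the highest-ranked member of a relation, fix unranked
parameters to nominal values, add data where state trajectories vary most).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ConfigError

__all__ = [
    "CorrelationReport",
    "FunctionalRelation",
    "IdentifiabilityReport",
    "correlation_from_sqrt",
    "ace_maximal_correlation",
    "mota_detect",
    "suggest_remedies",
]

#: |corr| above this flags a strong linear relation
DEFAULT_TAU_CORR = 0.8


@dataclass
class CorrelationReport:
    corr: np.ndarray
    param_names: tuple
    flagged_pairs: list  # (name_i, name_j, corr_ij) with |corr| >= tau
    tau: float = DEFAULT_TAU_CORR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.corr, index=list(self.param_names), columns=list(self.param_names)
        )


@dataclass
class FunctionalRelation:
    response: str
    predictors: tuple
    r2_mean: float
    r2_std: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "r2_mean": float(self.r2_mean),
            "r2_std": float(self.r2_std),
            "significant": bool(self.significant),
        }


@dataclass
class IdentifiabilityReport:
    """Per-parameter identifiability outcome plus detected relations.

    The underlying definition is distributional: parameter sets Θ₁ ≠ Θ₂
    are non-identifiable when they induce the same observation
    distribution, p(X|Θ₁) = p(X|Θ₂).  The report records how each
    parameter fails or passes that criterion in practice (profile class
    and confidence interval), which relations between parameters explain
    the failures, and what to do about them.
    """

    classes: dict  # name -> identifiable | structural | practical
    cis: dict  # name -> (lo, hi)
    ranks: dict  # name -> int rank or None
    relations: list = field(default_factory=list)  # FunctionalRelations
    correlations: CorrelationReport | None = None
    suggestions: list = field(default_factory=list)
    chi2_min: float = np.nan
    thresholds: dict = field(default_factory=dict)

    def nonidentifiable(self) -> list:
        return [p for p, c in self.classes.items() if c != "identifiable"]

    def to_dict(self) -> dict:
        return {
            "classes": dict(self.classes),
            "cis": {k: [float(a), float(b)] for k, (a, b) in self.cis.items()},
            "ranks": {k: (None if v is None else int(v)) for k, v in self.ranks.items()},
            "relations": [r.to_dict() for r in self.relations],
            "correlation": None
            if self.correlations is None
            else self.correlations.to_frame().to_dict(),
            "suggestions": list(self.suggestions),
            "chi2_min": float(self.chi2_min),
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
        }


def correlation_from_sqrt(
    S: np.ndarray,
    param_names: tuple | list,
    n_states: int = 0,
    tau: float = DEFAULT_TAU_CORR,
) -> CorrelationReport:
    """Parameter correlation matrix from a square-root covariance factor.

    ``S`` is the (augmented) factor with P = S Sᵀ; the parameter block is
    the trailing ``len(param_names)`` rows/columns after ``n_states``.
    """
    S = np.asarray(S, dtype=float)
    P = S @ S.T
    p = len(param_names)
    block = P[n_states : n_states + p, n_states : n_states + p]
    var = np.diag(block)
    if np.any(var <= 0):
        raise ConfigError("zero variance in parameter block: degenerate filter state")
    denom = np.sqrt(np.outer(var, var))
    corr = block / denom
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    flagged = [
        (param_names[i], param_names[j], float(corr[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr[i, j]) >= tau
    ]
    return CorrelationReport(corr=corr, param_names=tuple(param_names), flagged_pairs=flagged, tau=tau)


# ---------------------------------------------------------------------------
# ACE — alternating conditional expectations
# ---------------------------------------------------------------------------


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based normal scores (van der Waerden transform)."""
    from scipy import stats as _st

    n = len(x)
    ranks = _st.rankdata(x)
    return _st.norm.ppf(ranks / (n + 1.0))


def _smooth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Conditional-expectation smoother: Nadaraya–Watson with Silverman
    bandwidth, applied on the normal-scores scale of x.

    Smoothing over rank-based scores makes the global bandwidth appropriate
    for arbitrary marginals, and leaves the maximal correlation exactly
    invariant under strictly monotone transforms of the variable (ranks are
    unchanged).
    """
    n = len(x)
    if np.std(x) == 0:
        return np.full(n, np.mean(y), dtype=float)
    xs = _normal_scores(x)
    h = 1.06 * np.std(xs) * n ** (-1 / 5)
    d = (xs[:, None] - xs[None, :]) / h
    w = np.exp(-0.5 * d * d)
    wsum = w.sum(axis=1)
    wsum[wsum == 0] = 1.0
    return (w @ y) / wsum


def ace_maximal_correlation(
    y: np.ndarray,
    X: np.ndarray,
    *,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, dict]:
    """Maximal correlation r² between transforms of y and of the predictors.

    Alternates θ(y) <- E[Σ φ_i | y] (normalized to unit variance) with
    φ_i <- E[θ(y) − Σ_{j≠i} φ_j | x_i] until the correlation stabilizes.
    Returns (r², transforms) where transforms holds the fitted θ and φ_i
    values at the sample points.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n != len(y):
        raise ConfigError("y and X sample sizes differ")
    if n < 30:
        raise ConfigError(f"ACE needs >= 30 samples, got {n}")
    if np.std(y) == 0 or np.any(np.std(X, axis=0) == 0):
        raise ConfigError("constant column passed to ACE")

    theta = (y - y.mean()) / y.std()
    phis = np.zeros((n, p))
    r2_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        for i in range(p):
            resid = theta - (phis.sum(axis=1) - phis[:, i])
            phis[:, i] = _smooth(X[:, i], resid)
            phis[:, i] -= phis[:, i].mean()
        total = phis.sum(axis=1)
        theta = _smooth(y, total)
        theta -= theta.mean()
        sd = theta.std()
        if sd == 0:
            break
        theta /= sd
        denom = total.std()
        r = float(np.corrcoef(theta, total)[0, 1]) if denom > 0 else 0.0
        r2 = r * r
        if abs(r2 - r2_prev) < tol:
            converged = True
            break
        r2_prev = r2
    transforms = {"theta": theta, "phi": phis, "converged": converged}
    total = phis.sum(axis=1)
    r = float(np.corrcoef(theta, total)[0, 1]) if total.std() > 0 else 0.0
    return r * r, transforms


# ---------------------------------------------------------------------------
# MOTA — bootstrap functional-relation detection
# ---------------------------------------------------------------------------


def mota_detect(
    samples: pd.DataFrame | np.ndarray,
    param_names: list | None = None,
    *,
    max_set: int = 3,
    B: int = 50,
    tau: float = 0.9,
    r2_std_max: float = 0.1,
    seed: int = 0,
) -> list:
    """Detect functional relations among co-optimized parameter samples.

    For every response parameter, predictor subsets are grown greedily
    (forward selection scored by ACE r²) up to ``max_set`` members; each
    candidate is evaluated on ``B`` bootstrap resamples and reported when
    the mean r² reaches ``tau`` with spread at most ``r2_std_max``.
    Minimal subsets are preferred: once a subset passes, its supersets are
    not reported.
    """
    if isinstance(samples, pd.DataFrame):
        names = list(samples.columns)
        data = samples.to_numpy(dtype=float)
    else:
        data = np.asarray(samples, dtype=float)
        names = list(param_names or [f"p{j}" for j in range(data.shape[1])])
    n, p = data.shape
    if n < 30:
        raise ConfigError(
            f"MOTA needs >= 30 parameter samples, got {n}; extend profiling "
            "or add repeated fits"
        )
    rng = np.random.default_rng(seed)
    boot_idx = [rng.integers(0, n, size=n) for _ in range(B)]

    def score(resp: int, preds: tuple) -> tuple[float, float]:
        r2s = np.empty(B)
        for b, idx in enumerate(boot_idx):
            yb = data[idx, resp]
            Xb = data[np.ix_(idx, list(preds))]
            if np.std(yb) == 0 or np.any(np.std(Xb, axis=0) == 0):
                r2s[b] = 0.0
                continue
            r2s[b], _ = ace_maximal_correlation(yb, Xb)
        return float(r2s.mean()), float(r2s.std())

    relations: list[FunctionalRelation] = []
    for resp in range(p):
        candidates = [j for j in range(p) if j != resp]
        chosen: list[int] = []
        best_stats: tuple[float, float] | None = None
        while len(chosen) < max_set and candidates:
            scored = []
            for j in candidates:
                stats_ = score(resp, tuple(chosen + [j]))
                scored.append((stats_[0], j, stats_))
            scored.sort(reverse=True)
            _, j_best, stats_best = scored[0]
            if best_stats is not None and stats_best[0] <= best_stats[0] + 1e-3:
                break  # no improvement from growing the set
            chosen.append(j_best)
            candidates.remove(j_best)
            best_stats = stats_best
            if stats_best[0] >= tau and stats_best[1] <= r2_std_max:
                break  # minimal passing subset found
        if chosen and best_stats is not None:
            significant = best_stats[0] >= tau and best_stats[1] <= r2_std_max
            if significant:
                relations.append(
                    FunctionalRelation(
                        response=names[resp],
                        predictors=tuple(names[j] for j in chosen),
                        r2_mean=best_stats[0],
                        r2_std=best_stats[1],
                        significant=True,
                    )
                )
    return relations


# ---------------------------------------------------------------------------
# remedies
# ---------------------------------------------------------------------------


def suggest_remedies(
    report: IdentifiabilityReport,
    ranking,
    variability: dict | None = None,
) -> list:
    """Ordered remedy suggestions for the non-identifiable parameters.

    * parameters in a detected relation: measure the highest-ranked member;
    * ranking-unranked parameters with no relation: fix to a nominal value;
    * practically non-identifiable parameters with a variability hotspot:
      add/refine measurements of that state near that time.
    Ordered by rank priority (rank 1 first, unranked last).
    """
    ni = set(report.nonidentifiable())
    suggestions: list[dict] = []

    def rank_key(p: str):
        r = ranking.rank_of(p) if ranking is not None else None
        return (0, r) if r is not None else (1, 0)

    for rel in report.relations:
        members = {rel.response, *rel.predictors}
        if not members & ni:
            continue
        target = min(members, key=rank_key)
        suggestions.append(
            {
                "action": "measure_parameter",
                "parameter": target,
                "reason": f"functional relation {rel.response} ~ {rel.predictors}; "
                f"measuring the highest-ranked member resolves the group",
            }
        )
    if report.correlations is not None:
        for a, b, c in report.correlations.flagged_pairs:
            if {a, b} & ni:
                target = min((a, b), key=rank_key)
                suggestions.append(
                    {
                        "action": "measure_parameter",
                        "parameter": target,
                        "reason": f"strong linear correlation corr({a},{b})={c:.2f}",
                    }
                )
    if ranking is not None:
        for p in ranking.unranked:
            if p in ni and not any(
                s["parameter"] == p for s in suggestions if "parameter" in s
            ):
                suggestions.append(
                    {
                        "action": "fix_to_nominal",
                        "parameter": p,
                        "reason": "below ranking threshold: output nearly "
                        "insensitive, fixing has minimal effect",
                    }
                )
    if variability:
        for p, var in variability.items():
            if p in ni and report.classes.get(p) == "practical" and var.get("suggestion"):
                s = var["suggestion"]
                suggestions.append(
                    {
                        "action": "add_measurements",
                        "parameter": p,
                        "state": s["state"],
                        "time": s["time"],
                        "reason": "largest state-trajectory variability along "
                        "the profile",
                    }
                )
    seen = set()
    unique = []
    for s in suggestions:
        key = (s["action"], s.get("parameter"), s.get("state"))
        if key not in seen:
            seen.add(key)
            unique.append(s)
    unique.sort(key=lambda s: rank_key(s.get("parameter", "")))
    for p in ni:
        if not any(s.get("parameter") == p for s in unique):
            unique.append(
                {
                    "action": "none",
                    "parameter": p,
                    "reason": "no relation found; consider informed-prior estimation",
                }
            )
    return unique
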