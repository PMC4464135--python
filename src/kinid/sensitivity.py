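"""Scaled sensitivity matrix and orthogonal parameter ranking.

The sensitivity of output ``x_i`` (a (time, output) pair) to parameter
``theta_j`` is the partial derivative ``dx_i/dtheta_j``, scaled by
``theta_j / x_i`` so that columns are comparable across parameters and
outputs of different magnitudes (a relative/logarithmic sensitivity).

Ranking proceeds greedily: the column with the largest Euclidean norm is
ranked first; at each later step every remaining column is regressed onto
the span of the already-selected columns and the column with the largest
residual norm — the largest influence *orthogonal* to what is already
explained — is ranked next.  When the best residual norm falls below a
threshold the remaining parameters are left unranked: their effect on the
output is numerically indistinguishable from a linear combination of
higher-ranked parameters, which flags them as candidates for
non-identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ConfigError, KineticModel, simulate

__all__ = [
    "SensitivityMatrix",
    "RankingResult",
    "compute_sensitivities",
    "rank_parameters",
    "aggregate_rankings",
]

#: ranking stop threshold on the residual column norm
DEFAULT_RANK_THRESHOLD = 0.004
#: floor used when scaling by an output value that is (near) zero
EPS_SCALE = 1e-12


@dataclass
class SensitivityMatrix:
    """Scaled sensitivity coefficients, rows = (time, output), cols = parameters."""

    Z: np.ndarray
    row_labels: list  # (time, output-name) pairs
    param_names: tuple
    theta_hat: np.ndarray
    x_hat: np.ndarray  # flattened output values used for scaling
    Z_raw: np.ndarray  # unscaled partials dx_i/dtheta_j

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.row_labels, names=["time", "output"])
        return pd.DataFrame(self.Z, index=idx, columns=list(self.param_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class RankingResult:
    """Greedy orthogonal ranking outcome."""

    ranked: list  # parameter names, rank 1 first
    residual_norms: list  # residual norm accepted at each rank step
    unranked: list
    threshold: float = DEFAULT_RANK_THRESHOLD

    def rank_of(self, name: str) -> int | None:
        """1-based rank, or None when unranked."""
        return self.ranked.index(name) + 1 if name in self.ranked else None

    def to_dict(self) -> dict:
        return {
            "ranked": list(self.ranked),
            "residual_norms": [float(r) for r in self.residual_norms],
            "unranked": list(self.unranked),
            "threshold": float(self.threshold),
        }


def compute_sensitivities(
    model: KineticModel,
    theta_hat: np.ndarray | dict,
    times: np.ndarray,
    *,
    rel_step: float = 1e-6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SensitivityMatrix:
    """Central-finite-difference scaled sensitivities of all outputs.

    ``theta_hat`` covers the estimated parameters.  Each parameter is
    perturbed by ``rel_step`` relative to its value (absolute step
    ``rel_step`` when the value is zero).  Scaling divides by the nominal
    output, floored at ``EPS_SCALE`` in magnitude to keep rows finite when
    an output passes through zero.
    """
    if isinstance(theta_hat, dict):
        theta_hat = np.array([theta_hat[p] for p in model.estimated_params])
    theta_hat = np.asarray(theta_hat, dtype=float)
    params = model.estimated_params
    if theta_hat.shape != (len(params),):
        raise ConfigError(
            f"theta_hat has shape {theta_hat.shape}, expected ({len(params)},)"
        )
    base = simulate(model, theta_hat, times, full_theta=False, rtol=rtol, atol=atol)
    x_hat = base.values.ravel()  # row-major: time-major, output-minor
    n_rows = x_hat.size
    Z_raw = np.empty((n_rows, len(params)))
    for j, p in enumerate(params):
        h = rel_step * abs(theta_hat[j]) if theta_hat[j] != 0 else rel_step
        up = theta_hat.copy()
        dn = theta_hat.copy()
        up[j] += h
        dn[j] -= h
        y_up = simulate(model, up, times, full_theta=False, rtol=rtol, atol=atol)
        y_dn = simulate(model, dn, times, full_theta=False, rtol=rtol, atol=atol)
        Z_raw[:, j] = (y_up.values.ravel() - y_dn.values.ravel()) / (2 * h)
    sign = np.where(x_hat < 0, -1.0, 1.0)
    denom = sign * np.maximum(np.abs(x_hat), EPS_SCALE)
    Z = Z_raw * theta_hat[None, :] / denom[:, None]
    row_labels = [(t, name) for t in times for name in model.observed_names]
    return SensitivityMatrix(
        Z=Z,
        row_labels=row_labels,
        param_names=params,
        theta_hat=theta_hat,
        x_hat=x_hat,
        Z_raw=Z_raw,
    )


def rank_parameters(
    Z: SensitivityMatrix | np.ndarray,
    threshold: float = DEFAULT_RANK_THRESHOLD,
    param_names: Sequence[str] | None = None,
) -> RankingResult:
    """Greedy orthogonal ranking of sensitivity columns.

    Step 1 selects the column of largest Euclidean norm; each later step
    projects all columns onto the span of the selected ones (via
    pseudo-inverse, robust to rank deficiency) and selects the largest
    residual-norm column.  Stops when that norm drops below ``threshold``.
    """
    if isinstance(Z, SensitivityMatrix):
        mat = Z.Z
        names = list(Z.param_names)
    else:
        mat = np.asarray(Z, dtype=float)
        if param_names is None:
            names = [f"p{j}" for j in range(mat.shape[1])]
        else:
            names = list(param_names)
    if mat.size == 0:
        raise ConfigError("empty sensitivity matrix")
    remaining = list(range(mat.shape[1]))
    selected: list[int] = []
    residual_norms: list[float] = []
    while remaining:
        if not selected:
            resid = mat
        else:
            X = mat[:, selected]
            proj = X @ np.linalg.pinv(X)
            resid = mat - proj @ mat
        norms = np.linalg.norm(resid[:, remaining], axis=0)
        best = int(np.argmax(norms))
        if norms[best] < threshold:
            break
        selected.append(remaining.pop(best))
        residual_norms.append(float(norms[best]))
    return RankingResult(
        ranked=[names[i] for i in selected],
        residual_norms=residual_norms,
        unranked=[names[i] for i in remaining],
        threshold=threshold,
    )


def aggregate_rankings(runs: Sequence[RankingResult]) -> RankingResult:
    """Average-rank aggregation over repeated runs.

    Unranked occurrences count as (worst rank + 1).  A parameter unranked
    in more than half of the runs stays unranked in the aggregate.  Ties in
    average rank break lexicographically by parameter name.
    """
    runs = list(runs)
    if not runs:
        raise ConfigError("no ranking runs to aggregate")
    all_params = sorted(set(runs[0].ranked) | set(runs[0].unranked))
    for r in runs[1:]:
        if sorted(set(r.ranked) | set(r.unranked)) != all_params:
            raise ConfigError("rankings cover different parameter sets")
    n_params = len(all_params)
    avg: dict[str, float] = {}
    unranked_count: dict[str, int] = {p: 0 for p in all_params}
    for p in all_params:
        positions = []
        for r in runs:
            pos = r.rank_of(p)
            if pos is None:
                unranked_count[p] += 1
                pos = n_params + 1  # worst + 1
            positions.append(pos)
        avg[p] = float(np.mean(positions))
    majority_unranked = {p for p in all_params if unranked_count[p] * 2 > len(runs)}
    ordered = sorted(
        (p for p in all_params if p not in majority_unranked),
        key=lambda p: (avg[p], p),
    )
    return RankingResult(
        ranked=ordered,
        residual_norms=[avg[p] for p in ordered],
        unranked=sorted(majority_unranked),
        threshold=runs[0].threshold,
    )
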