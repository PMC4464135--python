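"""Scaled sensitivities and orthogonal ranking."""

import numpy as np
import pytest

from kinid.models import ConfigError, KineticModel
from kinid.sensitivity import (
    RankingResult,
    aggregate_rankings,
    compute_sensitivities,
    rank_parameters,
)


def linear_growth_model():
    """x(t) = theta * t observed directly (dx/dt = theta)."""
    return KineticModel(
        name="lin_growth",
        rhs=lambda x, th, t: np.array([th[0]]),
        observe=lambda x, th, t: x,
        state_names=("x",),
        param_names=("theta",),
        observed_names=("x",),
        x0=np.array([0.0]),
        theta_true=np.array([2.0]),
    )


def decay_model():
    return KineticModel(
        name="decay",
        rhs=lambda x, th, t: -th[0] * x,
        observe=lambda x, th, t: x,
        state_names=("x",),
        param_names=("theta",),
        observed_names=("x",),
        x0=np.array([1.0]),
        theta_true=np.array([0.7]),
    )


class TestComputeSensitivities:
    def test_linear_growth_scaled_entries_are_one(self):
        """(dx/dtheta)(theta/x) = t * theta / (theta t) = 1 at every time."""
        m = linear_growth_model()
        Z = compute_sensitivities(m, np.array([2.0]), np.linspace(0.5, 5, 10))
        assert np.allclose(Z.Z, 1.0, atol=1e-5)

    def test_exponential_decay_scaled_is_minus_theta_t(self):
        """x = e^{-theta t}: (dx/dtheta)(theta/x) = -theta t."""
        m = decay_model()
        times = np.linspace(0.2, 3.0, 8)
        theta = 0.7
        Z = compute_sensitivities(m, np.array([theta]), times)
        assert np.allclose(Z.Z[:, 0], -theta * times, rtol=1e-4)

    def test_matches_forward_sensitivity_ode(self, mm_model):
        """Finite differences vs the forward sensitivity ODE system."""
        from scipy.integrate import solve_ivp

        vmax, km = mm_model.theta_true
        times = np.linspace(50, 1000, 6)

        def rhs(t, z):
            s, p, dsv, dpv, dsk, dpk = z
            den = km + s
            v = vmax * s / den
            dv_ds = vmax * km / den**2
            dv_dvmax = s / den
            dv_dkm = -vmax * s / den**2
            return [
                -v, v,
                -(dv_dvmax + dv_ds * dsv), (dv_dvmax + dv_ds * dsv),
                -(dv_dkm + dv_ds * dsk), (dv_dkm + dv_ds * dsk),
            ]

        sol = solve_ivp(rhs, (0, times[-1]), [1.0, 1.0, 0, 0, 0, 0],
                        t_eval=times, rtol=1e-10, atol=1e-12, method="LSODA")
        Z = compute_sensitivities(mm_model, mm_model.theta_true, times)
        # unscaled partials, rows ordered (time, output)
        raw = Z.Z_raw.reshape(len(times), 2, 2)  # (time, output, param)
        ode = np.stack([
            np.stack([sol.y[2], sol.y[4]], axis=1),  # dS/d(Vmax, Km)
            np.stack([sol.y[3], sol.y[5]], axis=1),  # dP/d(Vmax, Km)
        ], axis=1)
        assert np.allclose(raw, ode, atol=1e-4)

    def test_scale_invariance_of_scaled_columns(self, mm_model):
        """Rescaling a parameter's unit leaves its scaled column unchanged."""
        import dataclasses

        times = np.linspace(100, 800, 5)
        Z1 = compute_sensitivities(mm_model, mm_model.theta_true, times)

        scaled = dataclasses.replace(
            mm_model,
            rhs=lambda x, th, t: mm_model.rhs(x, np.array([th[0] / 10.0, th[1]]), t),
            theta_true=np.array([mm_model.theta_true[0] * 10, mm_model.theta_true[1]]),
        )
        Z2 = compute_sensitivities(scaled, scaled.theta_true, times)
        assert np.allclose(Z1.Z, Z2.Z, rtol=1e-4)


class TestRankParameters:
    def test_identical_columns_one_ranked_one_not(self):
        col = np.full(10, 10 / np.sqrt(10))
        Z = np.stack([col, col], axis=1)
        r = rank_parameters(Z, threshold=0.004, param_names=["a", "b"])
        assert len(r.ranked) == 1 and len(r.unranked) == 1

    def test_orthogonal_columns_ranked_by_norm(self):
        Z = np.diag([3.0, 1.0, 2.0])
        r = rank_parameters(Z, threshold=0.0, param_names=["a", "b", "c"])
        assert r.ranked == ["a", "c", "b"]
        assert r.residual_norms == [3.0, 2.0, 1.0]

    def test_planted_collinear_block_left_unranked(self):
        """12 columns, 3 of them linear combinations of the rest -> 9 + 3 N.I."""
        rng = np.random.default_rng(0)
        base = rng.standard_normal((60, 9))
        mix = rng.standard_normal((9, 3))
        dep = base @ mix * 0.1
        Z = np.hstack([base, dep + 1e-9 * rng.standard_normal(dep.shape)])
        names = [f"p{j}" for j in range(12)]
        r = rank_parameters(Z, threshold=0.004, param_names=names)
        assert len(r.ranked) == 9
        assert sorted(r.unranked) == ["p10", "p11", "p9"]

    def test_matches_bruteforce_qr_greedy(self):
        """Greedy pinv-projection selection equals explicit QR residuals."""
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((30, 5))
        r = rank_parameters(Z, threshold=0.0)
        # brute force: recompute residual norms with QR at every step
        cols = list(range(5))
        chosen = []
        while cols:
            best, best_norm = None, -1.0
            for j in cols:
                if chosen:
                    q, _ = np.linalg.qr(Z[:, chosen])
                    resid = Z[:, j] - q @ (q.T @ Z[:, j])
                else:
                    resid = Z[:, j]
                nrm = np.linalg.norm(resid)
                if nrm > best_norm:
                    best, best_norm = j, nrm
            chosen.append(best)
            cols.remove(best)
        assert r.ranked == [f"p{j}" for j in chosen]

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((20, 4))
        assert rank_parameters(Z).ranked == rank_parameters(Z).ranked

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigError):
            rank_parameters(np.empty((0, 0)))


class TestAggregateRankings:
    def r(self, ranked, unranked=()):
        return RankingResult(ranked=list(ranked), residual_norms=[1.0] * len(ranked),
                             unranked=list(unranked))

    def test_identical_runs_unchanged(self):
        runs = [self.r(["a", "b", "c"])] * 3
        agg = aggregate_rankings(runs)
        assert agg.ranked == ["a", "b", "c"]

    def test_tie_broken_lexicographically(self):
        agg = aggregate_rankings([self.r(["a", "b"]), self.r(["b", "a"])])
        assert agg.ranked == ["a", "b"]

    def test_majority_unranked_stays_unranked(self):
        runs = [self.r(["a"], unranked=["b"])] * 30 + [self.r(["a", "b"])] * 20
        agg = aggregate_rankings(runs)
        assert agg.unranked == ["b"]

    def test_minority_unranked_gets_ranked(self):
        runs = [self.r(["a"], unranked=["b"])] * 20 + [self.r(["a", "b"])] * 30
        agg = aggregate_rankings(runs)
        assert "b" in agg.ranked

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_rankings([])
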