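"""CSUKF: sigma points, square-root algebra, filter oracles, estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinid.filtering import (
    BoxConstraints,
    FilterState,
    UTParams,
    cholupdate,
    estimate,
    initial_state,
    iterated_estimate,
    make_sigma_points,
    merit_chi2,
    predict,
    simulation_chi2,
    update,
)
from kinid.models import ConfigError, KineticModel, TimeSeries, simulate


def linear_model(a: float = 0.9):
    """Continuous model whose unit-step discretization is x -> a*x exactly."""
    return KineticModel(
        name="linear",
        rhs=lambda x, th, t: np.log(a) * x,
        observe=lambda x, th, t: np.asarray(x),
        state_names=("x",),
        param_names=(),
        observed_names=("x",),
        x0=np.array([1.0]),
    )


def make_state(mean, S, *, sqrt_Q=None, sqrt_R=None, constraints=None, ut=None):
    n = len(mean)
    return FilterState(
        mean=np.asarray(mean, float),
        S=np.atleast_2d(S).astype(float),
        sqrt_Q=np.zeros((n, n)) if sqrt_Q is None else np.atleast_2d(sqrt_Q),
        sqrt_R=np.eye(1) if sqrt_R is None else np.atleast_2d(sqrt_R),
        constraints=constraints or BoxConstraints.unbounded(n),
        ut=ut or UTParams(),
    )


class TestCholupdate:
    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_matches_direct_factorization(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 4))
        P = A @ A.T + 4 * np.eye(4)
        S = np.linalg.cholesky(P)
        v = rng.standard_normal(4)
        up = cholupdate(S, v, +1.0)
        assert np.allclose(up @ up.T, P + np.outer(v, v), atol=1e-10)
        dn = cholupdate(S, 0.5 * v, -1.0)
        assert np.allclose(dn @ dn.T, P - 0.25 * np.outer(v, v), atol=1e-10)

    def test_downdate_losing_pd_raises(self):
        from kinid.filtering import FilterDivergenceError

        S = np.eye(2)
        with pytest.raises(FilterDivergenceError):
            cholupdate(S, np.array([2.0, 0.0]), -1.0)


class TestSigmaPoints:
    def test_hand_computed_scalar_case(self):
        """n=1, alpha=1, beta=0, kappa=2: points {0, +sqrt3, -sqrt3}, wm={2/3,1/6,1/6}."""
        st_ = make_state([0.0], [[1.0]], ut=UTParams(alpha=1.0, beta=0.0, kappa=2.0))
        sp = make_sigma_points(st_)
        assert np.allclose(sorted(sp.points.ravel()), [-np.sqrt(3), 0, np.sqrt(3)])
        assert np.allclose(sp.wm, [2 / 3, 1 / 6, 1 / 6])
        # beta=0, alpha=1: wc equals wm here
        assert np.allclose(sp.wc, sp.wm)

    def test_constrained_point_lands_on_boundary(self):
        """Lower point 0.5 - sqrt(3) < 0 is pulled back exactly to 0."""
        cons = BoxConstraints(np.array([0.0]), np.array([np.inf]))
        st_ = make_state([0.5], [[1.0]], constraints=cons, ut=UTParams(alpha=1.0, beta=0.0, kappa=2.0))
        sp = make_sigma_points(st_)
        assert np.min(sp.points) == pytest.approx(0.0, abs=1e-15)
        assert np.isclose(sp.wm.sum(), 1.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_weights_sum_to_one_with_random_boxes(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 5)
        mean = rng.uniform(0.2, 0.8, n)
        lo = mean - rng.uniform(0.05, 0.5, n)
        hi = mean + rng.uniform(0.05, 0.5, n)
        A = rng.standard_normal((n, n)) * 0.3
        S = np.linalg.cholesky(A @ A.T + 0.01 * np.eye(n))
        st_ = make_state(mean, S, constraints=BoxConstraints(lo, hi))
        sp = make_sigma_points(st_)
        assert np.isclose(sp.wm.sum(), 1.0)
        assert np.all(sp.points >= lo - 1e-12) and np.all(sp.points <= hi + 1e-12)


class TestLinearGaussianOracle:
    def make_data(self, a, Q, R, n_steps, seed):
        rng = np.random.default_rng(seed)
        x = 1.0
        ys = []
        for _ in range(n_steps):
            x = a * x + rng.normal(0, np.sqrt(Q))
            ys.append(x + rng.normal(0, np.sqrt(R)))
        return TimeSeries(np.arange(1.0, n_steps + 1), np.array(ys)[:, None], ("x",))

    def analytic_kf(self, ys, a, Q, R, m0=1.0, P0=1.0):
        m, P = m0, P0
        means, covs = [], []
        for y in ys:
            m, P = a * m, a * P * a + Q
            K = P / (P + R)
            m, P = m + K * (y - m), (1 - K) * P
            means.append(m)
            covs.append(P)
        return np.array(means), np.array(covs)

    def test_matches_closed_form_kalman_filter(self):
        """Unconstrained CSUKF equals the analytic KF on a linear system."""
        a, Q, R = 0.9, 0.01, 0.04
        data = self.make_data(a, Q, R, 50, seed=0)
        m = linear_model(a)
        init = initial_state(
            m, np.array([]), constraints=BoxConstraints.unbounded(1),
            p0_state=1.0, q_state=Q, sqrt_R=np.array([[np.sqrt(R)]]),
        )
        res = estimate(m, data, init)
        means, covs = self.analytic_kf(data.values.ravel(), a, Q, R)
        assert np.max(np.abs(res.means[1:, 0] - means)) < 1e-6
        assert abs(res.final_S[0, 0] ** 2 - covs[-1]) < 1e-6

    def test_matches_full_covariance_ukf(self):
        """Square-root propagation equals a plain-covariance UKF (oracle)."""
        a, Q, R = 0.8, 0.02, 0.05
        data = self.make_data(a, Q, R, 30, seed=4)
        m = linear_model(a)
        init = initial_state(
            m, np.array([]), constraints=BoxConstraints.unbounded(1),
            p0_state=0.5, q_state=Q, sqrt_R=np.array([[np.sqrt(R)]]),
        )
        res = estimate(m, data, init)

        # independent full-covariance UKF with the same UT weights
        n = 1
        ut = UTParams()
        kappa = ut.resolved_kappa(n)
        lam = ut.alpha**2 * (n + kappa) - n
        g = np.sqrt(n + lam)
        wm = np.array([lam / (n + lam), 1 / (2 * (n + lam)), 1 / (2 * (n + lam))])
        wc = wm.copy()
        wc[0] += 1 - ut.alpha**2 + ut.beta
        x, P = 1.0, 0.5
        for y in data.values.ravel():
            s = np.sqrt(P)
            pts = np.array([x, x + g * s, x - g * s])
            pts = a * pts  # exact propagation of the linear map
            xm = wm @ pts
            Pm = wc @ (pts - xm) ** 2 + Q
            s2 = np.sqrt(Pm)
            pts2 = np.array([xm, xm + g * s2, xm - g * s2])
            ym = wm @ pts2
            Pyy = wc @ (pts2 - ym) ** 2 + R
            Pxy = wc @ ((pts2 - xm) * (pts2 - ym))
            K = Pxy / Pyy
            x = xm + K * (y - ym)
            P = Pm - K * Pyy * K
        assert abs(res.means[-1, 0] - x) < 1e-6
        assert abs(res.final_S[0, 0] ** 2 - P) < 1e-6


class TestPredictUpdate:
    def test_zero_field_zero_noise_is_identity(self):
        from kinid.fixtures import make_model

        m = make_model("constant")
        init = initial_state(
            m, np.array([]), constraints=BoxConstraints.unbounded(2),
            p0_state=0.1, q_state=0.0, sqrt_R=np.eye(2),
        )
        out = predict(init, m, 0.0, 1.0)
        assert np.allclose(out.mean, init.mean)
        assert np.allclose(out.S @ out.S.T, init.S @ init.S.T, atol=1e-10)

    def test_parameter_mean_invariant_under_predict(self, mm_model):
        """Zero parameter dynamics: predicted theta mean equals the prior
        mean whenever no box constraint clips the parameter sigma points."""
        init = initial_state(mm_model, np.array([0.4, 0.6]), p0_param=0.01)
        out = predict(init, mm_model, 0.0, 10.0)
        assert np.allclose(out.mean[2:], init.mean[2:], atol=1e-12)

    def test_huge_R_keeps_prior(self):
        m = linear_model(1.0)
        init = initial_state(
            m, np.array([]), constraints=BoxConstraints.unbounded(1),
            p0_state=0.2, q_state=0.0, sqrt_R=np.array([[1e6]]),
        )
        post, innov = update(init, np.array([5.0]), m, 0.0)
        assert abs(post.mean[0] - init.mean[0]) < 1e-6

    def test_scalar_linear_update_matches_textbook(self):
        m = linear_model(1.0)
        P0, R, y = 0.5, 0.1, 2.0
        init = initial_state(
            m, np.array([]), constraints=BoxConstraints.unbounded(1),
            p0_state=P0, q_state=0.0, sqrt_R=np.array([[np.sqrt(R)]]),
        )
        post, innov = update(init, np.array([y]), m, 0.0)
        K = P0 / (P0 + R)
        assert abs(post.mean[0] - (1.0 + K * (y - 1.0))) < 1e-8
        assert abs(post.S[0, 0] ** 2 - (1 - K) * P0) < 1e-8
        assert innov[0] == pytest.approx(y - 1.0, abs=1e-10)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 999))
    def test_posterior_mean_respects_tight_boxes(self, seed, mm_model):
        rng = np.random.default_rng(seed)
        lo = np.array([0.0, 0.0, 1e-4, 1e-4])
        hi = np.array([2.0, 2.0, 0.5, 0.5])
        init = initial_state(
            mm_model, rng.uniform(1e-4, 0.5, 2),
            constraints=BoxConstraints(lo, hi), sqrt_R=np.eye(2) * 0.1,
        )
        state = predict(init, mm_model, 0.0, 20.0)
        y = rng.uniform(0, 2, 2)
        post, _ = update(state, y, mm_model, 20.0)
        assert np.all(post.mean >= lo) and np.all(post.mean <= hi)


class TestMerit:
    def test_zero_residuals_zero_merit(self):
        assert merit_chi2([np.zeros(2)] * 5, np.eye(2)) == 0.0

    def test_hand_computed_scalar(self):
        assert merit_chi2([np.array([2.0])], np.array([[4.0]])) == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_equals_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        res = [rng.standard_normal(3) for _ in range(7)]
        A = rng.standard_normal((3, 3))
        R = A @ A.T + 3 * np.eye(3)
        Rinv = np.linalg.inv(R)
        naive = sum(float(r @ Rinv @ r) for r in res)
        assert merit_chi2(res, R) == pytest.approx(naive, rel=1e-10)

    def test_singular_R_rejected(self):
        with pytest.raises(ConfigError):
            merit_chi2([np.ones(2)], np.zeros((2, 2)))


class TestEstimation:
    def test_zero_noise_truth_is_fixed_point(self, product_data):
        m, clean, _ = product_data
        init = initial_state(m, m.theta_true, p0_state=1e-8, p0_param=1e-8,
                             q_state=1e-12, q_param=1e-12, sqrt_R=0.05)
        res = estimate(m, clean, init)
        assert np.allclose(res.final_theta_vector, m.theta_true, rtol=1e-3)

    def test_merit_recomputable_from_residuals(self, product_data):
        m, _, noisy = product_data
        init = initial_state(m, np.array([0.5, 0.5]), sqrt_R=0.1)
        res = estimate(m, noisy, init)
        assert res.merit == pytest.approx(merit_chi2(list(res.residuals), res.R_list), rel=1e-9)

    def test_single_parameter_decay_recovery(self):
        """Logistic-style decay, 1 parameter, low noise: recovered within 5%."""
        m = KineticModel(
            name="decay1",
            rhs=lambda x, th, t: -th[0] * x,
            observe=lambda x, th, t: x,
            state_names=("x",),
            param_names=("k",),
            observed_names=("x",),
            x0=np.array([1.0]),
            theta_true=np.array([0.8]),
        )
        grid = np.linspace(0.05, 5.0, 200)
        clean = simulate(m, m.theta_true, grid)
        rng = np.random.default_rng(1)
        noisy = TimeSeries(grid, np.maximum(0, clean.values * (1 + 0.02 * rng.standard_normal(clean.values.shape))), ("x",))
        res = iterated_estimate(m, noisy, np.array([0.3]), log_params=True,
                                n_anneal=6, decay=0.5, p0_state=1e-6, q_state=1e-9,
                                sqrt_R=0.02, rtol=1e-6, atol=1e-9)
        assert abs(res.final_theta["k"] - 0.8) / 0.8 < 0.05

    def test_product_combination_identified_individuals_spread(self, prop_r_fn):
        """Structurally NI pair: the product is pinned, the factors are not."""
        from kinid.fixtures import make_model
        from kinid.models import NoiseModel, apply_noise

        m = make_model("product_ni")
        grid = np.linspace(0.1, 4.0, 40)
        clean = simulate(m, m.theta_true, grid)
        prods, th1s = [], []
        for seed in range(12):
            noisy = apply_noise(clean, NoiseModel(kind="multiplicative", seed=seed))
            rng = np.random.default_rng(1000 + seed)
            res = iterated_estimate(m, noisy, rng.uniform(0.05, 1.0, 2),
                                    log_params=True, n_anneal=6, decay=0.5,
                                    p0_state=1e-4, q_state=1e-8,
                                    r_fn=prop_r_fn, rtol=1e-6, atol=1e-9)
            th = res.final_theta_vector
            prods.append(th[0] * th[1])
            th1s.append(th[0])
        prods, th1s = np.array(prods), np.array(th1s)
        assert abs(np.median(prods) - 1.0) < 0.05
        assert np.std(th1s) > 0.5 * abs(np.mean(th1s))
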