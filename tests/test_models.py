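"""Model core: simulation, discretization, noise models, containers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinid.fixtures import make_model
from kinid.models import (
    AugmentedState,
    ConfigError,
    KineticModel,
    NoiseModel,
    TimeSeries,
    apply_noise,
    discretize,
    log_param_model,
    simulate,
)


def constant_model():
    return make_model("constant")


class TestSimulate:
    def test_zero_vector_field_is_constant(self):
        m = constant_model()
        ts = simulate(m, m.theta_true, np.linspace(1, 10, 10))
        assert np.allclose(ts.values, m.x0[None, :])

    def test_exponential_decay_closed_form(self):
        """Scalar dx/dt = -theta*x against the analytic solution."""
        m = KineticModel(
            name="decay",
            rhs=lambda x, th, t: -th[0] * x,
            observe=lambda x, th, t: x,
            state_names=("x",),
            param_names=("theta",),
            observed_names=("x",),
            x0=np.array([1.0]),
        )
        ts = simulate(m, np.array([0.5]), np.array([0.0, 1.0, 2.0]))
        assert np.allclose(ts.values.ravel(), [1.0, np.exp(-0.5), np.exp(-1.0)], atol=1e-7)

    def test_sampling_grid_excludes_t0(self):
        """[0, 2340] s at 10 s steps gives 234 measurement instants."""
        grid = np.arange(10.0, 2341.0, 10.0)
        assert len(grid) == 234
        m = make_model("mm_chain")
        ts = simulate(m, m.theta_true, grid)
        assert len(ts) == 234

    def test_tolerance_convergence(self):
        m = make_model("mm_chain")
        grid = np.arange(10.0, 2341.0, 50.0)
        a = simulate(m, m.theta_true, grid, rtol=1e-8, atol=1e-10)
        b = simulate(m, m.theta_true, grid, rtol=1e-4, atol=1e-6)
        assert np.max(np.abs(a.values - b.values)) < 10 * 1e-4

    def test_bad_grid_raises(self):
        m = constant_model()
        with pytest.raises(ConfigError):
            simulate(m, m.theta_true, np.array([2.0, 1.0]))


class TestApplyNoise:
    def test_none_kind_is_identity(self):
        m = constant_model()
        ts = simulate(m, m.theta_true, np.linspace(1, 5, 5))
        out = apply_noise(ts, NoiseModel(kind="none"))
        assert np.array_equal(out.values, ts.values)

    def test_multiplicative_on_zeros_stays_zero(self):
        ts = TimeSeries(np.arange(1.0, 6.0), np.zeros((5, 2)), ("a", "b"))
        out = apply_noise(ts, NoiseModel(kind="multiplicative", seed=3))
        assert np.array_equal(out.values, np.zeros((5, 2)))

    def test_multiplicative_matches_seeded_stream(self):
        """Independently regenerate the seeded normal draws and compare."""
        ts = TimeSeries(np.arange(1.0, 11.0), np.ones((10, 1)), ("y",))
        out = apply_noise(ts, NoiseModel(kind="multiplicative", c_mult=0.2, seed=17))
        r = np.random.default_rng(17).standard_normal((10, 1))
        expected = np.maximum(0.0, 1.0 + 0.2 * r)
        assert np.allclose(out.values, expected)

    def test_mixed_matches_seeded_stream(self):
        ts = TimeSeries(np.arange(1.0, 11.0), np.full((10, 1), 2.0), ("y",))
        out = apply_noise(ts, NoiseModel(kind="mixed", a_add=0.1, C=0.2, seed=5))
        rng = np.random.default_rng(5)
        r1 = rng.standard_normal((10, 1))
        r2 = rng.standard_normal((10, 1))
        assert np.allclose(out.values, np.maximum(0.0, 2.0 + 0.1 * r1 + 0.2 * r2 * 2.0))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), kind=st.sampled_from(["multiplicative", "mixed"]))
    def test_noise_never_negative(self, seed, kind):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 2, size=(20, 2))
        ts = TimeSeries(np.arange(1.0, 21.0), vals, ("a", "b"))
        out = apply_noise(ts, NoiseModel(kind=kind, seed=seed))
        assert np.all(out.values >= 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            NoiseModel(kind="bogus")


class TestDiscretize:
    def test_zero_field_identity(self):
        m = constant_model()
        x = np.array([1.0, 3.0])
        out = discretize(m, x, 0.0, 5.0)
        assert np.allclose(out, x)

    def test_closed_form_step(self):
        m = KineticModel(
            name="decay",
            rhs=lambda x, th, t: -th[0] * x,
            observe=lambda x, th, t: x,
            state_names=("x",),
            param_names=("theta",),
            observed_names=("x",),
            x0=np.array([1.0]),
        )
        out = discretize(m, np.array([1.0, 1.0]), 0.0, 0.1)
        assert np.allclose(out, [np.exp(-0.1), 1.0], atol=1e-8)

    def test_parameter_block_bit_identical(self, mm_model):
        x_aug = np.array([0.7, 0.1, 0.123456789, 0.987654321])
        out = discretize(mm_model, x_aug, 0.0, 25.0)
        assert out[2] == x_aug[2] and out[3] == x_aug[3]

    def test_backwards_interval_rejected(self, mm_model):
        with pytest.raises(ConfigError):
            discretize(mm_model, np.zeros(4), 5.0, 5.0)


class TestContainers:
    def test_augmented_index_round_trip(self, mm_model):
        aug = AugmentedState(mm_model)
        for name in aug.names:
            assert aug.names[aug.index(name)] == name

    def test_timeseries_csv_round_trip(self, tmp_path):
        ts = TimeSeries(np.array([1.0, 2.0]), np.array([[1.0, 2.0], [3.0, 4.0]]), ("a", "b"))
        path = tmp_path / "ts.csv"
        ts.to_csv(path)
        back = TimeSeries.read_csv(path)
        assert back.observed_names == ("a", "b")
        assert np.allclose(back.values, ts.values)
        assert np.allclose(back.times, ts.times)

    def test_fixed_params_partition(self, mm_model):
        fixed = mm_model.fix(Km=0.3)
        assert fixed.estimated_params == ("Vmax",)
        assert fixed.full_theta(np.array([0.01]))[1] == 0.3

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError):
            KineticModel(
                name="dup",
                rhs=lambda x, th, t: x,
                observe=lambda x, th, t: x,
                state_names=("a", "a"),
                param_names=(),
                observed_names=("a",),
                x0=np.array([1.0, 2.0]),
            )


class TestLogParamModel:
    def test_same_trajectory_under_reparameterization(self, mm_model):
        lm = log_param_model(mm_model)
        grid = np.arange(10.0, 500.0, 50.0)
        a = simulate(mm_model, mm_model.theta_true, grid)
        b = simulate(lm, lm.theta_true, grid)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_theta_true_is_logged(self, mm_model):
        lm = log_param_model(mm_model)
        assert np.allclose(np.exp(lm.theta_true), mm_model.theta_true)
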