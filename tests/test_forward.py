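import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmfill.forward import (EffectiveConnectivity, HemodynamicParams,
                             HemodynamicState, IntegrationError,
                             NodeTimeSeries, bold_signal,
                             hemodynamic_derivative, neural_derivative,
                             simulate_bold)

from .conftest import box_stimulus


class TestEffectiveConnectivity:
    def test_diagonal_must_be_minus_one(self):
        A = np.zeros((2, 2))
        with pytest.raises(ValueError, match="diagonal"):
            EffectiveConnectivity(A, np.zeros((1, 2, 2)), np.zeros((2, 1)))

    def test_alpha_positive(self):
        with pytest.raises(ValueError, match="alpha_decay"):
            EffectiveConnectivity(-np.eye(2), np.zeros((1, 2, 2)),
                                  np.zeros((2, 1)), alpha_decay=0.0)

    def test_default_alpha_gives_50ms_lag(self, simple_conn):
        assert 1.0 / simple_conn.alpha_decay == pytest.approx(0.05)


class TestHemodynamicParams:
    def test_defaults_valid(self):
        h = HemodynamicParams.prior_means()
        assert 0 < h.E0 < 1 and 0 < h.V0 < 1 and 0 < h.alpha_grubb < 1

    @pytest.mark.parametrize("field", ["tau", "E0", "tau_s", "epsilon"])
    def test_positive_required(self, field):
        with pytest.raises(ValueError):
            HemodynamicParams(**{field: -1.0})


class TestNeuralDerivative:
    def test_pure_self_decay(self):
        conn = EffectiveConnectivity(-np.eye(4), np.zeros((1, 4, 4)),
                                     np.zeros((4, 1)), alpha_decay=20.0)
        dz = neural_derivative(np.array([1.0, 0, 0, 0]), np.zeros(1), conn)
        np.testing.assert_allclose(dz, [-20.0, 0, 0, 0])

    def test_input_drive_only(self):
        conn = EffectiveConnectivity(-np.eye(4), np.zeros((4, 4, 4)),
                                     np.eye(4), alpha_decay=20.0)
        dz = neural_derivative(np.zeros(4), np.array([1.0, 0, 0, 0]), conn)
        np.testing.assert_allclose(dz, [1.0, 0, 0, 0])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_elementwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 4, 2
        A = rng.normal(size=(n, n)) * 0.3
        np.fill_diagonal(A, -1.0)
        B = rng.normal(size=(m, n, n)) * 0.2
        C = rng.normal(size=(n, m))
        alpha = float(rng.uniform(1, 30))
        conn = EffectiveConnectivity(A, B, C, alpha)
        z = rng.normal(size=n)
        u = rng.normal(size=m)
        # brute-force scalar summation, no matrix routines
        expected = np.zeros(n)
        for i in range(n):
            for k in range(n):
                coef = alpha * A[i][k]
                for j in range(m):
                    coef += u[j] * B[j][i][k]
                expected[i] += coef * z[k]
            for j in range(m):
                expected[i] += C[i][j] * u[j]
        np.testing.assert_allclose(neural_derivative(z, u, conn), expected,
                                   rtol=1e-12)

    def test_shape_errors(self, simple_conn):
        with pytest.raises(ValueError, match="shape"):
            neural_derivative(np.zeros(3), np.zeros(2), simple_conn)
        with pytest.raises(ValueError, match="shape"):
            neural_derivative(np.zeros(4), np.zeros(3), simple_conn)


class TestHemodynamicDerivative:
    def test_resting_fixed_point(self):
        h = HemodynamicParams.prior_means()
        d = hemodynamic_derivative(HemodynamicState(), 0.0, h)
        np.testing.assert_allclose([d.s, d.f, d.v, d.q], 0.0, atol=1e-14)

    def test_domain_error(self):
        h = HemodynamicParams.prior_means()
        with pytest.raises(ValueError):
            hemodynamic_derivative(HemodynamicState(f=-0.1), 0.0, h)

    def test_inflow_rises_within_2s_of_pulse(self):
        # fine-step integration oracle on the balloon equations alone
        h = HemodynamicParams.prior_means()
        x = HemodynamicState()
        dt = 0.001
        for step in range(int(2.0 / dt)):
            z = 1.0 if step * dt < 0.5 else 0.0
            d = hemodynamic_derivative(x, z, h)
            x = HemodynamicState(x.s + dt * d.s, x.f + dt * d.f,
                                 x.v + dt * d.v, x.q + dt * d.q)
            if x.f > 1.0:
                break
        assert x.f > 1.0

    def test_impulse_response_peaks_3_to_7s(self, prior_hemo):
        conn = EffectiveConnectivity(-np.eye(1), np.zeros((1, 1, 1)),
                                     np.array([[4.6]]))
        dt = 0.01
        n = int(30.0 / dt)
        u = np.zeros((n, 1))
        u[: int(1.0 / dt)] = 1.0
        ts = simulate_bold(conn, prior_hemo[:1], u, 30.0, dt=dt, tr=dt)
        peak = np.argmax(ts.bold[:, 0]) * dt
        assert 3.0 <= peak <= 7.0


class TestBoldSignal:
    def test_rest_is_zero(self):
        assert bold_signal(1.0, 1.0, HemodynamicParams()) == 0.0

    def test_deoxyhemoglobin_decrease_raises_signal(self):
        h = HemodynamicParams()
        assert bold_signal(1.0, 0.9, h) > bold_signal(1.0, 1.0, h)
        assert bold_signal(1.0, 0.8, h) > bold_signal(1.0, 0.9, h)

    def test_domain(self):
        with pytest.raises(ValueError):
            bold_signal(-1.0, 1.0, HemodynamicParams())


class TestSimulateBold:
    def test_default_config_shape(self, simple_conn, prior_hemo):
        dt = 0.005
        u = box_stimulus(int(600 / dt), dt)
        ts = simulate_bold(simple_conn, prior_hemo, u, 600.0, dt=dt, tr=3.0)
        assert ts.bold.shape == (200, 4)
        assert ts.n_samples == 200 and ts.tr == 3.0

    def test_zero_input_zero_noise_constant(self, simple_conn, prior_hemo):
        u = np.zeros((int(60 / 0.005), 2))
        ts = simulate_bold(simple_conn, prior_hemo, u, 60.0, tr=3.0)
        np.testing.assert_allclose(ts.bold, 0.0, atol=1e-12)

    def test_seeded_determinism(self, simple_conn, prior_hemo):
        dt = 0.005
        u = box_stimulus(int(60 / dt), dt)
        a = simulate_bold(simple_conn, prior_hemo, u, 60.0, dt=dt,
                          noise_sd_frac=0.005, seed=42)
        b = simulate_bold(simple_conn, prior_hemo, u, 60.0, dt=dt,
                          noise_sd_frac=0.005, seed=42)
        assert np.array_equal(a.bold, b.bold)
        c = simulate_bold(simple_conn, prior_hemo, u, 60.0, dt=dt,
                          noise_sd_frac=0.005, seed=43)
        assert not np.array_equal(a.bold, c.bold)

    def test_rk4_matches_fine_euler_oracle(self, simple_conn, prior_hemo):
        # Euler at 0.1 ms as the independent integration oracle
        dt_fine = 0.0001
        u_fine = box_stimulus(int(60 / dt_fine), dt_fine)
        ref = simulate_bold(simple_conn, prior_hemo, u_fine, 60.0,
                            dt=dt_fine, tr=3.0, method="euler")
        u = u_fine[:: int(0.005 / dt_fine)]
        rk4 = simulate_bold(simple_conn, prior_hemo, u, 60.0, dt=0.005,
                            tr=3.0)
        signal_range = np.ptp(ref.bold)
        assert np.max(np.abs(rk4.bold - ref.bold)) < 0.01 * signal_range

    def test_fourth_order_convergence(self, simple_conn, prior_hemo):
        dt = 0.02
        u_fine = box_stimulus(int(60 / 0.01), 0.01)
        sims = {}
        for step in (0.01, 0.02, 0.04):
            u = u_fine[:: int(step / 0.01)]
            sims[step] = simulate_bold(simple_conn, prior_hemo, u, 60.0,
                                       dt=step, tr=3.0).bold
        err_half = np.max(np.abs(sims[dt] - sims[0.01]))
        err_double = np.max(np.abs(sims[dt] - sims[0.04]))
        assert err_half < err_double

    def test_linearity_limit(self, prior_hemo):
        # with B = 0 the neural subsystem is linear in the input gain
        dt = 0.005
        u = box_stimulus(int(60 / dt), dt)
        peaks = {}
        for lam in (1e-3, 2e-3):
            A = -np.eye(4)
            A[2, 0] = 0.4
            C = np.zeros((4, 2))
            C[0, 0] = lam
            conn = EffectiveConnectivity(A, np.zeros((2, 4, 4)), C)
            ts = simulate_bold(conn, prior_hemo, u, 60.0, dt=dt, tr=0.25,
                               store_neural=True)
            peaks[lam] = np.max(ts.neural[:, 0])
        assert peaks[2e-3] / peaks[1e-3] == pytest.approx(2.0, rel=0.02)

    def test_dt_must_divide_tr(self, simple_conn, prior_hemo):
        u = box_stimulus(1000, 0.007)
        with pytest.raises(ValueError, match="divide"):
            simulate_bold(simple_conn, prior_hemo, u, 7.0, dt=0.007, tr=3.0)

    def test_integration_error_reports_step(self, prior_hemo):
        A = -np.eye(4)
        A[1, 0] = 80.0  # absurdly strong coupling -> blow-up
        A[0, 1] = 80.0
        conn = EffectiveConnectivity(A, np.zeros((2, 4, 4)),
                                     np.full((4, 2), 10.0))
        u = np.ones((int(60 / 0.005), 2))
        with pytest.raises(IntegrationError) as exc:
            simulate_bold(conn, prior_hemo, u, 60.0)
        assert exc.value.step > 0

    def test_noise_scales_with_mean_level(self, simple_conn, prior_hemo):
        dt = 0.005
        u = box_stimulus(int(600 / dt), dt)
        clean = simulate_bold(simple_conn, prior_hemo, u, 600.0, dt=dt)
        noisy = simulate_bold(simple_conn, prior_hemo, u, 600.0, dt=dt,
                              noise_sd_frac=0.01, seed=0)
        resid = noisy.bold - clean.bold
        level = clean.bold.mean() + 100.0
        assert np.std(resid) == pytest.approx(0.01 * level, rel=0.1)


def test_node_time_series_requires_2d():
    with pytest.raises(ValueError):
        NodeTimeSeries(np.zeros(10), tr=3.0)
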