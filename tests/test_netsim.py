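import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from critnet import (NetworkParams, NoiseSpec, InvalidParameterError,
                     build_weights, control_parameter, gamma_for_G, linearize,
                     simulate, SupercriticalRunawayError)
from critnet.netsim import WeightMatrix


class TestControlParameter:
    def test_printed_criticality_condition(self):
        # gamma ~ 0.1 with p = 0.2 and mu_conn = 49.881 puts G at ~1
        assert control_parameter(0.1, 0.2, 49.881) == pytest.approx(0.99762)

    def test_zero_gain(self):
        assert control_parameter(0.0, 0.2, 49.881) == 0.0

    @given(st.floats(0.0, 1.5), st.floats(0.01, 1.0), st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_round_trip(self, target, p, mu):
        gamma = gamma_for_G(target, p, mu)
        assert control_parameter(gamma, p, mu) == pytest.approx(target, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            control_parameter(-0.1, 0.2, 49.881)
        with pytest.raises(InvalidParameterError):
            gamma_for_G(0.95, 0.0, 49.881)


class TestNetworkParams:
    def test_dt_must_resolve_tau(self):
        with pytest.raises(InvalidParameterError):
            NetworkParams(tau=0.005, dt=0.001)

    def test_invalid_sizes_and_values(self):
        with pytest.raises(InvalidParameterError):
            NetworkParams(n_units=1)
        with pytest.raises(InvalidParameterError):
            NetworkParams(sparseness=1.5)
        with pytest.raises(InvalidParameterError):
            NetworkParams(conn_mean=np.nan)


class TestBuildWeights:
    def test_realized_sparseness_concentrates(self):
        W = build_weights(NetworkParams(seed=3))
        n = 240
        sd = np.sqrt(0.2 * 0.8 / n ** 2) * n  # binomial SD of the entry fraction
        assert abs(W.realized_sparseness - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n ** 2) * n

    def test_zero_sparseness_gives_zero_matrix(self):
        W = build_weights(NetworkParams(sparseness=0.0, seed=1))
        assert not W.weights.any()
        assert linearize(W).effective_gain == 0.0

    def test_nonzero_entry_mean_scales_with_n(self):
        p = NetworkParams(seed=5)
        W = build_weights(p)
        nz = W.weights[W.weights != 0]
        expected = p.conn_mean / p.n_units
        assert nz.mean() == pytest.approx(expected, rel=0.05)

    def test_reproducible_given_seed(self):
        a = build_weights(NetworkParams(seed=9)).weights
        b = build_weights(NetworkParams(seed=9)).weights
        assert np.array_equal(a, b)


class TestLinearize:
    def test_zero_matrix(self, default_params):
        W = WeightMatrix(np.zeros((8, 8)), default_params.replace(n_units=8),
                         realized_sparseness=0.0)
        rep = linearize(W)
        assert rep.effective_gain == 0.0
        assert rep.predicted_timescale == pytest.approx(default_params.tau)
        assert rep.jacobian_dominant < 0

    def test_two_by_two_closed_form(self, default_params):
        # symmetric [[2, 1], [1, 2]] has eigenvalues 1 and 3
        W = WeightMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]),
                         default_params.replace(n_units=2, gain=0.1),
                         realized_sparseness=1.0)
        rep = linearize(W, gain=0.1, tau=0.02)
        assert sorted(rep.eigenvalues.real) == pytest.approx([0.1, 0.3])
        assert rep.effective_gain == pytest.approx(0.3)
        assert rep.predicted_timescale == pytest.approx(0.02 / 0.7)

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_matches_characteristic_polynomial(self, n, default_params):
        # brute-force oracle: roots of det(lambda I - gamma W) from poly coefficients
        rng = np.random.default_rng(n)
        mat = rng.normal(0, 1, (n, n))
        rep = linearize(WeightMatrix(mat, default_params.replace(n_units=n),
                                     realized_sparseness=1.0), gain=0.1, tau=0.02)
        coeffs = np.poly(0.1 * mat)
        roots = np.roots(coeffs)
        got = np.sort_complex(rep.eigenvalues)
        exp = np.sort_complex(roots)
        assert np.allclose(got, exp, atol=1e-8)

    def test_dominant_eigenvalue_real_and_isolated(self):
        W = build_weights(NetworkParams(seed=21, gain=gamma_for_G(0.95, 0.2, 49.881)))
        rep = linearize(W)
        eig = rep.eigenvalues
        dom = eig[np.argmax(eig.real)]
        assert abs(dom.imag) < 1e-8
        bulk = np.sort(eig.real)[-2]
        assert rep.effective_gain - bulk > 0.3  # isolated from the bulk cloud

    def test_jacobian_sign_matches_stability(self):
        for G in (0.8, 1.05):
            W = build_weights(NetworkParams(seed=2, gain=gamma_for_G(G, 0.2, 49.881)))
            rep = linearize(W)
            assert (rep.jacobian_dominant < 0) == (rep.effective_gain < 1)


class TestSimulate:
    def test_zero_drive_zero_state_stays_zero(self, default_params):
        p = default_params.replace(n_units=16, seed=1)
        W = build_weights(p)
        tr = simulate(W, NoiseSpec(mean=0.0, sd=0.0, seed=0), 2.0)
        assert not tr.values.any()

    def test_isolated_units_relax_to_gamma_i(self, default_params):
        # W = 0, constant drive I: closed-form linear ODE gives r -> gamma*I
        p = default_params.replace(n_units=4, sparseness=0.0, seed=1)
        W = build_weights(p)
        tr = simulate(W, NoiseSpec(mean=30.0, sd=0.0, seed=0), 0.2)
        after = tr.values[:, int(5 * p.tau * tr.fs):]
        assert np.allclose(after, p.gain * 30.0, rtol=0.02)

    @pytest.mark.parametrize("g_target", [0.3, 0.5, 0.8])
    def test_uniform_mode_impulse_decay_time(self, g_target):
        # linearised dominant-mode oracle: decay constant tau / (1 - G_eff)
        p = NetworkParams(seed=40, gain=gamma_for_G(g_target, 0.2, 49.881))
        W = build_weights(p)
        g_eff = linearize(W).effective_gain
        r0 = np.full(p.n_units, 10.0)
        tr = simulate(W, NoiseSpec(mean=0.0, sd=0.0, seed=0), 1.0,
                      initial_state=r0, fs_out=1000.0)
        m = tr.values.mean(axis=0)
        t = tr.times
        keep = m > m[0] * 1e-3
        slope = np.polyfit(t[keep], np.log(m[keep]), 1)[0]
        fitted_tau = -1.0 / slope
        expected = p.tau / (1.0 - g_eff)
        assert fitted_tau == pytest.approx(expected, rel=0.10)

    def test_rates_nonnegative_under_strong_noise(self):
        p = NetworkParams(n_units=32, seed=7, gain=gamma_for_G(0.9, 0.2, 49.881))
        W = build_weights(p)
        tr = simulate(W, NoiseSpec(mean=0.0, sd=30.0, seed=8), 5.0)
        assert tr.values.min() >= 0.0

    def test_supercritical_runaway_guard(self):
        p = NetworkParams(seed=13, gain=gamma_for_G(1.1, 0.2, 49.881))
        W = build_weights(p)
        with pytest.raises(SupercriticalRunawayError, match="effective_gain"):
            simulate(W, NoiseSpec(seed=14), 120.0)

    def test_effective_gain_dispersion_shrinks_with_size(self):
        sds = []
        for n in (50, 100, 200, 400):
            vals = [linearize(build_weights(NetworkParams(
                n_units=n, seed=1000 * n + k, gain=gamma_for_G(1.0, 0.2, 49.881)
            ))).effective_gain for k in range(10)]
            sds.append(np.std(vals))
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_euler_step_convergence_on_deterministic_drive(self):
        # halving dt changes band powers of the driven response by < 5 %
        from critnet import spectral as sp
        powers = []
        for dt in (0.001, 0.0005):
            p = NetworkParams(n_units=8, seed=3, dt=dt,
                              gain=gamma_for_G(0.8, 0.2, 49.881))
            W = build_weights(p)
            n_steps = int(40.0 / dt)
            t = np.arange(n_steps) * dt
            drive = 20.0 + 5.0 * np.sin(2 * np.pi * 2.0 * t) + 3.0 * np.sin(2 * np.pi * 11.0 * t)
            tr = simulate(W, np.tile(drive, (8, 1)), 40.0)
            x = tr.values[0, int(10 * tr.fs):]
            est = sp.welch_psd(x - x.mean(), tr.fs, nperseg=1024)
            powers.append([sp.band_power(est, (1.5, 2.5)), sp.band_power(est, (10, 12))])
        a, b = np.asarray(powers)
        assert np.all(np.abs(a / b - 1) < 0.05)

    def test_reproducible_given_seeds(self):
        p = NetworkParams(n_units=16, seed=5, gain=gamma_for_G(0.9, 0.2, 49.881))
        W = build_weights(p)
        a = simulate(W, NoiseSpec(seed=6), 3.0).values
        b = simulate(W, NoiseSpec(seed=6), 3.0).values
        assert np.array_equal(a, b)
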