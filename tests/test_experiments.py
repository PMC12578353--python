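import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from critnet import NetworkParams, NoiseSpec, ProxySpec, BlockProtocol
from critnet.experiments import (ScanConfig, ScanResult, correlation_scan,
                                 calibrate_Gstar, first_g_reaching,
                                 CalibrationOutOfRangeError, recall_contrast,
                                 signed_rank_test, bh_fdr, effective_sample_size,
                                 goodness_of_fit, effective_gain_vs_size,
                                 stability_boundary_scan, size_gain_heatmap)
from critnet import spectral as sp


# ---------------------------------------------------------------------------
# statistical primitives vs brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """Textbook Benjamini-Hochberg: p_(i) * n / i with tail-minimum monotonisation."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def brute_force_signed_rank_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_min_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(np.dot(signs, ranks))
        if min(w, total - w) <= w_min_obs:
            count += 1
    return count / 2 ** n


@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bh_fdr_matches_brute_force(pvals):
    p = np.asarray(pvals)
    assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


def test_bh_fdr_monotone_and_above_raw():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.001, 1.0, 15)
    adj = bh_fdr(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


@pytest.mark.parametrize("seed", range(6))
def test_signed_rank_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 9)
    d = np.round(rng.normal(0.3, 1.0, n), 3)
    d = d[d != 0]
    if np.unique(np.abs(d)).size < d.size or d.size < 5:
        d = np.array([0.11, -0.47, 0.52, 0.93, 1.41, -0.18, 0.77])[:max(5, d.size)]
    _, p = signed_rank_test(d)
    assert p == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)


def test_signed_rank_degenerate_inputs():
    with pytest.warns(UserWarning, match="undefined"):
        stat, p = signed_rank_test(np.zeros(8))
    assert p == 1.0 and np.isnan(stat)


class TestEffectiveSampleSize:
    def test_direct_formula_on_hand_built_rho(self):
        # residuals with a known single strong lag-1 autocorrelation: AR(1)-free
        # construction eps_t = z_t + z_{t-1} gives rho_1 = 0.5, rho_2 ~ 0
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 60000)
        eps = z[1:] + z[:-1]
        n_eff, rhos = effective_sample_size(eps)
        assert rhos[0] == pytest.approx(0.5, abs=0.02)
        assert n_eff == pytest.approx(eps.size / (1 + 2 * rhos.sum()), rel=1e-12)

    def test_iid_residuals_close_to_n(self):
        eps = np.random.default_rng(2).normal(0, 1, 2000)
        n_eff, _ = effective_sample_size(eps)
        assert n_eff == pytest.approx(2000, rel=0.20)

    def test_ar1_oracle(self):
        # brute-force oracle: simulated AR(1), phi = 0.8 -> N (1-phi)/(1+phi)
        rng = np.random.default_rng(3)
        phi, n = 0.8, 40000
        eps = np.empty(n)
        eps[0] = rng.normal()
        for t in range(1, n):
            eps[t] = phi * eps[t - 1] + rng.normal()
        n_eff, _ = effective_sample_size(eps)
        assert n_eff == pytest.approx(n * (1 - phi) / (1 + phi), rel=0.25)


class TestGoodnessOfFit:
    def _spec(self, power, f):
        return sp.SpectrumEstimate(f, power, 250.0, 4096, 2048)

    def test_identical_spectra(self):
        f = np.fft.rfftfreq(8192, 1 / 250.0)[1:]
        est = self._spec(2.0 * f ** -1.5, f)
        rep = goodness_of_fit(est, est)
        assert rep.r_squared_log == pytest.approx(1.0)
        assert rep.n_eff == rep.n_bins
        assert rep.p_value < 1e-10

    def test_neff_shrinks_for_smooth_residuals(self):
        f = np.fft.rfftfreq(8192, 1 / 250.0)[1:]
        sim = self._spec(2.0 * f ** -1.5, f)
        # smooth multiplicative mismatch -> strongly autocorrelated residuals
        ref = self._spec(2.0 * f ** -1.5 * (1 + 0.5 * np.sin(np.log10(f))), f)
        rep = goodness_of_fit(sim, ref)
        assert rep.n_eff < 0.2 * rep.n_bins

    def test_band_overlap_required(self):
        f_lo = np.linspace(0.001, 0.01, 50)
        f_hi = np.linspace(20.0, 100.0, 50)
        with pytest.raises(Exception):
            goodness_of_fit(self._spec(np.ones(50), f_hi), self._spec(np.ones(50), f_lo),
                            band=(0.05, 10.0))


# ---------------------------------------------------------------------------
# scan bookkeeping and calibration interpolation
# ---------------------------------------------------------------------------

def synthetic_scan(g, curve):
    g = np.asarray(g, dtype=float)
    curve = np.asarray(curve, dtype=float)
    fill = np.full_like(curve, np.nan)
    return ScanResult(g_grid=g, max_r=curve, mean_r=curve, sq_log_ratio=curve,
                      log_ratio=curve / 2, exp_ratio=fill,
                      raw=pd.DataFrame(), n_failed=0, config=None)


class TestCalibration:
    def test_linear_curve_interpolation_closed_form(self):
        scan = synthetic_scan([0.80, 0.90, 1.00], [2.0, 1.0, 0.0])
        cal = calibrate_Gstar(scan, 0.84, statistic="sq_log_ratio")
        assert cal.g_star == pytest.approx(0.90 + 0.10 * (1.0 - 0.84))

    def test_target_at_grid_point(self):
        scan = synthetic_scan([0.8, 0.9, 1.0], [2.0, 0.84, 0.1])
        assert calibrate_Gstar(scan, 0.84).g_star == pytest.approx(0.9)

    def test_out_of_range_raises(self):
        scan = synthetic_scan([0.8, 0.9], [0.5, 0.4])
        with pytest.raises(CalibrationOutOfRangeError):
            calibrate_Gstar(scan, 0.84)

    def test_first_g_reaching(self):
        scan = synthetic_scan([0.8, 0.9, 1.0], [0.1, 0.6, 0.9])
        assert first_g_reaching(scan, "mean_r", 0.56) == pytest.approx(0.9)
        with pytest.raises(CalibrationOutOfRangeError):
            first_g_reaching(scan, "mean_r", 0.95)


class TestScanSmallScale:
    def test_scan_shapes_and_monotone_mean_correlation(self):
        # paired seeds at three well-separated G values; expectation increases
        cfg = ScanConfig(g_grid=(0.5, 0.85, 0.97), n_realizations=3,
                         duration=220.0, discard=40.0, seed=7)
        res = correlation_scan(cfg)
        assert res.g_grid.tolist() == [0.5, 0.85, 0.97]
        assert res.raw.shape[0] == 9
        assert res.mean_r[0] < res.mean_r[1] < res.mean_r[2]
        assert np.all(res.max_r >= res.mean_r)
        frame = res.to_frame()
        assert set(frame.columns) >= {"G", "max_r", "mean_r", "sq_log_ratio"}


# ---------------------------------------------------------------------------
# recall contrast (small scale; full scale lives in the acceptance suite)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_gain_contrast():
    return recall_contrast(n_realizations=6, mode="gain", gain_multiplier=1.05,
                           g_star=0.9,
                           network=NetworkParams(n_units=120),
                           protocol=BlockProtocol(block_length=220.0, discard=60.0),
                           proxy=ProxySpec(alpha=0.05),
                           nperseg_seconds=64.0, seed=3)


class TestRecallContrast:
    def test_gain_mode_elevates_low_band(self, small_gain_contrast):
        res = small_gain_contrast
        rest, recall = res.mean_spectra()
        low = (res.freqs > 0) & (res.freqs < 0.1)
        assert recall[low].mean() > rest[low].mean()

    def test_adjusted_p_dominates_raw_and_bh_is_monotone(self, small_gain_contrast):
        res = small_gain_contrast
        assert np.all(res.p_adj >= res.p_raw - 1e-15)
        order = np.argsort(res.p_raw)
        assert np.all(np.diff(res.p_adj[order]) >= -1e-15)

    def test_label_swap_flips_effect_sign(self, small_gain_contrast):
        res = small_gain_contrast
        diff = res.recall_spectra - res.rest_spectra
        swapped = res.rest_spectra - res.recall_spectra
        assert np.allclose(diff, -swapped)

    def test_additive_mode_paired_design_is_exact(self):
        # same weights and same noise stream: the additive condition shifts the
        # baseline; fluctuation bins (beyond the Hann main lobe) are unchanged
        res = recall_contrast(n_realizations=5, mode="additive", i_add=12.5,
                              g_star=0.9, network=NetworkParams(n_units=120),
                              protocol=BlockProtocol(block_length=160.0, discard=40.0),
                              proxy=ProxySpec(alpha=0.05),
                              nperseg_seconds=32.0, seed=4)
        rest, recall = res.mean_spectra()
        assert recall[0] > 2.0 * rest[0]          # DC bin carries the shift
        fluct = res.tested.copy()
        fluct[:4] = False  # DC main lobe plus the symmetric-window skirt
        rel = np.abs(res.recall_spectra[:, fluct] / res.rest_spectra[:, fluct] - 1)
        assert np.max(rel) < 0.05  # residual window-skirt wiggle, percent scale
        band = (res.recall_spectra[:, fluct].mean()
                / res.rest_spectra[:, fluct].mean())
        assert band == pytest.approx(1.0, abs=0.01)


# ---------------------------------------------------------------------------
# eigen-statistics
# ---------------------------------------------------------------------------

class TestEigenStatistics:
    def test_effective_gain_iqr_decreases_with_size(self):
        tab = effective_gain_vs_size(sizes=(16, 60, 240), reps=25, seed=5)
        iqr = tab.set_index("n_units")["iqr"]
        assert iqr[16] > iqr[60] > iqr[240]
        assert abs(tab.set_index("n_units")["median"][240] - 1.0) < 0.02

    def test_stability_boundary_near_one_small_network(self):
        g_c, tab = stability_boundary_scan(g_grid=np.arange(0.9, 1.11, 0.05),
                                           n_seeds=12,
                                           network=NetworkParams(n_units=80), seed=6)
        assert 0.9 < g_c < 1.1
        assert tab.shape[0] == 5

    def test_heatmap_shape_and_g_dominance(self):
        res = size_gain_heatmap(sizes=(60, 120), g_grid=(0.6, 0.95), reps=1,
                                duration=200.0, discard=50.0, seed=8)
        assert res.values.shape == (2, 2)
        assert np.all(np.isfinite(res.values))
        # criticality dominates: variation across G far exceeds variation across N
        across_g = np.abs(np.diff(res.values, axis=1)).mean()
        across_n = np.abs(np.diff(res.values, axis=0)).mean()
        assert across_g > across_n
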