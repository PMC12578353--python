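"""Spectral and correlation estimation.

Welch spectra are computed, as in the original analysis pipeline, with a
symmetric Hann taper and *no* detrending, so the signal mean contributes to
the f = 0 bin (and, through the main lobe, to the first nonzero bin).  All
band statistics that should not see the baseline therefore use bands whose
lower edge excludes those bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .params import InvalidParameterError, _require

#: default Welch segment length (samples) for mid/high-frequency bands
SEGMENT_STANDARD = 4096
#: long-segment mode (seconds) resolving the ultra-slow (< 0.2 Hz) range
SEGMENT_LONG_SECONDS = 256.0
#: band (Hz) used for "low frequency" mean-power ratios
LOW_BAND = (0.01, 0.1)
#: band (Hz) normalising "slow" power in heatmap-style summaries
FAST_BAND = (1.0, 10.0)
#: regression band (Hz) for power-law exponents
FIT_BAND = (0.1, 10.0)


class FitError(RuntimeError):
    """A spectral model fit failed or is ill-posed."""


@dataclass(frozen=True)
class SpectrumEstimate:
    freqs: np.ndarray
    power: np.ndarray
    fs: float
    nperseg: int
    noverlap: int
    window: str = "hann-symmetric"
    detrend: Optional[str] = None
    scale_k: float = 1.0

    def __post_init__(self) -> None:
        _require(self.scale_k > 0, "scale_k must be positive")

    def band_mask(self, band: Sequence[float]) -> np.ndarray:
        lo, hi = band
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if not m.any():
            raise InvalidParameterError(f"no frequency bins inside band {band}")
        return m

    def rescaled(self, k: float) -> "SpectrumEstimate":
        return SpectrumEstimate(self.freqs, self.power * (k / self.scale_k), self.fs,
                                self.nperseg, self.noverlap, self.window,
                                self.detrend, k)


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    intercept: float
    band: tuple
    r_squared: float


@dataclass(frozen=True)
class LorentzianFit:
    amplitude: float
    knee_freq: float
    residual_norm: float


@dataclass(frozen=True)
class CorrelationReport:
    pair_r: np.ndarray
    max_r: float
    mean_r: float
    band: tuple
    lag_mode: str = "zero"
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _welch_args(n: int, fs: float, nperseg: Optional[int], noverlap: Optional[int]):
    if nperseg is None:
        nperseg = min(SEGMENT_STANDARD, n)
    nperseg = int(min(nperseg, n))
    if noverlap is None:
        noverlap = nperseg // 2
    return nperseg, int(noverlap)


def welch_psd(x: np.ndarray, fs: float, nperseg: Optional[int] = None,
              noverlap: Optional[int] = None, scale_k: float = 1.0,
              detrend: Optional[str] = None) -> SpectrumEstimate:
    """Welch power spectral density (density scaling), times ``scale_k``.

    The taper is the symmetric Hann window and, by default, segments are not
    detrended, matching the original estimation convention; pass
    ``detrend='constant'`` for a mean-free estimate.
    """
    x = np.asarray(x, dtype=float)
    nperseg, noverlap = _welch_args(x.size, fs, nperseg, noverlap)
    if x.size < 2 * nperseg - noverlap:
        raise InvalidParameterError(
            f"signal too short ({x.size} samples) for two Welch segments of {nperseg}")
    f, p = sps.welch(x, fs=fs, window=np.hanning(nperseg), nperseg=nperseg,
                     noverlap=noverlap, detrend=(detrend or False))
    return SpectrumEstimate(freqs=f, power=p * scale_k, fs=fs, nperseg=nperseg,
                            noverlap=noverlap, detrend=detrend, scale_k=scale_k)


def long_segment_samples(fs: float) -> int:
    return int(round(SEGMENT_LONG_SECONDS * fs))


def lowpass(x: np.ndarray, fs: float, cutoff: float = 0.1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    if not 0 < cutoff < fs / 2:
        raise InvalidParameterError("cutoff must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def pair_correlations(signals: np.ndarray, fs: float, band: tuple = (0.0, 0.1),
                      lag_mode: str = "zero", max_lag: float = 10.0,
                      prefiltered: bool = False) -> CorrelationReport:
    """Pearson correlations of slow (< band[1]) fluctuations over distinct pairs.

    Signals are low-pass filtered at the band's upper edge, then correlated at
    zero lag (default) or, in ``lag_mode='max'``, the maximum over lags up to
    ``max_lag`` seconds is taken.  Constant signals yield undefined
    correlations and are excluded (counted in ``n_excluded``).
    """
    x = np.asarray(signals, dtype=float)
    _require(x.ndim == 2 and x.shape[0] >= 2, "need >= 2 equal-length signals")
    y = x if prefiltered else lowpass(x, fs, cutoff=band[1])
    y = y - y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1)
    ok = sd > 0
    n_excl_sig = int((~ok).sum())
    y = y[ok] / sd[ok][:, None]
    m, n = y.shape
    rs = []
    if lag_mode == "zero":
        c = (y @ y.T) / n
        iu = np.triu_indices(m, k=1)
        rs = c[iu]
    elif lag_mode == "max":
        lags = int(round(max_lag * fs))
        for i in range(m):
            for j in range(i + 1, m):
                cc = sps.correlate(y[i], y[j], mode="full") / n
                mid = n - 1
                rs.append(cc[mid - lags:mid + lags + 1].max())
        rs = np.asarray(rs)
    else:
        raise InvalidParameterError("lag_mode must be 'zero' or 'max'")
    rs = np.clip(np.asarray(rs, dtype=float), -1.0, 1.0)
    if rs.size == 0:
        raise InvalidParameterError("all signal pairs degenerate (constant)")
    return CorrelationReport(pair_r=rs, max_r=float(rs.max()), mean_r=float(rs.mean()),
                             band=tuple(band), lag_mode=lag_mode,
                             n_excluded=n_excl_sig)


def auto_cross_psd(sample_a: np.ndarray, sample_b: np.ndarray, fs: float,
                   nperseg: Optional[int] = None, detrend: Optional[str] = None,
                   cross_mode: str = "pair-magnitude",
                   demean: bool = False) -> tuple[SpectrumEstimate, SpectrumEstimate]:
    """Mean auto-PSD of the first sample and the cross-PSD across samples.

    Auto spectra come from the first sample only.  In ``'pair-magnitude'``
    mode the cross spectrum is the magnitude of the segment-averaged complex
    cross-spectral density, averaged over all pairs (a, b) across the two
    samples.  In ``'mean-signal'`` mode it is |CSD(mean of A, mean of B)| —
    identical to the complex pair average (the mean cross-correlation
    function over all A x B pairs equals the cross-correlation of the sample
    means), which suppresses the incoherent floor by the pair count and is
    the convention behind the calibration ratio.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    _require(a.shape[1] == b.shape[1], "samples must share the time grid")
    if demean:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    nperseg, noverlap = _welch_args(a.shape[1], fs, nperseg, None)
    win = np.hanning(nperseg)
    kw = dict(fs=fs, window=win, nperseg=nperseg, noverlap=noverlap,
              detrend=(detrend or False))
    f = None
    autos = []
    for row in a:
        f, p = sps.welch(row, **kw)
        autos.append(p)
    if cross_mode == "pair-magnitude":
        crosses = []
        for ra in a:
            for rb in b:
                _, c = sps.csd(ra, rb, **kw)
                crosses.append(np.abs(c))
        cross_p = np.mean(crosses, axis=0)
    elif cross_mode == "mean-signal":
        _, c = sps.csd(a.mean(axis=0), b.mean(axis=0), **kw)
        cross_p = np.abs(c)
    else:
        raise InvalidParameterError("cross_mode must be 'pair-magnitude' or 'mean-signal'")
    auto = SpectrumEstimate(f, np.mean(autos, axis=0), fs, nperseg, noverlap,
                            detrend=detrend)
    cross = SpectrumEstimate(f, cross_p, fs, nperseg, noverlap, detrend=detrend)
    return auto, cross


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_powerlaw(spectrum: SpectrumEstimate, f_lo: float = FIT_BAND[0],
                 f_hi: float = FIT_BAND[1]) -> PowerLawFit:
    """Least-squares line in log10-log10 space over [f_lo, f_hi]."""
    m = spectrum.band_mask((f_lo, f_hi)) & (spectrum.freqs > 0)
    if m.sum() < 5:
        raise FitError(f"need >= 5 bins in [{f_lo}, {f_hi}] Hz, have {int(m.sum())}")
    p = spectrum.power[m]
    if np.any(p <= 0):
        raise FitError("nonpositive power inside the fit band")
    lx, ly = np.log10(spectrum.freqs[m]), np.log10(p)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(exponent=float(slope), intercept=float(intercept),
                       band=(f_lo, f_hi), r_squared=float(max(0.0, min(1.0, r2))))


def fit_lorentzian(spectrum: SpectrumEstimate, f_min: float = 0.0,
                   f_max: Optional[float] = None, refine: bool = False) -> LorentzianFit:
    """Fit S(f) = A / (1 + (f/f_knee)^2) by least squares in log power.

    With ``refine=True`` a second pass restricts the fit to the knee region
    (a factor 20 below to a factor 5 above the first-pass knee), discounting
    the far tail where a discretely integrated unit deviates from the ideal
    first-order spectrum.
    """
    if refine:
        first = fit_lorentzian(spectrum, f_min, f_max, refine=False)
        lo = max(f_min, first.knee_freq / 20.0)
        hi = first.knee_freq * 5.0 if f_max is None else min(f_max, first.knee_freq * 5.0)
        try:
            return fit_lorentzian(spectrum, lo, hi, refine=False)
        except FitError:
            return first
    f, p = spectrum.freqs, spectrum.power
    keep = (f > 0) & (f >= f_min) & (p > 0)
    if f_max is not None:
        keep &= f <= f_max
    f, p = f[keep], p[keep]
    if f.size < 8 or f[-1] / f[0] < 30.0:
        raise FitError("spectrum must span at least 1.5 decades for a knee fit")

    def model(logf, logA, logfk):
        return logA - np.log10(1.0 + (10.0 ** (logf - logfk)) ** 2)

    plateau = np.median(np.log10(p[: max(4, f.size // 20)]))
    below = np.log10(p) < plateau - np.log10(2.0)
    fk0 = np.log10(f[np.argmax(below)] if below.any() else np.sqrt(f[0] * f[-1]))
    try:
        popt, _ = curve_fit(model, np.log10(f), np.log10(p), p0=[plateau, fk0],
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Lorentzian fit did not converge: {exc}") from exc
    resid = np.log10(p) - model(np.log10(f), *popt)
    return LorentzianFit(amplitude=float(10.0 ** popt[0]),
                         knee_freq=float(10.0 ** popt[1]),
                         residual_norm=float(np.sqrt(np.mean(resid ** 2))))


def fit_scale_k(sim: SpectrumEstimate, ref: SpectrumEstimate,
                band: Sequence[float] = FIT_BAND) -> float:
    """Least-squares amplitude scaling factor k matching sim to ref in log power.

    The free multiplier that aligns a simulated spectrum with a reference one
    (different estimators scale differently); it is reported and applied
    explicitly via ``SpectrumEstimate.rescaled``, never silently.
    """
    m = sim.band_mask(band) & (sim.freqs > 0) & (sim.power > 0)
    f = sim.freqs[m]
    rm = (ref.freqs > 0) & (ref.power > 0)
    lo, hi = ref.freqs[rm].min(), ref.freqs[rm].max()
    keep = (f >= lo) & (f <= hi)
    _require(keep.sum() >= 3, "need >= 3 overlapping bins to fit the scale factor")
    pr = np.interp(np.log10(f[keep]), np.log10(ref.freqs[rm]), np.log10(ref.power[rm]))
    return float(10.0 ** np.mean(pr - np.log10(sim.power[m][keep])))


def knee_from_tau(tau: float) -> float:
    """Lorentzian knee frequency of a first-order unit, 1 / (2 pi tau)."""
    _require(tau > 0, "tau must be positive")
    return 1.0 / (2.0 * np.pi * tau)


# ---------------------------------------------------------------------------
# band statistics
# ---------------------------------------------------------------------------

def band_power(spectrum: SpectrumEstimate, band: Sequence[float]) -> float:
    """Mean power over the bins inside ``band``."""
    return float(spectrum.power[spectrum.band_mask(band)].mean())


def log_power_ratio(auto: SpectrumEstimate, cross: SpectrumEstimate,
                    band: Sequence[float] = LOW_BAND) -> float:
    """log10 of auto over cross mean band power."""
    return float(np.log10(band_power(auto, band) / band_power(cross, band)))


def exponent_ratio(auto: SpectrumEstimate, cross: SpectrumEstimate,
                   band: Sequence[float] = FIT_BAND) -> float:
    """Ratio of low-frequency power-law exponents, auto over cross.

    The alternative reading of the auto/cross "log ratio" statistic: the
    regression slopes of the two spectra in log-log space over ``band``,
    reported as exponent(auto) / exponent(cross).
    """
    ea = fit_powerlaw(auto, *band).exponent
    ec = fit_powerlaw(cross, *band).exponent
    if ec == 0:
        raise FitError("cross-spectrum exponent is zero; ratio undefined")
    return float(ea / ec)


def slow_fast_ratio(spectrum: SpectrumEstimate, slow_band: Sequence[float] = LOW_BAND,
                    fast_band: Sequence[float] = FAST_BAND) -> float:
    """Mean slow-band power normalised by mean fast-band power."""
    return band_power(spectrum, slow_band) / band_power(spectrum, fast_band)


def spectrum_to_csv(spectrum: SpectrumEstimate, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.freqs, spectrum.power]),
               delimiter=",", header="freq_hz,power", comments="")
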