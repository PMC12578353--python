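"""Synthetic stand-ins for the (non-deposited) intracranial recordings.

The calibration stage needs "empirical" inputs with three properties of
resting-state high-frequency-broadband (HFB) envelopes: a two-regime
power-law spectrum with a knee near 1 Hz, an inter-channel Pearson
correlation of about 0.56 for the slow (< 0.1 Hz) fluctuations, and an
auto-to-cross low-frequency log power ratio of about 0.84.  Everything in
this module is synthetic by construction and is labelled as such in the
files it writes; it emulates only those statistical properties, not clinical
artefacts (line noise, transients, drift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .params import InvalidParameterError, _require
from . import spectral as sp


@dataclass(frozen=True)
class SurrogateSpec:
    """Two-regime spectrum and cross-channel structure of the surrogate data."""

    exponent_low: float = -0.8    # log-log slope below the knee
    exponent_high: float = -2.0   # slope above the knee
    knee_hz: float = 1.0
    amplitude: float = 1.0
    r_target: float = 0.56        # slow-band Pearson correlation between channels
    log_ratio_target: float = 0.84
    duration: float = 1200.0
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.exponent_low <= 0 and self.exponent_high <= 0,
                 "exponents must be <= 0")
        _require(self.knee_hz > 0, "knee must be positive")
        _require(-1.0 < self.r_target < 1.0, "r_target must lie in (-1, 1)")
        _require(self.amplitude > 0, "amplitude must be positive")
        _require(self.duration * self.fs >= 2048, "surrogate too short")


def surrogate_spectrum(spec: SurrogateSpec,
                       freqs: np.ndarray | None = None) -> sp.SpectrumEstimate:
    """Deterministic two-regime power-law spectrum with a smooth knee.

    S(f) = A * f^a_low * (1 + (f/knee)^2)^((a_high - a_low)/2): slope a_low
    well below the knee, a_high well above it.
    """
    if freqs is None:
        nper = min(int(256 * spec.fs), int(spec.duration * spec.fs))
        freqs = np.fft.rfftfreq(nper, d=1.0 / spec.fs)[1:]
    freqs = np.asarray(freqs, dtype=float)
    _require(np.all(freqs > 0), "frequency grid must be positive")
    s = (spec.amplitude * freqs ** spec.exponent_low
         * (1.0 + (freqs / spec.knee_hz) ** 2) ** ((spec.exponent_high - spec.exponent_low) / 2.0))
    return sp.SpectrumEstimate(freqs=freqs, power=s, fs=spec.fs,
                               nperseg=2 * (freqs.size), noverlap=0,
                               window="analytic", detrend=None)


def _shaped_noise(spec: SurrogateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """White noise coloured by the square root of the target spectrum."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    shape = np.zeros_like(f)
    pos = f > 0
    shape[pos] = np.sqrt(surrogate_spectrum(spec, f[pos]).power)
    return np.fft.irfft(X * shape, n=n)


def surrogate_pair(spec: SurrogateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two channels sharing a common component so the slow-band Pearson
    correlation has expectation ``r_target``.

    Each channel is sqrt(w)*common + sqrt(1-w)*independent with w = r_target
    (all components identically spectrally shaped, so the mixture weight is
    the correlation at every frequency).
    """
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    w = spec.r_target
    if w < 0:
        raise InvalidParameterError("negative r_target not supported by the mixture")
    common = _shaped_noise(spec, n, rng)
    a = np.sqrt(w) * common + np.sqrt(1 - w) * _shaped_noise(spec, n, rng)
    b = np.sqrt(w) * common + np.sqrt(1 - w) * _shaped_noise(spec, n, rng)
    return a, b


def surrogate_bundle(spec: SurrogateSpec, out_dir) -> dict:
    """Write the synthetic channel pair, spectra, and a manifest to ``out_dir``.

    Files: ``channels.csv`` (time, ch1, ch2), ``auto_spectrum.csv`` and
    ``cross_spectrum.csv`` (freq_hz, power), ``manifest.json``.  The cross
    spectrum is the estimated cross-spectral density rescaled so the
    realised low-band auto/cross log ratio equals ``log_ratio_target`` (the
    scale factor is recorded in the manifest) — the bundle's role is to carry
    the empirical reference statistics, all of which are synthetic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a, b = surrogate_pair(spec)
    t = np.arange(a.size) / spec.fs
    np.savetxt(out / "channels.csv", np.column_stack([t, a, b]), delimiter=",",
               header="time_s,ch1_synthetic,ch2_synthetic", comments="")
    nper = min(int(128 * spec.fs), a.size // 2)
    auto, cross = sp.auto_cross_psd(a[None, :], b[None, :], spec.fs, nperseg=nper,
                                    cross_mode="mean-signal", demean=True)
    realized_raw = sp.log_power_ratio(auto, cross, sp.LOW_BAND)
    scale = 10.0 ** (realized_raw - spec.log_ratio_target)
    cross = cross.rescaled(scale)
    rep = sp.pair_correlations(np.vstack([a, b]), spec.fs)
    manifest = {
        "synthetic": True,
        "spec": asdict(spec),
        "realized_low_band_log_ratio": sp.log_power_ratio(auto, cross, sp.LOW_BAND),
        "raw_log_ratio_before_scaling": realized_raw,
        "cross_scale_factor": scale,
        "realized_slow_correlation": rep.mean_r,
        "low_band_hz": list(sp.LOW_BAND),
    }
    sp.spectrum_to_csv(auto, out / "auto_spectrum.csv")
    sp.spectrum_to_csv(cross, out / "cross_spectrum.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
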