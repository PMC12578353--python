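"""External drives, electrode-proxy summation, stationarity trimming, block protocol."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import signal as sps
from statsmodels.tsa.stattools import adfuller

from .params import NetworkParams, NoiseSpec, ProxySpec, BlockProtocol, InvalidParameterError, _require
from .netsim import WeightMatrix, RateTraces, simulate


class NonStationarySignalError(RuntimeError):
    """No trailing segment of the signal passes the stationarity test."""


def make_drive(spec: NoiseSpec, n_units: int, n_steps: int,
               dt: float = 0.001) -> np.ndarray:
    """Materialise the external input stream, shape (n_units, n_steps), pA.

    Independent Normal(mean, sd) draw per unit per integration step; when a
    high-pass shaping is requested it is applied along time (zero-phase
    Butterworth) to the zero-mean part before the mean and DC offset are
    restored, so filtering changes only the temporal correlation structure,
    not the marginal mean.
    """
    _require(n_steps >= 1, "n_steps must be >= 1")
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(0.0, spec.sd, size=(n_units, n_steps))
    if spec.highpass is not None:
        nyq = 0.5 / dt
        _require(spec.highpass.cutoff_hz < nyq, "high-pass cutoff must be below Nyquist")
        sos = sps.butter(spec.highpass.order, spec.highpass.cutoff_hz,
                         btype="highpass", fs=1.0 / dt, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    return x + (spec.mean + spec.dc_offset)


def ieeg_proxy(traces: RateTraces, spec: ProxySpec) -> list[np.ndarray]:
    """Sum the rates of each sampled unit set: one iEEG-like signal per sample.

    Sample membership is reproducible from ``spec.seed``; the samples are
    mutually disjoint.
    """
    samples = spec.draw(traces.n_units)
    if spec.sample_size(traces.n_units) < 1:  # pragma: no cover - guarded in spec
        raise InvalidParameterError("alpha * N < 1: empty electrode sample")
    return [traces.values[idx].sum(axis=0) for idx in samples]


def proxy_unit_sets(traces: RateTraces, spec: ProxySpec) -> list[np.ndarray]:
    """The sampled unit-index sets behind :func:`ieeg_proxy` (same draw)."""
    return spec.draw(traces.n_units)


def trim_to_stationary(x: np.ndarray, fs: float, p_threshold: float = 0.01,
                       step: float = 10.0, max_discard: Optional[float] = None,
                       regression: str = "c") -> tuple[np.ndarray, float]:
    """Iteratively drop a prefix until the ADF test rejects non-stationarity.

    Removes the smallest prefix, in increments of ``step`` seconds, such that
    the augmented Dickey-Fuller test on the remainder attains
    p < ``p_threshold``.  Returns (trimmed signal, discarded seconds).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    step_n = max(1, int(round(step * fs)))
    _require(n > 2 * step_n, "signal must be longer than twice the trimming step")
    limit = n // 2 if max_discard is None else int(round(max_discard * fs))
    start = 0
    while start <= limit:
        seg = x[start:]
        # adfuller needs variation; a constant segment is non-stationarity-free
        if np.ptp(seg) == 0:
            return seg, start / fs
        p = adfuller(seg, regression=regression, autolag="AIC")[1]
        if p < p_threshold:
            return seg, start / fs
        start += step_n
    raise NonStationarySignalError(
        f"no suffix up to a {limit / fs:.0f} s discard reached ADF p < {p_threshold}")


@dataclass(frozen=True)
class ConditionResult:
    label: str
    traces: RateTraces
    proxies: list[np.ndarray]
    unit_sets: list[np.ndarray]
    noise: NoiseSpec


def run_block_protocol(W: WeightMatrix, base_noise: NoiseSpec,
                       protocol: BlockProtocol, proxy: ProxySpec,
                       params: Optional[NetworkParams] = None) -> list[ConditionResult]:
    """One simulation per condition over the same weight realisation.

    Each condition entry is ``(label, modifier)`` where the modifier is either
    a DC shift in pA (added to the drive mean, the I_add route) or a
    ``("gain", multiplier)`` pair that scales gamma (the gain route).  All
    conditions share the weight matrix and the noise seed, isolating the
    modifier's effect; the stabilisation discard is applied before the
    proxies are formed.
    """
    p = W.params if params is None else params
    out = []
    for cond in protocol.conditions:
        label, mod = cond
        noise, run_p = base_noise, p
        if isinstance(mod, tuple) and len(mod) == 2 and mod[0] == "gain":
            run_p = p.replace(gain=p.gain * float(mod[1]))
        else:
            noise = base_noise.replace(dc_offset=base_noise.dc_offset + float(mod))
        tr = simulate(W, noise, protocol.block_length, params=run_p)
        keep = tr.values[:, int(round(protocol.discard * tr.fs)):]
        tr = RateTraces(values=keep, fs=tr.fs, t_start=protocol.discard,
                        params=run_p, input_meta=tr.input_meta)
        out.append(ConditionResult(label=label, traces=tr,
                                   proxies=ieeg_proxy(tr, proxy),
                                   unit_sets=proxy_unit_sets(tr, proxy),
                                   noise=noise))
    return out
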