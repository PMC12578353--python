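"""Sparse random recurrent rate network: construction, linear stability, integration.

The model is the rectified-linear rate network

    tau * dr_j/dt = -r_j + gamma * [ sum_k W_jk r_k + I_j^ext(t) ]_+

whose proximity to the instability of the mean (uniform) activity mode is
set by the dimensionless control parameter G = gamma * p * mu_conn.  The
weight matrix is Bernoulli(p)-sparse with nonzero entries drawn from
Normal(mu_conn/N, (sigma_conn/N)^2); with this normalisation the dominant
eigenvalue of gamma*W concentrates on G, and the linearised dynamics lose
stability at G = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numba import njit

from .params import NetworkParams, NoiseSpec, InvalidParameterError, _require


class SupercriticalRunawayError(RuntimeError):
    """Raised when a rate exceeds the overflow guard during integration."""


#: any rate above this (Hz) is treated as runaway growth
RATE_OVERFLOW_GUARD = 1.0e6

#: output sampling rate of stored rate traces (Hz)
DEFAULT_FS_OUT = 250.0


@dataclass(frozen=True)
class WeightMatrix:
    weights: np.ndarray            # (N, N), pA/Hz per unit presynaptic rate
    params: NetworkParams
    realized_sparseness: float

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class LinearizationReport:
    """Eigen-analysis of gamma*W and the derived stability quantities.

    ``effective_gain`` is the largest real part of the eigenvalues of
    gamma*W (the realisation-specific counterpart of G); the dominant
    eigenvalue of the Jacobian of the linearised dynamics is
    (effective_gain - 1)/tau, and the predicted relaxation time of the
    uniform mode is tau / (1 - effective_gain) for effective_gain < 1.
    """

    eigenvalues: np.ndarray
    dominant_real: float
    effective_gain: float
    jacobian_dominant: float
    predicted_timescale: float


@dataclass(frozen=True)
class RateTraces:
    values: np.ndarray             # (n_units, n_timepoints), Hz, >= 0
    fs: float
    t_start: float
    params: NetworkParams
    input_meta: str = ""

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.values.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# control parameter
# ---------------------------------------------------------------------------

def control_parameter(gain: float, sparseness: float, conn_mean: float) -> float:
    """G = gain * sparseness * conn_mean (dimensionless)."""
    for name, v in (("gain", gain), ("sparseness", sparseness), ("conn_mean", conn_mean)):
        if not np.isfinite(v) or v < 0:
            raise InvalidParameterError(f"{name} must be finite and nonnegative")
    return gain * sparseness * conn_mean


def gamma_for_G(target_G: float, sparseness: float, conn_mean: float) -> float:
    """Gain placing the network at control parameter ``target_G``."""
    denom = sparseness * conn_mean
    if denom <= 0:
        raise InvalidParameterError("sparseness * conn_mean must be positive")
    if not np.isfinite(target_G) or target_G < 0:
        raise InvalidParameterError("target_G must be finite and nonnegative")
    return target_G / denom


# ---------------------------------------------------------------------------
# construction and linearisation
# ---------------------------------------------------------------------------

def build_weights(params: NetworkParams, seed: Optional[int] = None) -> WeightMatrix:
    """Draw the Bernoulli(p)-masked Gaussian weight matrix.

    Nonzero entries ~ Normal(conn_mean/N, (conn_sd/N)^2); self-connections
    are treated like any other entry.
    """
    n = params.n_units
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mask = rng.random((n, n)) < params.sparseness
    vals = rng.normal(params.conn_mean / n, params.conn_sd / n, size=(n, n))
    w = np.where(mask, vals, 0.0)
    return WeightMatrix(weights=w, params=params,
                        realized_sparseness=float(mask.mean()))


def linearize(W: Union[WeightMatrix, np.ndarray], gain: Optional[float] = None,
              tau: Optional[float] = None) -> LinearizationReport:
    """Full eigen-spectrum of gamma*W and the stability summary."""
    if isinstance(W, WeightMatrix):
        mat, p = W.weights, W.params
        gain = p.gain if gain is None else gain
        tau = p.tau if tau is None else tau
    else:
        mat = np.asarray(W, dtype=float)
        if gain is None or tau is None:
            raise InvalidParameterError("gain and tau are required for a bare matrix")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidParameterError("weight matrix must be square")
    try:
        eig = np.linalg.eigvals(gain * mat)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy fallback rare
        raise np.linalg.LinAlgError(
            f"eigen-decomposition failed for {mat.shape[0]}x{mat.shape[0]} matrix "
            f"(norm={np.linalg.norm(mat):.3g}): {exc}") from exc
    g_eff = float(eig.real.max()) if eig.size else 0.0
    return LinearizationReport(
        eigenvalues=eig,
        dominant_real=g_eff,
        effective_gain=g_eff,
        jacobian_dominant=(g_eff - 1.0) / tau,
        predicted_timescale=(tau / (1.0 - g_eff)) if g_eff < 1.0 else np.inf,
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _euler_chunk(w, r, drive, a, b, decim, phase, acc, out, out_pos, guard):
    """Integrate one chunk of steps; returns (out_pos, phase, overflow_step).

    r <- r*(1-dt/tau) + (dt/tau)*gamma*relu(W r + I_t); ``a`` = 1-dt/tau,
    ``b`` = (dt/tau)*gamma.  Output is decimated by block averaging over
    ``decim`` consecutive steps (boxcar anti-aliasing: the averager has
    spectral nulls at the frequencies that would fold onto the stored band).
    """
    n_steps = drive.shape[1]
    n = r.shape[0]
    inv = 1.0 / decim
    for t in range(n_steps):
        u = np.dot(w, r)
        for j in range(n):
            v = u[j] + drive[j, t]
            if v < 0.0:
                v = 0.0
            r[j] = a * r[j] + b * v
            acc[j] += r[j]
        phase += 1
        if phase == decim:
            phase = 0
            rmax = 0.0
            for j in range(n):
                out[j, out_pos] = acc[j] * inv
                if r[j] > rmax:
                    rmax = r[j]
                acc[j] = 0.0
            out_pos += 1
            if rmax > guard:
                return out_pos, phase, t
    return out_pos, phase, -1


def _drive_chunks(drive, n_units: int, n_steps: int, chunk: int, dtype, dt: float):
    """Yield (start, block) pairs of the external input, pA, shape (N, k)."""
    if isinstance(drive, np.ndarray):
        if drive.shape != (n_units, n_steps):
            raise InvalidParameterError(
                f"drive array must have shape ({n_units}, {n_steps}), got {drive.shape}")
        for s in range(0, n_steps, chunk):
            yield s, np.ascontiguousarray(drive[:, s:s + chunk], dtype=dtype)
        return
    if isinstance(drive, NoiseSpec):
        if drive.highpass is not None:
            from .signal_synth import make_drive  # filtered drives are materialised
            arr = make_drive(drive, n_units, n_steps, dt=dt)
            yield from _drive_chunks(arr, n_units, n_steps, chunk, dtype, dt)
            return
        rng = np.random.default_rng(drive.seed)
        loc = drive.mean + drive.dc_offset
        for s in range(0, n_steps, chunk):
            k = min(chunk, n_steps - s)
            yield s, rng.normal(loc, drive.sd, size=(n_units, k)).astype(dtype)
        return
    raise InvalidParameterError(f"unsupported drive type: {type(drive)!r}")


def simulate(W: WeightMatrix, drive, duration: float,
             initial_state: Optional[np.ndarray] = None,
             params: Optional[NetworkParams] = None,
             fs_out: float = DEFAULT_FS_OUT,
             chunk_steps: int = 20000,
             dtype=np.float32) -> RateTraces:
    """Forward-Euler integration of the rectified-linear rate dynamics.

    Parameters
    ----------
    W
        Weight matrix realisation (its ``params`` supply gamma, tau, dt
        unless ``params`` overrides them).
    drive
        Either a :class:`~critnet.params.NoiseSpec` (white, optionally
        high-pass-shaped, optionally DC-shifted noise generated on the fly,
        one independent draw per unit per integration step) or an explicit
        (n_units, n_steps) array in pA.
    duration
        Simulated time in seconds; the trace is stored at ``fs_out``.
    dtype
        Working precision of the integration kernel.  Single precision is
        the default (the stochastic discretisation error dominates rounding
        by many orders of magnitude); pass ``np.float64`` for double.

    Raises
    ------
    SupercriticalRunawayError
        If any rate exceeds the overflow guard (runaway growth above the
        critical point).
    """
    p = W.params if params is None else params
    n = W.n_units
    decim = int(round(1.0 / (fs_out * p.dt)))
    if decim < 1 or abs(decim * fs_out * p.dt - 1.0) > 1e-9:
        raise InvalidParameterError("1/(fs_out*dt) must be a positive integer")
    n_steps = int(round(duration / p.dt))
    n_out = n_steps // decim
    dtype = np.dtype(dtype).type
    if initial_state is None:
        r = np.zeros(n, dtype=dtype)
    else:
        r = np.array(initial_state, dtype=dtype)
        _require(r.shape == (n,), "initial_state must have one entry per unit")
        _require(np.all(r >= 0), "initial_state must be nonnegative")

    w = np.ascontiguousarray(W.weights, dtype=dtype)
    a = dtype(1.0 - p.dt / p.tau)
    b = dtype((p.dt / p.tau) * p.gain)
    guard = dtype(RATE_OVERFLOW_GUARD)
    out = np.empty((n, n_out), dtype=dtype)
    acc = np.zeros(n, dtype=dtype)
    pos, phase = 0, 0
    for start, block in _drive_chunks(drive, n, n_steps, chunk_steps, dtype, p.dt):
        pos, phase, bad = _euler_chunk(w, r, block, a, b, decim, phase, acc, out, pos, guard)
        if bad >= 0:
            rep = linearize(W, gain=p.gain, tau=p.tau)
            raise SupercriticalRunawayError(
                f"rate exceeded {RATE_OVERFLOW_GUARD:g} Hz at step {start + bad} "
                f"(t={(start + bad) * p.dt:.3f} s); effective_gain={rep.effective_gain:.4f}")
    meta = repr(drive) if isinstance(drive, NoiseSpec) else "explicit drive array"
    return RateTraces(values=out[:, :pos].astype(np.float64), fs=fs_out,
                      t_start=0.0, params=p, input_meta=meta)
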