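"""Parameter containers for the network model, drives and sampling.

All quantities carry the units used throughout the package: currents in pA,
rates in Hz, connection strengths in pA/Hz (current per unit presynaptic
rate), times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml


class InvalidParameterError(ValueError):
    """A model parameter is out of its admissible range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class NetworkParams:
    """Generative constants of the sparse random recurrent rate network.

    Attributes
    ----------
    n_units
        Network size N.
    sparseness
        Connection probability p of each entry of the weight matrix.
    conn_mean, conn_sd
        Mean and SD (pA/Hz) of the nonzero connection strengths *before*
        the 1/N normalisation applied at matrix construction.
    gain
        Slope of the rectified-linear f-I curve (Hz/pA).
    tau
        Characteristic integration time constant (s).
    dt
        Forward-Euler integration step (s); must satisfy dt <= tau / 10.
    seed
        Seed for the weight-matrix draw.
    """

    n_units: int = 240
    sparseness: float = 0.2
    conn_mean: float = 49.881
    conn_sd: float = 4.988
    gain: float = 0.1
    tau: float = 0.020
    dt: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sparseness", "conn_mean", "conn_sd", "gain", "tau", "dt"):
            _require(np.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.n_units >= 2, "n_units must be >= 2")
        _require(0.0 <= self.sparseness <= 1.0, "sparseness must lie in [0, 1]")
        _require(self.tau > 0, "tau must be positive")
        _require(0 < self.dt <= self.tau / 10.0, "dt must satisfy 0 < dt <= tau/10")
        _require(self.gain >= 0, "gain must be nonnegative")
        _require(self.conn_sd >= 0, "conn_sd must be nonnegative")
        G = self.gain * self.sparseness * self.conn_mean
        _require(np.isfinite(G) and G >= 0, "control parameter gpmu must be finite and >= 0")

    @property
    def control_parameter(self) -> float:
        """Theoretical control parameter G = gain * sparseness * conn_mean."""
        return self.gain * self.sparseness * self.conn_mean

    def replace(self, **kw) -> "NetworkParams":
        d = asdict(self)
        d.update(kw)
        return NetworkParams(**d)


@dataclass(frozen=True)
class HighpassSpec:
    """Butterworth high-pass shaping applied to the white drive (zero phase)."""

    cutoff_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        _require(self.cutoff_hz > 0, "high-pass cutoff must be positive")
        _require(self.order >= 1, "filter order must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """External drive: per-unit, per-step independent Gaussian current (pA).

    ``dc_offset`` is the constant shift I_add used to emulate the
    recall-condition baseline increase; it is added after any filtering.
    """

    mean: float = 20.0
    sd: float = 11.5
    dc_offset: float = 0.0
    highpass: Optional[HighpassSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        _require(np.isfinite(self.mean) and np.isfinite(self.sd), "noise mean/sd must be finite")
        _require(self.sd >= 0, "noise sd must be nonnegative")

    def replace(self, **kw) -> "NoiseSpec":
        d = dict(mean=self.mean, sd=self.sd, dc_offset=self.dc_offset,
                 highpass=self.highpass, seed=self.seed)
        d.update(kw)
        return NoiseSpec(**d)


@dataclass(frozen=True)
class ProxySpec:
    """Electrode-like sampling: sum the rates of round(alpha*N) random units.

    Two disjoint samples are drawn so that auto-spectra can be estimated from
    the first sample and cross-spectra from unit pairs across both.
    """

    alpha: float = 0.01
    n_samples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 < self.alpha <= 1.0, "alpha must lie in (0, 1]")
        _require(self.n_samples >= 1, "n_samples must be >= 1")

    def sample_size(self, n_units: int) -> int:
        return max(1, int(round(self.alpha * n_units)))

    def replace_seed(self, seed: int) -> "ProxySpec":
        return ProxySpec(alpha=self.alpha, n_samples=self.n_samples, seed=int(seed))

    def draw(self, n_units: int) -> list[np.ndarray]:
        """Disjoint unit-index sets, reproducible from the seed."""
        k = self.sample_size(n_units)
        _require(self.n_samples * k <= n_units,
                 "not enough units for disjoint samples of this size")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n_units)
        return [np.sort(perm[i * k:(i + 1) * k]) for i in range(self.n_samples)]


@dataclass(frozen=True)
class BlockProtocol:
    """Rest/recall style block design: equal-length conditions, shared discard."""

    block_length: float = 1800.0
    discard: float = 600.0
    conditions: Sequence[tuple] = field(default_factory=lambda: (("rest", 0.0), ("recall", 12.5)))

    def __post_init__(self) -> None:
        _require(self.block_length > 0, "block_length must be positive")
        _require(0 <= self.discard < self.block_length, "discard must lie in [0, block_length)")
        _require(len(self.conditions) >= 1, "conditions must be nonempty")


# ---------------------------------------------------------------------------
# Config round-trip (YAML; sections [network], [noise], [protocol])
# ---------------------------------------------------------------------------

def to_config(network: NetworkParams, noise: Optional[NoiseSpec] = None,
              protocol: Optional[BlockProtocol] = None) -> dict:
    cfg: dict = {"network": asdict(network)}
    if noise is not None:
        d = dict(mean=noise.mean, sd=noise.sd, dc_offset=noise.dc_offset, seed=noise.seed)
        if noise.highpass is not None:
            d["highpass"] = {"cutoff_hz": noise.highpass.cutoff_hz, "order": noise.highpass.order}
        cfg["noise"] = d
    if protocol is not None:
        cfg["protocol"] = {
            "block_length": protocol.block_length,
            "discard": protocol.discard,
            "conditions": [list(c) for c in protocol.conditions],
        }
    return cfg


def network_from_config(cfg: dict) -> NetworkParams:
    return NetworkParams(**cfg["network"])


def noise_from_config(cfg: dict) -> NoiseSpec:
    d = dict(cfg.get("noise", {}))
    hp = d.pop("highpass", None)
    if hp is not None:
        d["highpass"] = HighpassSpec(**hp)
    return NoiseSpec(**d)


def protocol_from_config(cfg: dict) -> BlockProtocol:
    d = dict(cfg.get("protocol", {}))
    if "conditions" in d:
        d["conditions"] = tuple(tuple(c) for c in d["conditions"])
    return BlockProtocol(**d)


def save_config(path, network: NetworkParams, noise: Optional[NoiseSpec] = None,
                protocol: Optional[BlockProtocol] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config(network, noise, protocol), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
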