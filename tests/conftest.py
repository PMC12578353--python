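import numpy as np
import pytest

from critnet import NetworkParams, NoiseSpec, build_weights, gamma_for_G, simulate


@pytest.fixture(scope="session")
def default_params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture(scope="session")
def near_critical_traces():
    """One 300 s realisation at G = 0.95 (N = 240), 100 s discarded."""
    p = NetworkParams(seed=11, gain=gamma_for_G(0.95, 0.2, 49.881))
    W = build_weights(p)
    tr = simulate(W, NoiseSpec(seed=12), 300.0)
    x = tr.values[:, int(100 * tr.fs):]
    return x, tr.fs, W


@pytest.fixture(scope="session")
def acceptance_scan():
    """The scaled-down calibration scan shared by the acceptance tests.

    Grid 0.80-0.99 step 0.01, 5 realisations per G, 400 s of analysed signal
    per run after a 100 s stabilisation discard.
    """
    from critnet.experiments import ScanConfig, correlation_scan
    return correlation_scan(ScanConfig(seed=0))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
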