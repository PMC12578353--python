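"""HDF5 persistence for weight matrices and rate traces."""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np

from .params import NetworkParams
from .netsim import WeightMatrix, RateTraces


def _write_params(grp, params: NetworkParams) -> None:
    for k, v in asdict(params).items():
        grp.attrs[k] = v


def _read_params(grp) -> NetworkParams:
    fields = NetworkParams.__dataclass_fields__
    kw = {k: grp.attrs[k] for k in fields if k in grp.attrs}
    kw["n_units"] = int(kw["n_units"])
    kw["seed"] = int(kw["seed"])
    return NetworkParams(**kw)


def save_weights(path, W: WeightMatrix) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("weights", data=W.weights)
        ds.attrs["realized_sparseness"] = W.realized_sparseness
        _write_params(fh, W.params)


def load_weights(path) -> WeightMatrix:
    with h5py.File(path, "r") as fh:
        return WeightMatrix(weights=fh["weights"][()],
                            params=_read_params(fh),
                            realized_sparseness=float(fh["weights"].attrs["realized_sparseness"]))


def save_traces(path, tr: RateTraces) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rates", data=tr.values.astype(np.float32))
        fh.create_dataset("time", data=tr.times)
        fh.attrs["fs"] = tr.fs
        fh.attrs["t_start"] = tr.t_start
        fh.attrs["input_meta"] = tr.input_meta
        _write_params(fh, tr.params)


def load_traces(path) -> RateTraces:
    with h5py.File(path, "r") as fh:
        return RateTraces(values=fh["rates"][()].astype(np.float64),
                          fs=float(fh.attrs["fs"]),
                          t_start=float(fh.attrs["t_start"]),
                          params=_read_params(fh),
                          input_meta=str(fh.attrs["input_meta"]))
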