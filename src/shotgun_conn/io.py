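"""Artifact serialization: HDF5 containers and TSV/JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .ell import InferenceResult
from .moments import MomentStats
from .netsim import NetworkParams, SpikeMatrix
from .observer import ObservationMask

__all__ = [
    "save_raster", "load_raster",
    "save_network", "load_network",
    "save_moments", "load_moments",
    "save_result", "load_result",
]


def save_raster(
    path, spikes: SpikeMatrix, mask: Optional[ObservationMask] = None, **meta
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("S", data=spikes.S.astype(np.uint8), chunks=True,
                         compression="gzip", track_times=False)
        f.attrs["bin_width"] = spikes.bin_width
        if mask is not None:
            f.create_dataset("O", data=mask.O.astype(np.uint8), chunks=True,
                             compression="gzip", track_times=False)
            f.attrs["scheme"] = mask.scheme
            f.attrs["p_obs_target"] = mask.p_obs_target
        for k, v in meta.items():
            f.attrs[k] = v


def load_raster(path) -> tuple[SpikeMatrix, Optional[ObservationMask]]:
    with h5py.File(path, "r") as f:
        spikes = SpikeMatrix(S=f["S"][()], bin_width=float(f.attrs.get("bin_width", 0.01)))
        mask = None
        if "O" in f:
            mask = ObservationMask(
                O=f["O"][()],
                scheme=str(f.attrs.get("scheme", "custom")),
                p_obs_target=float(f.attrs.get("p_obs_target", 1.0)),
            )
    return spikes, mask


def save_network(path, params: NetworkParams, **meta) -> None:
    """Dense TSV weight matrix plus a JSON sidecar for b, G and metadata."""
    path = Path(path)
    np.savetxt(path, params.W, delimiter="\t")
    side = {"b": params.b.tolist(), **meta}
    if params.G is not None:
        side["G"] = params.G.tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))


def load_network(path) -> NetworkParams:
    path = Path(path)
    W = np.loadtxt(path, delimiter="\t")
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    G = np.asarray(side["G"]) if "G" in side else None
    return NetworkParams(W=W, b=np.asarray(side["b"]), G=G)


def save_moments(path, mom: MomentStats, **meta) -> None:
    with h5py.File(path, "w") as f:
        for name in ("m", "Sigma0", "Sigma1", "count_m", "count0", "count1"):
            f.create_dataset(name, data=getattr(mom, name), track_times=False)
        f.attrs["T_effective"] = mom.T_effective
        for k, v in meta.items():
            f.attrs[k] = v


def load_moments(path) -> MomentStats:
    with h5py.File(path, "r") as f:
        return MomentStats(
            m=f["m"][()], Sigma0=f["Sigma0"][()], Sigma1=f["Sigma1"][()],
            count_m=f["count_m"][()], count0=f["count0"][()], count1=f["count1"][()],
            T_effective=int(f.attrs["T_effective"]),
        )


def save_result(path, res: InferenceResult, **meta) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W_hat", data=res.W_hat, track_times=False)
        f.create_dataset("b_hat", data=res.b_hat, track_times=False)
        f.create_dataset("objective_trace", data=res.objective_trace,
                         track_times=False)
        f.attrs["lambda_used"] = res.lambda_used
        f.attrs["iterations"] = res.iterations
        f.attrs["converged"] = res.converged
        f.attrs["flags"] = json.dumps(
            {k: v for k, v in res.flags.items() if _jsonable(v)}
        )
        for k, v in meta.items():
            f.attrs[k] = v


def load_result(path) -> InferenceResult:
    with h5py.File(path, "r") as f:
        return InferenceResult(
            W_hat=f["W_hat"][()], b_hat=f["b_hat"][()],
            lambda_used=float(f.attrs["lambda_used"]),
            objective_trace=f["objective_trace"][()],
            iterations=int(f.attrs["iterations"]),
            converged=bool(f.attrs["converged"]),
            flags=json.loads(str(f.attrs.get("flags", "{}"))),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
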