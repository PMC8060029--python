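"""HDF5 fixtures for paired recordings, plus TIFF movie export."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .ephys import VoltageTrace
from .synthetic_data import GroundTruthRecording, SimConfig


def write_recording(path, rec: GroundTruthRecording) -> None:
    """Write a recording to HDF5 (groups /vm, /ap_times, /movie, /masks, /truth;
    the config rides along as a JSON root attribute)."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = rec.config.to_json()
        f.attrs["provenance"] = json.dumps(rec.provenance)
        g = f.create_group("vm")
        g.create_dataset("samples", data=rec.vm.samples, compression="gzip")
        g.attrs["rate"] = rec.vm.rate
        g.attrs["t0"] = rec.vm.t0
        f.create_dataset("ap_times", data=rec.ap_times)
        m = f.create_group("movie")
        m.create_dataset("data", data=rec.movie, compression="gzip")
        m.attrs["frame_rate"] = rec.frame_rate
        masks = f.create_group("masks")
        masks.create_dataset("soma", data=rec.soma_mask)
        masks.create_dataset("neuropil", data=rec.neuropil_mask)
        t = f.create_group("truth")
        for key, val in rec.truth.items():
            t.create_dataset(key, data=np.asarray(val))


def read_recording(path) -> GroundTruthRecording:
    with h5py.File(path, "r") as f:
        config = SimConfig.from_json(f.attrs["config"])
        provenance = json.loads(f.attrs.get("provenance", "[]"))
        vm = VoltageTrace(f["vm/samples"][...], float(f["vm"].attrs["rate"]),
                          float(f["vm"].attrs["t0"]))
        truth = {k: f["truth"][k][...] for k in f["truth"]}
        truth["r_true"] = float(truth["r_true"])
        truth["photon_gain"] = float(truth["photon_gain"])
        truth["pedestal"] = float(truth["pedestal"])
        return GroundTruthRecording(
            ap_times=f["ap_times"][...], vm=vm, movie=f["movie/data"][...],
            frame_rate=float(f["movie"].attrs["frame_rate"]),
            soma_mask=f["masks/soma"][...].astype(bool),
            neuropil_mask=f["masks/neuropil"][...].astype(bool),
            truth=truth, config=config, provenance=provenance)


def export_tiff(path, movie: np.ndarray) -> None:
    """Write a movie as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
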