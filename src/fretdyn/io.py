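"""File I/O: photon streams, decay curves and distance tables.

Photon streams use a portable Photon-HDF5-style layout
(``photon_data/{timestamps, nanotimes, detectors}`` plus the sync period
and micro-channel width as attributes) with a plain-CSV fallback; decay
curves are two-column whitespace text with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_fit import DecayCurve, DecayDataset
from .photon_sim import PhotonStream

__all__ = [
    "write_photon_hdf5",
    "read_photon_hdf5",
    "write_photon_csv",
    "read_photon_csv",
    "write_decay",
    "read_decay",
    "write_decay_dataset",
    "read_decay_dataset",
    "read_distance_set",
    "write_distance_set",
]


def write_photon_hdf5(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.macrotimes)
        g.create_dataset("nanotimes", data=stream.microtimes)
        g.create_dataset("detectors", data=stream.detectors)
        g.attrs["timestamps_unit_s"] = stream.sync_period_s
        g.attrs["nanotimes_unit_ns"] = stream.micro_channel_width_ns
        g.attrs["nanotimes_num_channels"] = stream.n_channels
        g.attrs["duration_s"] = stream.duration_s


def read_photon_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        return PhotonStream(
            macrotimes=g["timestamps"][:],
            microtimes=g["nanotimes"][:],
            detectors=g["detectors"][:],
            sync_period_s=float(g.attrs["timestamps_unit_s"]),
            micro_channel_width_ns=float(g.attrs["nanotimes_unit_ns"]),
            n_channels=int(g.attrs["nanotimes_num_channels"]),
            meta={"duration_s": float(g.attrs.get("duration_s", 0.0))},
        )


def write_photon_csv(stream: PhotonStream, path) -> None:
    df = pd.DataFrame({
        "macrotime_ticks": stream.macrotimes,
        "microtime_channel": stream.microtimes,
        "detector": stream.detectors,
    })
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({
        "sync_period_s": stream.sync_period_s,
        "micro_channel_width_ns": stream.micro_channel_width_ns,
        "n_channels": stream.n_channels,
        "duration_s": stream.duration_s,
    }))


def read_photon_csv(path) -> PhotonStream:
    df = pd.read_csv(path)
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return PhotonStream(
        macrotimes=df["macrotime_ticks"].to_numpy(np.int64),
        microtimes=df["microtime_channel"].to_numpy(np.int32),
        detectors=df["detector"].to_numpy(np.int8),
        sync_period_s=meta["sync_period_s"],
        micro_channel_width_ns=meta["micro_channel_width_ns"],
        n_channels=meta["n_channels"],
        meta={"duration_s": meta.get("duration_s", 0.0)},
    )


def write_decay(curve: DecayCurve, path, meta: dict | None = None) -> None:
    curve.to_text(path)
    if meta is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(meta))


def read_decay(path) -> DecayCurve:
    return DecayCurve.from_text(path)


def write_decay_dataset(ds: DecayDataset, prefix) -> None:
    prefix = Path(prefix)
    write_decay(ds.da, prefix.with_name(prefix.name + "_da.txt"))
    write_decay(ds.irf, prefix.with_name(prefix.name + "_irf.txt"))
    if ds.donly is not None:
        write_decay(ds.donly, prefix.with_name(prefix.name + "_donly.txt"))
    prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps({
        "scatter_fraction": ds.scatter_fraction,
        "background": ds.background,
        "shift_channels": ds.shift_channels,
        "fit_range": list(ds.fit_range),
        "meta": ds.meta,
    }))


def read_decay_dataset(prefix) -> DecayDataset:
    prefix = Path(prefix)
    da = read_decay(prefix.with_name(prefix.name + "_da.txt"))
    irf = read_decay(prefix.with_name(prefix.name + "_irf.txt"))
    donly_path = prefix.with_name(prefix.name + "_donly.txt")
    donly = read_decay(donly_path) if donly_path.exists() else None
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    kw = {}
    if meta_path.exists():
        m = json.loads(meta_path.read_text())
        kw = dict(scatter_fraction=m.get("scatter_fraction", 0.0),
                  background=m.get("background", 0.0),
                  shift_channels=m.get("shift_channels", 0.0),
                  fit_range=tuple(m["fit_range"]) if m.get("fit_range") else None,
                  meta=m.get("meta", {}))
    return DecayDataset(da=da, irf=irf, donly=donly, **kw)


DISTANCE_COLUMNS = ["pair_id", "don_res", "acc_res", "state",
                    "R_exp_A", "dR_minus_A", "dR_plus_A"]


def read_distance_set(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DISTANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"distance set lacks columns {sorted(missing)}")
    return df


def write_distance_set(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in DISTANCE_COLUMNS
                                          if c in df.columns])
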