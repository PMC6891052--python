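"""Persistence helpers: HDF5 recordings, TSV event tables, YAML configs."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthmeeg import Recording, SensorArray

__all__ = ["save_recording", "load_recording", "save_ground_truth", "load_config_yaml"]


def save_recording(path, rec: Recording) -> None:
    """Write a recording (data, channel metadata, event table) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data, compression="gzip")
        fh.attrs["sfreq"] = rec.sfreq
        fh.attrs["condition"] = rec.condition
        sens = fh.create_group("sensors")
        sens.create_dataset("ids", data=np.array(rec.sensors.ids, dtype="S"))
        sens.create_dataset("families", data=np.array(rec.sensors.families, dtype="S"))
        sens.create_dataset("positions", data=rec.sensors.positions)
        ev = fh.create_group("events")
        for col in rec.events.columns:
            vals = rec.events[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            ev.create_dataset(col, data=vals)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as fh:
        sensors = SensorArray(
            ids=tuple(s.decode() for s in fh["sensors/ids"][()]),
            families=np.array([s.decode() for s in fh["sensors/families"][()]]),
            positions=fh["sensors/positions"][()],
        )
        cols = {}
        for name, ds in fh["events"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            cols[name] = vals
        return Recording(
            data=fh["data"][()], sfreq=float(fh.attrs["sfreq"]), sensors=sensors,
            events=pd.DataFrame(cols), condition=str(fh.attrs["condition"]),
        )


def save_ground_truth(path, truth) -> None:
    """Save ground-truth parameters as YAML for later recovery tests."""
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(truth)), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config_yaml(path):
    """Build a :class:`~rhythmgain.pipeline.RunConfig` from a YAML file."""
    from .pipeline import RunConfig
    from .synthmeeg import GroundTruth

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    truth = GroundTruth(**raw.pop("truth", {}))
    for key in list(raw):
        val = raw[key]
        if isinstance(val, list):
            raw[key] = tuple(val)
    return RunConfig(truth=truth, **raw)
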