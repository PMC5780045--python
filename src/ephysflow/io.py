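"""HDF5 / TSV / JSON serialization of the pipeline's data containers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import Channel, Recording, SpikeTrain, TimeFreqTensor, \
    validate_event_table

__all__ = [
    "write_recording", "read_recording", "write_events", "read_events",
    "write_tensor", "read_tensor", "write_spikes", "read_spikes",
    "write_json",
]


def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.data.astype(np.float32))
        f["fs"] = rec.fs
        table = np.array([(c.name, c.role, c.group) for c in rec.channels],
                         dtype=h5py.string_dtype())
        f.create_dataset("channel_table", data=table)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["signals"][...].astype(float)
        fs = float(f["fs"][()])
        table = f["channel_table"][...]
        channels = [Channel(*(s.decode() if isinstance(s, bytes) else str(s)
                              for s in row)) for row in table]
    return Recording(data=data, fs=fs, channels=channels)


def write_events(path, events: pd.DataFrame) -> None:
    validate_event_table(events)
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    events["correct"] = events["correct"].astype(bool)
    return validate_event_table(events)


def write_tensor(path, tensor: TimeFreqTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
        f.create_dataset("freqs", data=tensor.freqs)
        f.create_dataset("times", data=tensor.times)
        f["kind"] = tensor.kind
        f["channel"] = tensor.channel
        if tensor.trial_index is not None:
            f.create_dataset("trial_index", data=np.asarray(tensor.trial_index))
        if tensor.analysis_window is not None:
            f["analysis_window"] = list(tensor.analysis_window)


def read_tensor(path) -> TimeFreqTensor:
    with h5py.File(path, "r") as f:
        kwargs = dict(values=f["values"][...], freqs=f["freqs"][...],
                      times=f["times"][...], kind=f["kind"][()].decode(),
                      channel=f["channel"][()].decode())
        if "trial_index" in f:
            kwargs["trial_index"] = f["trial_index"][...]
        if "analysis_window" in f:
            kwargs["analysis_window"] = tuple(f["analysis_window"][...])
    return TimeFreqTensor(**kwargs)


def write_spikes(path, trains: list[SpikeTrain]) -> None:
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.cluster_id, t, tr.depth_pct, tr.paired_macro))
    pd.DataFrame(rows, columns=["cluster_id", "time_ms", "depth_pct",
                                "paired_macro"]).to_csv(path, sep="\t",
                                                        index=False)


def read_spikes(path) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    trains = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        depth = grp["depth_pct"].iloc[0]
        macro = grp["paired_macro"].iloc[0]
        trains.append(SpikeTrain(
            spike_times=np.sort(grp["time_ms"].to_numpy(dtype=float)),
            cluster_id=str(cid),
            depth_pct=None if pd.isna(depth) else float(depth),
            paired_macro=None if pd.isna(macro) else str(macro)))
    return trains


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def write_cluster_result(json_path, result, h5_path=None) -> None:
    """ClusterResult to JSON (extents, stats, corrected p) and, optionally,
    an HDF5 boolean mask aligned to the input grid."""
    write_json(json_path, result.to_dict())
    if h5_path is not None:
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("significant_mask",
                             data=result.significant_mask().astype(np.uint8))
            f.create_dataset("surrogate_max_stats",
                             data=result.surrogate_max_stats)
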