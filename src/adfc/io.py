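"""Readers and writers for the package's on-disk formats.

Spike data travels as CSV (``channel,time_s``, one spike per row) or an
equivalent HDF5 layout (``/spikes/<channel>`` timestamp arrays with
``t_start``/``t_end`` attributes); stimulation schedules as CSV
(``time_s,amplitude,protocol``); metric records as JSON; controller
traces as HDF5 arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .controllers import ControllerTrace
from .types import MetricsTriplet, SpikeTrainSet, StimulationSchedule

__all__ = [
    "read_spikes_csv", "write_spikes_csv",
    "read_spikes_hdf5", "write_spikes_hdf5",
    "read_schedule_csv", "write_schedule_csv",
    "write_metrics_json", "write_trace_hdf5",
]


def read_spikes_csv(path, t_start: float | None = None,
                    t_end: float | None = None) -> SpikeTrainSet:
    """Load a ``channel,time_s`` spike table; validates monotonicity.

    The window defaults to [0, max spike time] unless given explicitly.
    """
    df = pd.read_csv(path)
    if not {"channel", "time_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'channel,time_s'")
    channels = sorted(df["channel"].unique().tolist())
    trains = [np.sort(df.loc[df["channel"] == ch, "time_s"].to_numpy(float))
              for ch in channels]
    if t_start is None:
        t_start = 0.0
    if t_end is None:
        t_end = max((tr[-1] for tr in trains if tr.size), default=1.0)
    return SpikeTrainSet(channels, trains, t_start, t_end)


def write_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    rows = [(ch, t) for ch, tr in zip(spikes.channels, spikes.spikes) for t in tr]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_spikes_hdf5(path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        grp = f["spikes"]
        channels = sorted(grp.keys())
        trains = [np.asarray(grp[ch][()], dtype=float) for ch in channels]
        t_start = float(f.attrs["t_start"])
        t_end = float(f.attrs["t_end"])
    return SpikeTrainSet(channels, trains, t_start, t_end)


def write_spikes_hdf5(spikes: SpikeTrainSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["t_start"] = spikes.t_start
        f.attrs["t_end"] = spikes.t_end
        grp = f.create_group("spikes")
        for ch, tr in zip(spikes.channels, spikes.spikes):
            grp.create_dataset(str(ch), data=tr)


def read_schedule_csv(path) -> StimulationSchedule:
    df = pd.read_csv(path)
    protocol = str(df["protocol"].iloc[0]) if len(df) else "DFC"
    return StimulationSchedule(df["time_s"].to_numpy(float),
                               df["amplitude"].to_numpy(float) if len(df) else 1.0,
                               protocol=protocol)


def write_schedule_csv(schedule: StimulationSchedule, path) -> None:
    pd.DataFrame({
        "time_s": schedule.times,
        "amplitude": schedule.amplitude,
        "protocol": schedule.protocol,
    }).to_csv(path, index=False)


def write_metrics_json(triplet: MetricsTriplet, path, parameters: dict | None = None) -> None:
    record = triplet.as_dict()
    record["parameters"] = parameters or {}
    Path(path).write_text(json.dumps(record, indent=2, default=float) + "\n")


def write_trace_hdf5(trace: ControllerTrace, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("t", "xdot", "xdot_delayed", "sf", "T_history",
                     "omega_history", "burst_times"):
            f.create_dataset(name, data=getattr(trace, name))
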