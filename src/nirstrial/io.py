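"""Plain-text (CSV) and HDF5 readers/writers for the pipeline's data types.

CSV schema
----------
Raw recording (wide): ``time_s, ch{i}_wl{lambda}_intensity ..., ambient``
plus a side-car events file ``onset_s, duration_s, condition``.
Concentration series: ``time_s, ch{i}_o2hb, ch{i}_hhb``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preproc import HemoSeries, RawRecording
from .synthgen import EventTable

_FLOAT_FMT = "%.17g"    # exact float round-trip through text


def write_events_csv(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path, total_duration: float | None = None) -> EventTable:
    return EventTable.from_frame(pd.read_csv(path), total_duration)


def write_raw_csv(raw: RawRecording, data_path, events_path=None) -> None:
    cols = {"time_s": raw.time}
    for ch in range(raw.n_channels):
        for wi, wl in enumerate(raw.wavelengths):
            cols[f"ch{ch + 1}_wl{int(round(wl))}_intensity"] = raw.intensity[ch, wi]
    cols["ambient"] = raw.ambient
    pd.DataFrame(cols).to_csv(data_path, index=False, float_format=_FLOAT_FMT)
    if events_path is not None and raw.events is not None:
        write_events_csv(raw.events, events_path)


def read_raw_csv(data_path, events_path=None, distance_mm: float = 12.5) -> RawRecording:
    df = pd.read_csv(data_path, float_precision="round_trip")
    time = df["time_s"].to_numpy()
    if len(time) < 2:
        raise ValueError("recording too short")
    dt = np.diff(time)
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValueError("non-uniform sampling in raw CSV")
    fs = 1.0 / dt[0]
    chan_wl = {}
    for col in df.columns:
        if col.endswith("_intensity"):
            ch_part, wl_part = col[: -len("_intensity")].split("_wl")
            chan_wl.setdefault(int(ch_part[2:]), {})[float(wl_part)] = df[col].to_numpy()
    channels = sorted(chan_wl)
    wavelengths = tuple(sorted(chan_wl[channels[0]]))
    intensity = np.stack([
        np.stack([chan_wl[ch][wl] for wl in wavelengths]) for ch in channels])
    events = None
    if events_path is not None and Path(events_path).exists():
        events = read_events_csv(events_path, total_duration=len(time) / fs)
    return RawRecording(sampling_rate=float(round(fs, 9)), intensity=intensity,
                        ambient=df["ambient"].to_numpy(), events=events,
                        wavelengths=wavelengths, distance_mm=distance_mm)


def write_hemo_csv(hemo: HemoSeries, path) -> None:
    cols = {"time_s": hemo.time}
    for ch in range(hemo.n_channels):
        cols[f"ch{ch + 1}_o2hb"] = hemo.o2hb[ch]
        cols[f"ch{ch + 1}_hhb"] = hemo.hhb[ch]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_hemo_csv(path, events: EventTable | None = None) -> HemoSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    time = df["time_s"].to_numpy()
    fs = 1.0 / (time[1] - time[0])
    n_ch = sum(1 for c in df.columns if c.endswith("_o2hb"))
    o2hb = np.stack([df[f"ch{ch}_o2hb"].to_numpy() for ch in range(1, n_ch + 1)])
    hhb = np.stack([df[f"ch{ch}_hhb"].to_numpy() for ch in range(1, n_ch + 1)])
    return HemoSeries(float(round(fs, 9)), o2hb, hhb, events)


# ---------------------------------------------------------------------------
# optional single-file HDF5 container (same schema)
# ---------------------------------------------------------------------------

def write_raw_hdf5(raw: RawRecording, path) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=raw.intensity)
        f.create_dataset("ambient", data=raw.ambient)
        f.attrs["sampling_rate"] = raw.sampling_rate
        f.attrs["wavelengths"] = list(raw.wavelengths)
        f.attrs["distance_mm"] = raw.distance_mm
        f.attrs["log"] = json.dumps(raw.log)
        if raw.events is not None:
            g = f.create_group("events")
            g.create_dataset("onset_s", data=raw.events.onsets)
            g.create_dataset("duration_s", data=raw.events.durations)
            g.create_dataset("condition",
                             data=np.array([str(c) for c in raw.events.conditions],
                                           dtype=h5py.string_dtype()))
            g.attrs["total_duration"] = raw.events.total_duration


def read_raw_hdf5(path) -> RawRecording:
    import h5py
    with h5py.File(path, "r") as f:
        events = None
        if "events" in f:
            g = f["events"]
            events = EventTable(g["onset_s"][:], g["duration_s"][:],
                                np.array([c.decode() if isinstance(c, bytes) else c
                                          for c in g["condition"][:]], dtype=object),
                                float(g.attrs["total_duration"]))
        return RawRecording(
            sampling_rate=float(f.attrs["sampling_rate"]),
            intensity=f["intensity"][:], ambient=f["ambient"][:],
            events=events, wavelengths=tuple(f.attrs["wavelengths"]),
            distance_mm=float(f.attrs["distance_mm"]),
            log=json.loads(f.attrs["log"]))


def write_hemo_hdf5(hemo: HemoSeries, path) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("o2hb", data=hemo.o2hb)
        f.create_dataset("hhb", data=hemo.hhb)
        f.attrs["sampling_rate"] = hemo.sampling_rate
        f.attrs["log"] = json.dumps(hemo.log, default=str)


def read_hemo_hdf5(path, events: EventTable | None = None) -> HemoSeries:
    import h5py
    with h5py.File(path, "r") as f:
        return HemoSeries(float(f.attrs["sampling_rate"]), f["o2hb"][:],
                          f["hhb"][:], events, json.loads(f.attrs["log"]))
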