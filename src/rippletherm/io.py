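"""Session container and event-table I/O.

Native container is HDF5 with groups ``/lfp/<name>``, ``/emg/<name>``,
``/temperature`` and an ``/annotations`` group; sampling rates and units are
stored as dataset attributes. A CSV fallback (one file per channel plus a
JSON manifest) supports dependency-free fixtures, and EDF files can be read
for ingest (never written).
"""

from __future__ import annotations

import json
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import List, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .core import EpilepticEvent, Recording, RippleEvent, TimeSeries

__all__ = [
    "write_session",
    "read_session",
    "write_session_csv",
    "read_session_csv",
    "read_edf",
    "write_events",
    "read_events",
]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _write_series(group: h5py.Group, name: str, ts: TimeSeries) -> None:
    d = group.create_dataset(name, data=ts.values)
    d.attrs["sampling_rate"] = ts.sampling_rate
    d.attrs["start_time"] = ts.start_time
    d.attrs["units"] = ts.units
    d.attrs["label"] = ts.label


def _read_series(dset: h5py.Dataset) -> TimeSeries:
    return TimeSeries(
        dset[...],
        sampling_rate=float(dset.attrs["sampling_rate"]),
        start_time=float(dset.attrs.get("start_time", 0.0)),
        units=str(dset.attrs.get("units", "")),
        label=str(dset.attrs.get("label", "")),
    )


def write_session(recording: Recording, path: Union[str, Path]) -> None:
    """Write a :class:`Recording` to the native HDF5 layout."""
    with h5py.File(path, "w") as f:
        lfp = f.create_group("lfp")
        for i, ch in enumerate(recording.lfp_channels):
            _write_series(lfp, f"ch{i}", ch)
        emg = f.create_group("emg")
        for i, ch in enumerate(recording.emg_channels):
            _write_series(emg, f"ch{i}", ch)
        _write_series(f, "temperature", recording.temperature)
        ann = f.create_group("annotations")
        for key, value in recording.annotations.items():
            ann.attrs[key] = value
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["genotype"] = recording.genotype


def _read_hdf5(path: Union[str, Path]) -> Recording:
    with h5py.File(path, "r") as f:
        if "temperature" not in f:
            raise ValueError("temperature required: container has no /temperature")
        lfp = [_read_series(f["lfp"][k]) for k in sorted(f["lfp"])] if "lfp" in f else []
        emg = [_read_series(f["emg"][k]) for k in sorted(f["emg"])] if "emg" in f else []
        temp = _read_series(f["temperature"])
        ann = {}
        if "annotations" in f:
            ann = {k: float(v) for k, v in f["annotations"].attrs.items()}
        return Recording(
            lfp_channels=lfp,
            emg_channels=emg,
            temperature=temp,
            annotations=ann,
            subject_id=str(f.attrs.get("subject_id", "")),
            genotype=str(f.attrs.get("genotype", "WT")),
        )


# ---------------------------------------------------------------------------
# CSV fallback: one file per channel + manifest.json
# ---------------------------------------------------------------------------

def write_session_csv(recording: Recording, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": recording.subject_id,
        "genotype": recording.genotype,
        "annotations": recording.annotations,
        "lfp": [],
        "emg": [],
    }
    for kind, channels in (("lfp", recording.lfp_channels),
                           ("emg", recording.emg_channels)):
        for i, ch in enumerate(channels):
            fname = f"{kind}_ch{i}.csv"
            np.savetxt(directory / fname, ch.values, fmt="%.9g")
            manifest[kind].append({
                "file": fname,
                "sampling_rate": ch.sampling_rate,
                "start_time": ch.start_time,
                "units": ch.units,
                "label": ch.label,
            })
    # temperature as two columns: time (s), degC
    t = recording.temperature
    np.savetxt(directory / "temperature.csv",
               np.column_stack([t.times(), t.values]),
               fmt="%.9g", delimiter=",", header="time_s,temperature_c")
    manifest["temperature"] = {
        "file": "temperature.csv",
        "sampling_rate": t.sampling_rate,
        "start_time": t.start_time,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_session_csv(directory: Union[str, Path]) -> Recording:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    if "temperature" not in manifest:
        raise ValueError("temperature required: manifest lists no temperature file")

    def load(entry, units="uV"):
        values = np.loadtxt(directory / entry["file"])
        return TimeSeries(values, entry["sampling_rate"],
                          start_time=entry.get("start_time", 0.0),
                          units=entry.get("units", units),
                          label=entry.get("label", ""))

    lfp = [load(e) for e in manifest.get("lfp", [])]
    emg = [load(e) for e in manifest.get("emg", [])]
    tdata = np.loadtxt(directory / manifest["temperature"]["file"], delimiter=",")
    temp = TimeSeries(tdata[:, 1], manifest["temperature"]["sampling_rate"],
                      start_time=manifest["temperature"].get("start_time", 0.0),
                      units="degC", label="temperature")
    return Recording(lfp_channels=lfp, emg_channels=emg, temperature=temp,
                     annotations=manifest.get("annotations", {}),
                     subject_id=manifest.get("subject_id", ""),
                     genotype=manifest.get("genotype", "WT"))


# ---------------------------------------------------------------------------
# EDF ingest (read-only)
# ---------------------------------------------------------------------------

def read_edf(path: Union[str, Path], temperature: TimeSeries,
             emg_prefixes: Sequence[str] = ("EMG", "emg"),
             subject_id: str = "", genotype: str = "WT") -> Recording:
    """Read an EDF file into a :class:`Recording`.

    EDF carries no core-temperature trace, so the caller must supply one.
    Channels whose labels start with one of ``emg_prefixes`` become EMG
    channels; all others are treated as LFP.
    """
    if temperature is None:
        raise ValueError("temperature required: EDF files carry no temperature trace")
    import mne  # lazy: only needed for EDF ingest

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # MNE returns volts; sessions are in uV
    lfp, emg = [], []
    for name, row in zip(raw.ch_names, data):
        ts = TimeSeries(row, fs, units="uV", label=name)
        if any(name.startswith(p) for p in emg_prefixes):
            emg.append(ts)
        else:
            lfp.append(ts)
    return Recording(lfp_channels=lfp, emg_channels=emg, temperature=temperature,
                     subject_id=subject_id, genotype=genotype)


def read_session(path: Union[str, Path], temperature: TimeSeries = None) -> Recording:
    """Read a session container, dispatching on layout.

    ``.h5``/``.hdf5`` files use the native layout; a directory containing
    ``manifest.json`` uses the CSV fallback; ``.edf`` files are ingested
    (and require a ``temperature`` series).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return read_session_csv(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if suffix == ".edf":
        return read_edf(path, temperature)
    raise ValueError(f"unrecognised session container: {path}")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_LIST_FIELDS = ("trough_times", "peak_times")


def _event_to_row(ev) -> dict:
    row = {}
    for f in dataclass_fields(ev):
        v = getattr(ev, f.name)
        if f.name in _LIST_FIELDS:
            v = ";".join(f"{x:.9f}" for x in np.atleast_1d(v))
        row[f.name] = v
    return row


def write_events(events: List, path: Union[str, Path]) -> None:
    """Write a homogeneous event list to CSV, one row per event.

    Times are written with nanosecond precision (well beyond the documented
    1 ms requirement). An empty list yields a header-only ripple table.
    """
    if events:
        kinds = {type(e) for e in events}
        if len(kinds) > 1:
            raise ValueError(f"mixed event types: {sorted(k.__name__ for k in kinds)}")
        kind = kinds.pop()
        if kind not in (RippleEvent, EpilepticEvent):
            raise ValueError(f"unsupported event type {kind.__name__}")
        rows = [_event_to_row(e) for e in events]
        df = pd.DataFrame(rows)
    else:
        kind = RippleEvent
        df = pd.DataFrame(columns=[f.name for f in dataclass_fields(RippleEvent)])
    df.to_csv(path, index=False, float_format="%.9f")


def read_events(path: Union[str, Path], kind: str = "ripple") -> List:
    """Read an event table written by :func:`write_events`.

    ``kind`` is ``"ripple"`` or ``"epileptic"``.
    """
    df = pd.read_csv(path)
    out = []
    if kind == "ripple":
        for _, row in df.iterrows():
            out.append(RippleEvent(
                start=float(row["start"]),
                end=float(row["end"]),
                trough_times=_parse_list(row["trough_times"]),
                peak_times=_parse_list(row["peak_times"]),
                frequency=float(row["frequency"]),
                ripple_power_avg=float(row["ripple_power_avg"]),
                ripple_power_max=float(row["ripple_power_max"]),
                spw_power_avg=float(row["spw_power_avg"]),
                spw_power_max=float(row["spw_power_max"]),
                temperature=float(row["temperature"]),
                burst_id=None if pd.isna(row["burst_id"]) else int(row["burst_id"]),
            ))
    elif kind == "epileptic":
        for _, row in df.iterrows():
            out.append(EpilepticEvent(
                trough_time=float(row["trough_time"]),
                event_class=str(row["event_class"]),
                amplitude=float(row["amplitude"]),
                emg_power_pre=_opt_float(row["emg_power_pre"]),
                emg_power_post=_opt_float(row["emg_power_post"]),
                emg_ratio=_opt_float(row["emg_ratio"]),
                temperature=float(row["temperature"]),
            ))
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return out


def _parse_list(s) -> np.ndarray:
    if pd.isna(s) or s == "":
        return np.array([])
    return np.array([float(x) for x in str(s).split(";")])


def _opt_float(v):
    return None if pd.isna(v) else float(v)
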