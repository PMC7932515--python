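"""Readers and writers for spike trains, waveforms and frequency trajectories.

Spike CSV dialect: header ``trial_id,polarity,spike_time_s``, one row per
spike. JSON dialect mirrors :class:`~appsth.types.SpikeTrainSet`:
``{"duration_s": ..., "trains": [{"polarity": 1, "times_s": [...]}, ...]}``.
Waveforms are WAV (PCM16 or float32) or two-column CSV ``time_s,value``.
Trajectory files are two-column CSV ``time_s,freq_hz``.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import FrequencyTrajectory, SpikeTrainSet, TimeSeries, ValidationError

__all__ = [
    "load_spike_trains",
    "save_spike_trains",
    "read_waveform",
    "write_waveform",
    "read_trajectory",
    "write_trajectory",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file."""


def _infer_duration(trains, bin_width: float = 1e-3) -> float:
    """Max spike time rounded up to a whole number of bins (>= one bin)."""
    tmax = max((t[-1] for t in trains if len(t)), default=0.0)
    return max(1, math.ceil((tmax + 1e-12) / bin_width)) * bin_width


def load_spike_trains(path: PathLike, dialect: str = None) -> SpikeTrainSet:
    """Load a :class:`SpikeTrainSet` from CSV or JSON.

    ``dialect`` is inferred from the file suffix when omitted. Unsorted
    spike times are sorted; a file with only a header yields an empty set
    (with a warning). Negative times or times beyond a declared duration
    raise :class:`~appsth.types.ValidationError`.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        with open(path) as fh:
            obj = json.load(fh)
        trains = [np.asarray(tr["times_s"], float) for tr in obj["trains"]]
        pols = [int(tr["polarity"]) for tr in obj["trains"]]
        duration = float(obj.get("duration_s") or _infer_duration(trains))
        meta = obj.get("meta", {})
        if not trains:
            warnings.warn(f"{path}: no spike trains found")
            trains, pols = [], []
        return SpikeTrainSet(trains, pols, duration,
                             cf=meta.get("cf_hz"), spont_rate=meta.get("spont_rate"))
    if dialect != "csv":
        raise ParseError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise ParseError(f"{path}: {exc}") from exc
    required = {"trial_id", "polarity", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: CSV must have columns {sorted(required)}")
    bad = df[~df["polarity"].isin((1, -1))]
    if len(bad):
        raise ParseError(f"{path}: invalid polarity at data row {bad.index[0] + 1}")
    # optional duration declared as a comment line '# duration_s = X'
    duration = _read_declared_duration(path)
    trains, pols = [], []
    for (trial, pol), grp in df.groupby(["trial_id", "polarity"], sort=True):
        trains.append(np.sort(grp["spike_time_s"].to_numpy(float)))
        pols.append(int(pol))
    if not trains:
        warnings.warn(f"{path}: no spike trains found")
    if duration is None:
        duration = _infer_duration(trains)
    return SpikeTrainSet(trains, pols, duration)


def _read_declared_duration(path: Path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            if "duration_s" in line and "=" in line:
                return float(line.split("=", 1)[1])
    return None


def save_spike_trains(spikes: SpikeTrainSet, path: PathLike) -> None:
    """Write a SpikeTrainSet as CSV (.csv) or JSON (.json); round-trip safe."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "duration_s": spikes.duration,
            "meta": {"cf_hz": spikes.cf, "spont_rate": spikes.spont_rate},
            "trains": [
                {"polarity": int(p), "times_s": t.tolist()}
                for p, t in zip(spikes.polarities, spikes.trains)
            ],
        }
        path.write_text(json.dumps(obj))
        return
    rows = [f"# duration_s = {float(spikes.duration)!r}",
            "trial_id,polarity,spike_time_s"]
    for i, (p, t) in enumerate(zip(spikes.polarities, spikes.trains)):
        rows.extend(f"{i},{int(p)},{float(tk)!r}" for tk in t)
    path.write_text("\n".join(rows) + "\n")


def read_waveform(path: PathLike) -> TimeSeries:
    """Read a WAV (PCM16/float) or two-column CSV (time_s, value) waveform."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if data.dtype.kind == "i":
            data = data / float(np.iinfo(data.dtype).max)
        return TimeSeries(data.astype(float), float(fs))
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValidationError(f"{path}: time column is not uniformly sampled")
    return TimeSeries(df.iloc[:, 1].to_numpy(float), 1.0 / dt[0], t0=float(t[0]))


def write_waveform(ts: TimeSeries, path: PathLike) -> None:
    """Write a TimeSeries as float32 WAV (.wav) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(ts.fs)), ts.values.astype(np.float32))
        return
    pd.DataFrame({"time_s": ts.times, "value": ts.values}).to_csv(path, index=False)


def read_trajectory(path: PathLike, fs: float = None) -> FrequencyTrajectory:
    """Read a two-column (time_s, freq_hz) trajectory.

    When ``fs`` is given the contour is linearly resampled onto the signal's
    uniform grid starting at the first tabulated time.
    """
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    f = df.iloc[:, 1].to_numpy(float)
    if fs is None:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValidationError(f"{path}: non-uniform trajectory requires fs")
        return FrequencyTrajectory(f, 1.0 / dt[0])
    grid = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    return FrequencyTrajectory(np.interp(grid, t, f), fs)


def write_trajectory(traj: FrequencyTrajectory, path: PathLike) -> None:
    t = np.arange(traj.n) / traj.fs
    pd.DataFrame({"time_s": t, "freq_hz": traj.values}).to_csv(path, index=False)
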