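"""Trace-file I/O and the episode recording container.

Traces are stored as plain delimited text: column 1 is time in seconds,
subsequent columns are named voltage channels (header row carries the
names).  Event data (spike times, nerve impulse times, condition tags)
travel in a JSON sidecar next to the trace file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpisodeRecording",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
]


@dataclass
class EpisodeRecording:
    """Multi-channel traces plus event times for one swim episode.

    Attributes
    ----------
    dt_ms : float
        Sampling interval in milliseconds.
    channels : dict[str, np.ndarray]
        Named voltage traces (mV), e.g. ``"C2"``, ``"VSI_soma"``,
        ``"PdN6"`` (extracellular, arbitrary units).
    spike_times : dict[str, np.ndarray]
        Per-unit somatic spike times in seconds.
    nerve_impulse_times : np.ndarray
        Times (s) of axonal impulses crossing the commissure electrode.
    stim_window : tuple[float, float]
        Start and end (s) of the initiating nerve stimulation.
    condition : dict
        Tags: ``pdn6_intact``, ``hi_di``, ``clamp_mode``, animal id, seed.
    """

    dt_ms: float
    channels: dict = field(default_factory=dict)
    spike_times: dict = field(default_factory=dict)
    nerve_impulse_times: np.ndarray = field(default_factory=lambda: np.array([]))
    stim_window: tuple = (0.0, 0.0)
    condition: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        n = max((len(v) for v in self.channels.values()), default=0)
        return n * self.dt_ms / 1000.0

    @property
    def time_s(self) -> np.ndarray:
        n = max((len(v) for v in self.channels.values()), default=0)
        return np.arange(n) * self.dt_ms / 1000.0

    # -- persistence ----------------------------------------------------

    def save(self, trace_path: str | Path) -> None:
        """Write the trace file and a ``.events.json`` sidecar."""
        trace_path = Path(trace_path)
        write_trace(trace_path, self.time_s, self.channels)
        sidecar = trace_path.with_suffix(trace_path.suffix + ".events.json")
        write_events(
            sidecar,
            {
                "dt_ms": self.dt_ms,
                "spike_times": {k: list(map(float, v)) for k, v in self.spike_times.items()},
                "nerve_impulse_times": list(map(float, self.nerve_impulse_times)),
                "stim_window": list(self.stim_window),
                "condition": self.condition,
            },
        )

    @classmethod
    def load(cls, trace_path: str | Path) -> "EpisodeRecording":
        trace_path = Path(trace_path)
        t, channels = read_trace(trace_path)
        sidecar = trace_path.with_suffix(trace_path.suffix + ".events.json")
        meta = read_events(sidecar)
        return cls(
            dt_ms=float(meta["dt_ms"]),
            channels=channels,
            spike_times={k: np.asarray(v, float) for k, v in meta["spike_times"].items()},
            nerve_impulse_times=np.asarray(meta["nerve_impulse_times"], float),
            stim_window=tuple(meta["stim_window"]),
            condition=meta["condition"],
        )


def write_trace(path: str | Path, time_s: np.ndarray, channels: dict) -> None:
    df = pd.DataFrame({"time_s": np.asarray(time_s, float)})
    for name, v in channels.items():
        df[name] = np.asarray(v, float)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trace(path: str | Path):
    """Read a delimited-text trace file -> (time_s, {channel: array})."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"trace file {path} lacks a 'time_s' column")
    t = df["time_s"].to_numpy(float)
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "time_s"}
    return t, channels


def write_events(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_events(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
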