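"""Core in-memory containers for motion and envelope time series.

Axis convention (fixed throughout the package): ``x`` is horizontal
(left-right), ``y`` is vertical (up is positive, so downward motion has
negative y-velocity), ``z`` is depth (toward/away from the viewer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AXES = ("x", "y", "z")


@dataclass
class MotionRecording:
    """Raw (or segment-reduced) marker positions over time.

    Parameters
    ----------
    positions : ndarray, shape (n_frames, n_markers, 3)
        Marker positions per frame; units arbitrary but consistent.
    frame_rate_hz : float
        Capture rate in frames per second.
    marker_labels : list of str
        One name per marker.
    """

    positions: np.ndarray
    frame_rate_hz: float
    marker_labels: list[str]
    axis_labels: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if len(self.marker_labels) != self.positions.shape[1]:
            raise ValueError("marker_labels length must match marker count")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values; "
                             "interpolate gaps before constructing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time plus one column per ``<MARKER>_<axis>``."""
        cols = {"time": np.arange(self.n_frames) / self.frame_rate_hz}
        for m, label in enumerate(self.marker_labels):
            for a, ax in enumerate(self.axis_labels):
                cols[f"{label}_{ax}"] = self.positions[:, m, a]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {"frame_rate_hz": self.frame_rate_hz,
                   "marker_labels": self.marker_labels,
                   "axis_labels": list(self.axis_labels)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path,
                 frame_rate_hz: float | None = None) -> "MotionRecording":
        """Read a wide marker table (``NAME_x, NAME_y, NAME_z`` columns).

        The frame rate is taken from the JSON sidecar if present, else from
        the ``time`` column spacing, else from ``frame_rate_hz``.
        """
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            frame_rate_hz = meta["frame_rate_hz"]
        elif "time" in df.columns and len(df) > 1:
            frame_rate_hz = 1.0 / float(np.median(np.diff(df["time"])))
        if frame_rate_hz is None:
            raise ValueError("frame rate not recoverable; pass frame_rate_hz")
        markers: list[str] = []
        for c in df.columns:
            if c.endswith("_x"):
                markers.append(c[:-2])
        arr = np.empty((len(df), len(markers), 3))
        for m, label in enumerate(markers):
            for a, ax in enumerate(AXES):
                arr[:, m, a] = df[f"{label}_{ax}"].to_numpy()
        arr = _interpolate_gaps(arr)
        return cls(arr, float(frame_rate_hz), markers)


def _interpolate_gaps(arr: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly interpolate NaN gaps of at most ``max_gap`` frames.

    Longer gaps are rejected: downstream derivative estimates would be
    dominated by the imputation.
    """
    if not np.isnan(arr).any():
        return arr
    out = arr.copy()
    n = arr.shape[0]
    t = np.arange(n)
    for m in range(arr.shape[1]):
        for a in range(arr.shape[2]):
            col = out[:, m, a]
            bad = np.isnan(col)
            if not bad.any():
                continue
            # longest run of consecutive NaNs
            longest = 0
            run = 0
            for b in bad:
                run = run + 1 if b else 0
                longest = max(longest, run)
            if longest > max_gap or bad[0] or bad[-1]:
                raise ValueError(
                    f"gap of {longest} frames (> {max_gap}) or edge gap in "
                    "marker data; file rejected")
            col[bad] = np.interp(t[bad], t[~bad], col[~bad])
    return out


@dataclass
class KinematicSeries:
    """Multichannel kinematic feature series (decoder input).

    ``values`` is (n_samples, n_channels); ``channel_meta`` pairs each
    channel with its (segment, axis). ``encoding`` is one of ``velocity``,
    ``speed`` or ``acceleration``.
    """

    values: np.ndarray
    channel_meta: list[tuple[str, str]]
    rate_hz: float
    derivative_order: int
    encoding: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples, channels)")
        if len(self.channel_meta) != self.values.shape[1]:
            raise ValueError("channel_meta length must match channel count")
        if self.encoding not in ("velocity", "speed", "acceleration"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "speed" and (self.values < 0).any():
            raise ValueError("speed encoding requires nonnegative values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray | None = None, **kw) -> "KinematicSeries":
        d = dict(values=self.values if values is None else values,
                 channel_meta=list(self.channel_meta), rate_hz=self.rate_hz,
                 derivative_order=self.derivative_order, encoding=self.encoding)
        d.update(kw)
        return KinematicSeries(**d)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = {"time": np.arange(self.n_samples) / self.rate_hz}
        for c, (seg, ax) in enumerate(self.channel_meta):
            cols[f"{seg}_{ax}"] = self.values[:, c]
        pd.DataFrame(cols).to_csv(path, index=False)
        meta = {"rate_hz": self.rate_hz, "derivative_order": self.derivative_order,
                "encoding": self.encoding,
                "channel_meta": [list(t) for t in self.channel_meta]}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "KinematicSeries":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        channel_meta = [tuple(t) for t in meta["channel_meta"]]
        values = np.column_stack([df[f"{seg}_{ax}"].to_numpy()
                                  for seg, ax in channel_meta])
        return cls(values, channel_meta, meta["rate_hz"],
                   meta["derivative_order"], meta["encoding"])


@dataclass
class EnvelopeSeries:
    """Amplitude envelope: a 1-D series at ``rate_hz``.

    Envelopes measured from audio are nonnegative by construction; decoder
    *predictions* are unconstrained linear readouts and may go negative, so
    the container itself does not enforce a sign.
    """

    values: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        t = np.arange(self.n_samples) / self.rate_hz
        pd.DataFrame({"time": t, "amplitude": self.values}).to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"rate_hz": self.rate_hz}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnvelopeSeries":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            rate = json.loads(sidecar.read_text())["rate_hz"]
        else:
            rate = 1.0 / float(np.median(np.diff(df["time"])))
        return cls(df["amplitude"].to_numpy(), float(rate))
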