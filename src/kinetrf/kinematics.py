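"""Kinematic feature extraction from marker position data.

The pipeline mirrors standard motion-capture preprocessing for decoding
analyses: dense markers are pooled into a ~20-segment body model by
averaging, derivatives (velocity or acceleration) are taken at the raw
frame rate, and the result is anti-alias resampled to the 30 Hz analysis
rate. Encodings: ``velocity`` keeps the signed per-axis derivative,
``speed`` takes its absolute value per axis (direction destroyed);
``acceleration`` is the second derivative, always signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly

from .containers import AXES, KinematicSeries, MotionRecording

ANALYSIS_RATE_HZ = 30.0

#: Default 20-segment body model: segment -> substring patterns of source
#: marker names. Used when reducing a dense marker set; for data that is
#: already segment-level an identity map is built instead.
DEFAULT_SEGMENTS: tuple[str, ...] = (
    "head", "neck", "l_shoulder", "r_shoulder", "upper_trunk", "lower_trunk",
    "pelvis", "root",
    "l_upper_arm", "l_forearm", "l_hand",
    "r_upper_arm", "r_forearm", "r_hand",
    "l_thigh", "l_shank", "l_foot",
    "r_thigh", "r_shank", "r_foot",
)

#: Arm segments: the primary gesturing effectors in the body model.
ARM_SEGMENTS: tuple[str, ...] = (
    "l_upper_arm", "l_forearm", "l_hand",
    "r_upper_arm", "r_forearm", "r_hand",
)


@dataclass
class SegmentMap:
    """Mapping from body segments to the marker names averaged into them."""

    mapping: dict[str, list[str]]

    def __post_init__(self) -> None:
        for seg, markers in self.mapping.items():
            if not markers:
                raise ValueError(f"segment {seg!r} has no source markers")

    @property
    def segments(self) -> list[str]:
        return list(self.mapping)

    @classmethod
    def identity(cls, labels: list[str]) -> "SegmentMap":
        return cls({lab: [lab] for lab in labels})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentMap":
        data = yaml.safe_load(Path(path).read_text())
        return cls({str(k): [str(m) for m in v] for k, v in data.items()})

    @classmethod
    def default(cls) -> "SegmentMap":
        """The shipped 20-segment mapping (editable YAML in package data)."""
        return cls.from_yaml(Path(__file__).parent / "data"
                             / "segment_map_default.yaml")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.mapping, sort_keys=False))


def reduce_to_segments(rec: MotionRecording, seg_map: SegmentMap) -> MotionRecording:
    """Pool markers into body segments by per-frame, per-axis averaging."""
    index = {lab: i for i, lab in enumerate(rec.marker_labels)}
    out = np.empty((rec.n_frames, len(seg_map.mapping), 3))
    for s, (seg, markers) in enumerate(seg_map.mapping.items()):
        try:
            cols = [index[m] for m in markers]
        except KeyError as e:
            raise KeyError(f"segment {seg!r} references unknown marker {e}") from e
        out[:, s, :] = rec.positions[:, cols, :].mean(axis=1)
    return MotionRecording(out, rec.frame_rate_hz, seg_map.segments,
                           rec.axis_labels)


def differentiate(rec: MotionRecording, order: int = 1) -> KinematicSeries:
    """Finite-difference derivative of position, in units/s (or units/s²).

    Central differences in the interior with one-sided endpoints keep the
    output length and phase aligned with the input. ``order=2`` is the
    derivative applied twice.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if rec.n_frames < order + 1:
        raise ValueError(f"need at least {order + 1} frames for order {order}")
    dt = 1.0 / rec.frame_rate_hz
    deriv = rec.positions
    for _ in range(order):
        deriv = np.gradient(deriv, dt, axis=0)
    n_frames, n_markers, _ = deriv.shape
    values = deriv.reshape(n_frames, n_markers * 3)
    meta = [(seg, ax) for seg in rec.marker_labels for ax in rec.axis_labels]
    encoding = "velocity" if order == 1 else "acceleration"
    return KinematicSeries(values, meta, rec.frame_rate_hz, order, encoding)


def _resample_values(values: np.ndarray, rate: float, target: float) -> np.ndarray:
    frac = Fraction(target / rate).limit_denominator(1000)
    return resample_poly(values, frac.numerator, frac.denominator, axis=0,
                         padtype="line")


def resample(series: KinematicSeries, target_hz: float = ANALYSIS_RATE_HZ) -> KinematicSeries:
    """Anti-alias filter and resample to ``target_hz`` (downsampling only)."""
    if target_hz > series.rate_hz:
        raise ValueError("upsampling is not supported")
    if target_hz == series.rate_hz:
        return series.copy_with()
    values = _resample_values(series.values, series.rate_hz, target_hz)
    if series.encoding == "speed":
        values = np.maximum(values, 0.0)  # filter ringing can dip below zero
    return series.copy_with(values=values, rate_hz=float(target_hz))


def encode(series: KinematicSeries, encoding: str) -> KinematicSeries:
    """Choose the movement encoding: signed ``velocity`` or scalar ``speed``.

    Both encodings carry the same per-axis magnitude; only velocity retains
    direction (left/right on x, up/down on y). Speed is the per-channel
    absolute value of the per-axis derivative, keeping the encoding
    axis-specific (a 3-D Euclidean norm would not be).
    """
    if series.derivative_order != 1:
        raise ValueError("encode applies to first-derivative series only")
    if encoding == "velocity":
        return series.copy_with(encoding="velocity")
    if encoding == "speed":
        return series.copy_with(values=np.abs(series.values), encoding="speed")
    raise ValueError(f"unknown encoding {encoding!r}")


def select_axis(series: KinematicSeries, axis: str) -> KinematicSeries:
    """Keep only the channels of one spatial axis (x, y or z)."""
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}")
    idx = [c for c, (_, ax) in enumerate(series.channel_meta) if ax == axis]
    if not idx:
        raise ValueError(f"series has no channels on axis {axis!r}")
    return series.copy_with(values=series.values[:, idx],
                            channel_meta=[series.channel_meta[c] for c in idx])


def invert_axis(series: KinematicSeries, axis: str) -> KinematicSeries:
    """Mirror the body along one axis by negating that axis's channels.

    Vertical (y) inversion turns gravity-compatible downward strokes into
    upward ones; horizontal (x) inversion is the gravity-neutral control.
    Only signed encodings can be inverted.
    """
    if series.encoding == "speed":
        raise ValueError("cannot invert a speed encoding: direction already "
                         "destroyed")
    if axis not in ("x", "y"):
        raise ValueError("inversion is defined for the x or y axis")
    values = series.values.copy()
    for c, (_, ax) in enumerate(series.channel_meta):
        if ax == axis:
            values[:, c] *= -1.0
    return series.copy_with(values=values)


def variance_summary(series: KinematicSeries) -> pd.DataFrame:
    """Temporal variance per channel, tidy by segment and axis."""
    var = series.values.var(axis=0)
    rows = [{"segment": seg, "axis": ax, "variance": v}
            for (seg, ax), v in zip(series.channel_meta, var)]
    return pd.DataFrame(rows)
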