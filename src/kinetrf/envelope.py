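"""Speech amplitude envelope extraction and alignment.

The envelope is the slow (< 10 Hz) intensity contour of the waveform that
carries prosodic, suprasegmental structure: Hilbert analytic-signal
magnitude followed by a zero-phase 4th-order Butterworth low-pass at
10 Hz, then anti-alias resampling to the 30 Hz analysis rate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import EnvelopeSeries, KinematicSeries
from .kinematics import ANALYSIS_RATE_HZ, _resample_values

LOWPASS_HZ = 10.0
FILTER_ORDER = 4


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as float64 in [-1, 1]; mono required."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("stereo audio: mix down to mono before envelope "
                         "extraction")
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        data = (data.astype(float) - np.iinfo(data.dtype).max / 2) / (
            np.iinfo(data.dtype).max / 2)
    else:
        data = data.astype(float)
    return data, float(rate)


def compute_envelope(audio: np.ndarray, rate_hz: float) -> EnvelopeSeries:
    """Low-pass amplitude envelope of a mono waveform, at the audio rate.

    Raises on empty or multichannel input or rates below 8 kHz (speech
    bandwidth would already be missing).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a nonempty 1-D mono array")
    if rate_hz < 8000:
        raise ValueError("audio rate must be at least 8 kHz")
    magnitude = np.abs(hilbert(audio))
    sos = butter(FILTER_ORDER, LOWPASS_HZ, fs=rate_hz, output="sos")
    env = sosfiltfilt(sos, magnitude)
    return EnvelopeSeries(np.maximum(env, 0.0), rate_hz)


def resample_envelope(env: EnvelopeSeries,
                      target_hz: float = ANALYSIS_RATE_HZ) -> EnvelopeSeries:
    """Anti-alias filter and resample the envelope (downsampling only)."""
    if target_hz > env.rate_hz:
        raise ValueError("upsampling is not supported")
    if target_hz == env.rate_hz:
        return EnvelopeSeries(env.values.copy(), env.rate_hz)
    values = _resample_values(env.values, env.rate_hz, target_hz)
    return EnvelopeSeries(values, float(target_hz))


def align(env: EnvelopeSeries,
          kin: KinematicSeries) -> tuple[EnvelopeSeries, KinematicSeries]:
    """Truncate envelope and kinematics to their common length.

    Start times are assumed coincident; both series must share a rate.
    """
    if env.rate_hz != kin.rate_hz:
        raise ValueError(f"rate mismatch: envelope {env.rate_hz} Hz vs "
                         f"kinematics {kin.rate_hz} Hz")
    n = min(env.n_samples, kin.n_samples)
    return (EnvelopeSeries(env.values[:n], env.rate_hz),
            kin.copy_with(values=kin.values[:n]))
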