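"""Synthetic gesture-and-speech generator with known, gravity-asymmetric coupling.

The generator emulates the statistical structure the decoding analysis
assumes: a 20-segment body whose arm segments perform smooth, ballistic
stroke-like movements, and a speech amplitude envelope that is a lagged
linear function of the body's vertical velocity — downward-positive, so
that gravity-assisted downward strokes drive acoustic amplitude — plus a
sign-symmetric horizontal loudness term, a small signed horizontal
(handedness) term, and additive noise.

Because the envelope couples to the *signed* vertical velocity while
downward strokes carry ``asym_gamma`` times the impulse of upward ones,
direction is informative on the vertical axis: a decoder given signed
velocity can recover the coupling exactly, while one given per-axis speed
cannot. On the horizontal axis the symmetric term favors speed and the
small signed term favors velocity, leaving the two encodings roughly
matched. This is the ground-truth analogue of the effect pattern the
analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .containers import EnvelopeSeries, MotionRecording
from .kinematics import ARM_SEGMENTS, DEFAULT_SEGMENTS

#: Gaussian stroke velocity profile width (ballistic gesture stroke).
STROKE_SIGMA_S = 0.12
#: Trunk/head segments follow limb motion through a low-pass coupling.
TRUNK_GAIN = 0.3
TRUNK_CUTOFF_HZ = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic gesture-speech generator.

    Defaults are the package's reference condition: 20 body segments,
    downward strokes carrying twice the impulse of upward ones
    (``asym_gamma=2``), envelope coupling peaking 150 ms after the motion,
    and a noise level leaving held-out vertical-velocity decoding around
    r ≈ 0.55 at the reference corpus size.
    """

    n_files: int = 8
    duration_s: float = 120.0
    raw_rate_hz: float = 120.0
    n_segments: int = 20
    stroke_rate_hz: float = 0.6          # strokes / s / limb segment / axis
    asym_gamma: float = 2.0              # |down| / |up| stroke impulse ratio
    kernel_delay_s: float = 0.15         # peak of motion -> envelope kernel
    kernel_width_s: float = 0.3          # kernel support = [0, 2 * width]
    coupling_gain_vertical: float = 1.0  # signed, downward-positive
    coupling_gain_horizontal_symmetric: float = 0.27
    coupling_gain_horizontal_signed: float = 0.15
    coupling_gain_depth: float = 0.0     # signed depth coupling (unused by default)
    noise_sd: float = 13.0
    baseline: float = 60.0               # resting envelope amplitude
    trunk_sway_sd: float = 0.1           # independent trunk/head velocity sd
    clip_negative: bool = True           # floor the noisy envelope at 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("raw_rate_hz",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stroke_rate_hz < 0:
            raise ValueError("stroke_rate_hz must be nonnegative")
        if self.asym_gamma < 1:
            raise ValueError("asym_gamma must be >= 1")
        if not (0 <= self.kernel_delay_s <= 1.0):
            raise ValueError("kernel_delay_s must lie in [0, 1] s so the "
                             "coupling sits inside the decoder lag window")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")

    @property
    def segment_names(self) -> list[str]:
        if self.n_segments == 20:
            return list(DEFAULT_SEGMENTS)
        return [f"SEG{k:02d}" for k in range(self.n_segments)]

    @property
    def limb_indices(self) -> list[int]:
        """Indices of the gesturing (arm) segments."""
        names = self.segment_names
        if self.n_segments == 20:
            return [names.index(s) for s in ARM_SEGMENTS]
        n_limb = max(2, round(0.3 * self.n_segments))
        return list(range(n_limb))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.raw_rate_hz))

    def null_symmetric(self, scale: float = 1.0) -> "GeneratorConfig":
        """The exchangeable null condition: no stroke asymmetry and equal
        signed coupling on every axis, so no Axis x Encoding interaction
        exists by construction. ``scale`` rescales the per-axis gain (the
        default splits the vertical gain evenly across the three axes)."""
        g = scale * self.coupling_gain_vertical / 3.0
        return replace(self, asym_gamma=1.0,
                       coupling_gain_vertical=g,
                       coupling_gain_horizontal_symmetric=0.0,
                       coupling_gain_horizontal_signed=g,
                       coupling_gain_depth=g)


def _file_rng(config: GeneratorConfig, file_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, file_index])


def coupling_kernel(config: GeneratorConfig) -> np.ndarray:
    """Causal motion-to-envelope kernel on delays [0, 2 * kernel_width_s].

    A Gaussian bump centered at ``kernel_delay_s`` (sd = width / 4),
    normalized to unit sum; length round(2 * width * raw_rate) + 1.
    """
    n = int(round(2 * config.kernel_width_s * config.raw_rate_hz)) + 1
    delays = np.arange(n) / config.raw_rate_hz
    sigma = config.kernel_width_s / 4.0
    k = np.exp(-0.5 * ((delays - config.kernel_delay_s) / sigma) ** 2)
    return k / k.sum()


def generate_strokes(config: GeneratorConfig, file_index: int) -> np.ndarray:
    """Draw stroke events for one file.

    Returns a structured array with fields ``time`` (s), ``segment`` (index),
    ``axis`` (0=x, 1=y, 2=z) and ``amplitude`` (signed net displacement).
    Event counts are Poisson per limb segment and axis; vertical downward
    amplitudes (negative y) carry ``asym_gamma`` times the magnitude of
    upward ones, horizontal and depth amplitudes are sign-symmetric.
    """
    rng = _file_rng(config, file_index)
    dtype = [("time", float), ("segment", int), ("axis", int), ("amplitude", float)]
    events: list[tuple[float, int, int, float]] = []
    for seg in config.limb_indices:
        for axis in range(3):
            n_ev = rng.poisson(config.stroke_rate_hz * config.duration_s)
            times = rng.uniform(0.0, config.duration_s, n_ev)
            mags = np.abs(rng.normal(1.0, 0.3, n_ev))
            down = rng.random(n_ev) < 0.5
            if axis == 1:  # vertical: downward strokes are stronger
                amps = np.where(down, -config.asym_gamma * mags, mags)
            else:
                amps = np.where(down, -mags, mags)
            events.extend(zip(times, [seg] * n_ev, [axis] * n_ev, amps))
    out = np.array(events, dtype=dtype)
    return np.sort(out, order="time")


def generate_motion(events: np.ndarray, config: GeneratorConfig,
                    file_index: int = 0) -> MotionRecording:
    """Render stroke events into segment positions.

    Each event contributes a Gaussian velocity pulse (sd 120 ms) on its
    segment and axis whose time integral equals the event amplitude;
    positions are the cumulative integral of velocity. Non-limb segments
    (trunk, head, legs) receive an attenuated, 1 Hz low-passed copy of the
    mean limb velocity (passive momentum transfer) plus their own slow
    independent sway (posture shifts, head nods) of velocity sd
    ``trunk_sway_sd``, so trunk motion is not a deterministic function of
    the limbs.
    """
    n = config.n_frames
    fs = config.raw_rate_hz
    vel = np.zeros((n, config.n_segments, 3))
    half = int(round(3 * STROKE_SIGMA_S * fs))
    tk = np.arange(-half, half + 1) / fs
    pulse = np.exp(-0.5 * (tk / STROKE_SIGMA_S) ** 2)
    pulse /= pulse.sum() / fs  # unit displacement integral
    L = pulse.size
    for ev in events:
        i = int(round(ev["time"] * fs))
        lo = max(0, i - half)
        hi = min(n, i - half + L)
        vel[lo:hi, ev["segment"], ev["axis"]] += (
            ev["amplitude"] * pulse[lo - (i - half):hi - (i - half)])

    limb = config.limb_indices
    others = [s for s in range(config.n_segments) if s not in limb]
    if others:
        sos = butter(2, TRUNK_CUTOFF_HZ, fs=fs, output="sos")
        rng = np.random.default_rng(
            [int(config.seed) & 0x7FFFFFFF, 10_000 + file_index])
        scales = rng.uniform(0.7, 1.3, size=len(others))
        if events.size:
            drive = sosfiltfilt(sos, vel[:, limb, :].mean(axis=1), axis=0)
        else:
            drive = np.zeros((n, 3))
        for k, s in enumerate(others):
            vel[:, s, :] = TRUNK_GAIN * scales[k] * drive
        if config.trunk_sway_sd > 0:
            sway = sosfiltfilt(sos, rng.normal(0.0, 1.0, (n, len(others), 3)),
                               axis=0)
            sd = sway.std(axis=0, keepdims=True)
            sd[sd < 1e-12] = 1.0
            vel[:, others, :] += config.trunk_sway_sd * sway / sd
    pos = np.cumsum(vel, axis=0) / fs
    return MotionRecording(pos, fs, config.segment_names)


def _limb_velocity(rec: MotionRecording, config: GeneratorConfig) -> np.ndarray:
    """(n, n_limb, 3) velocity of the limb segments, central differences."""
    v = np.gradient(rec.positions, 1.0 / rec.frame_rate_hz, axis=0)
    return v[:, config.limb_indices, :]


def generate_envelope_from_motion(
        rec: MotionRecording, config: GeneratorConfig,
        file_index: int = 0, return_clean: bool = False):
    """Build the amplitude envelope as a lagged linear function of motion.

    ``envelope = baseline + K * (g_v * sum(-v_y) + g_hs * sum(|v_x|)
    + g_hsig * sum(v_x) + g_z * sum(v_z)) + noise`` with ``K`` the causal
    coupling kernel and the sums over limb segments. The vertical term is
    odd in sign (downward-positive, directional), the symmetric horizontal
    term even (non-directional). Noise is Gaussian; the noisy envelope is
    floored at 0 when ``clip_negative``. The baseline (resting vocal
    amplitude) keeps the envelope positive, so with default settings the
    floor is essentially never active and the envelope stays an exact
    lagged linear function of the motion plus noise.
    """
    if rec.frame_rate_hz != config.raw_rate_hz:
        raise ValueError("recording rate does not match config.raw_rate_hz")
    v = _limb_velocity(rec, config)
    drive = (config.coupling_gain_vertical * (-v[:, :, 1]).sum(axis=1)
             + config.coupling_gain_horizontal_symmetric * np.abs(v[:, :, 0]).sum(axis=1)
             + config.coupling_gain_horizontal_signed * v[:, :, 0].sum(axis=1)
             + config.coupling_gain_depth * v[:, :, 2].sum(axis=1))
    kernel = coupling_kernel(config)
    clean = config.baseline + np.convolve(drive, kernel)[: rec.n_frames]
    # noise stream disjoint from the stroke/motion streams by construction
    rng = np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, 20_000 + file_index])
    noisy = clean + rng.normal(0.0, config.noise_sd, clean.size) \
        if config.noise_sd > 0 else clean.copy()
    if config.clip_negative:
        noisy = np.maximum(noisy, 0.0)
    env = EnvelopeSeries(noisy, rec.frame_rate_hz)
    if return_clean:
        return env, EnvelopeSeries(clean, rec.frame_rate_hz)
    return env


@dataclass
class SyntheticDataset:
    """A generated corpus: recordings with matched envelopes and the true kernel."""

    recordings: list[MotionRecording]
    envelopes: list[EnvelopeSeries]
    envelopes_clean: list[EnvelopeSeries]
    true_kernel: np.ndarray
    config: GeneratorConfig

    @property
    def n_files(self) -> int:
        return len(self.recordings)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate ``n_files`` recordings with coupled envelopes; deterministic
    under ``config.seed``."""
    recordings, envelopes, clean = [], [], []
    for i in range(config.n_files):
        events = generate_strokes(config, i)
        rec = generate_motion(events, config, file_index=i)
        env, env_clean = generate_envelope_from_motion(
            rec, config, file_index=i, return_clean=True)
        recordings.append(rec)
        envelopes.append(env)
        clean.append(env_clean)
    return SyntheticDataset(recordings, envelopes, clean,
                            coupling_kernel(config), config)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                  wav: bool = False, wav_rate: int = 8000,
                  carrier_hz: float = 220.0) -> list[Path]:
    """Write each file's marker table and envelope as CSV; optionally an
    amplitude-modulated carrier WAV for exercising the audio pipeline."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (rec, env) in enumerate(zip(dataset.recordings, dataset.envelopes)):
        mpath = out_dir / f"file{i:02d}_motion.csv"
        epath = out_dir / f"file{i:02d}_envelope.csv"
        rec.to_csv(mpath)
        env.to_csv(epath)
        written += [mpath, epath]
        if wav:
            t = np.arange(int(rec.duration_s * wav_rate)) / wav_rate
            mod = np.interp(t, np.arange(env.n_samples) / env.rate_hz,
                            np.maximum(env.values, 0.0))
            mod = mod / (mod.max() or 1.0)
            audio = (mod * np.sin(2 * np.pi * carrier_hz * t) * 0.9)
            wpath = out_dir / f"file{i:02d}_audio.wav"
            wavfile.write(wpath, wav_rate, (audio * 32767).astype(np.int16))
            written.append(wpath)
    return written
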