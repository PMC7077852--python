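"""Synthetic EEG session generator for motor-imagery ERD/ERS studies.

Emulates a cue-based left/right foot kinaesthetic motor-imagery protocol:
a 19-channel 10-20 montage sampled at 256 Hz, trials of 3 s fixation
(baseline), a 2 s visual cue at t=0 and a 5 s imagery window, separated by
random pauses. Band-limited oscillatory sources over the sensorimotor strip
(C3/Cz/C4) are amplitude-modulated inside per-trial windows to produce
event-related desynchronization (amplitude scale < 1) or synchronization
(scale > 1), with class-conditional lateral gains encoding contralateral
dominance, on top of 1/f background noise and optional ocular artifacts.

Every source is a white-noise process band-filtered to its frequency
interval, so power-spectral estimates of the output behave like real EEG
rather than like pure sinusoids.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: 10-20 channel labels of the default 19-electrode cap.
CHANNELS_1020 = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Approximate 2-D scalp positions on the unit disc (x: right, y: nose).
POSITIONS_1020 = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T3": (-0.95, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (0.95, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: Transverse neighbours used for spatial spread of sensorimotor sources.
_TRANSVERSE_NEIGHBOURS = {"C3": ("Cz",), "Cz": ("C3", "C4"), "C4": ("Cz",)}

#: Relative ocular-artifact gain per frontal channel.
_BLINK_TOPOGRAPHY = {
    "FP1": 1.0, "FP2": 1.0, "F7": 0.4, "F3": 0.5,
    "Fz": 0.4, "F4": 0.5, "F8": 0.4,
}

LABELS = ("left", "right")


@dataclass(frozen=True)
class MontageSpec:
    """Electrode montage: unique 10-20 labels with 2-D scalp coordinates."""

    channel_names: tuple[str, ...] = CHANNELS_1020
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(POSITIONS_1020)
    )

    def __post_init__(self):
        names = list(self.channel_names)
        if len(set(names)) != len(names):
            raise ConfigurationError("montage channel names must be unique")
        for required in ("C3", "Cz", "C4"):
            if required not in names:
                raise ConfigurationError(f"montage must include {required}")
        for name in names:
            if name not in self.positions:
                raise ConfigurationError(f"no scalp position for channel {name}")
            if not np.all(np.isfinite(self.positions[name])):
                raise ConfigurationError(f"non-finite position for channel {name}")

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not in montage {list(self.channel_names)}"
            ) from None

    def subset(self, names) -> "MontageSpec":
        return MontageSpec(tuple(names), {n: self.positions[n] for n in names})


@dataclass(frozen=True)
class TrialSchedule:
    """Per-trial timing of the cue-based imagery protocol.

    Each trial is ``baseline_s`` of fixation, the cue onset (t=0, displayed
    for ``cue_s``), and a blank-screen imagery window ending at
    ``cue_s + task_s`` (10 s total with the defaults), followed by a random
    pause drawn uniformly from ``pause_range_s``.
    """

    baseline_s: float = 3.0
    cue_s: float = 2.0
    task_s: float = 5.0
    pause_range_s: tuple[float, float] = (1.5, 3.5)
    n_trials_per_class: int = 80
    fs: float = 256.0

    def __post_init__(self):
        if min(self.baseline_s, self.cue_s, self.task_s) <= 0:
            raise ConfigurationError("all trial durations must be positive")
        if self.pause_range_s[0] > self.pause_range_s[1]:
            raise ConfigurationError("pause_range_s lower bound exceeds upper")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("need at least one trial per class")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.cue_s + self.task_s


@dataclass(frozen=True)
class EffectSpec:
    """One band-limited oscillatory source with an ERD/ERS modulation window.

    The source oscillates continuously; inside the per-trial active window
    ``[onset_s, offset_s]`` (relative to cue onset, jittered per trial) its
    amplitude is multiplied by ``erd_scale`` times the class-conditional
    lateral gain. A scale s yields an expected band-power change of
    (s**2 - 1) * 100 percent, so s < 1 produces ERD and s > 1 ERS.

    ``shape`` controls the modulation envelope: ``plateau`` ramps in and out
    over ``ramp_s`` and is flat in between (calibrated power change on the
    plateau); ``hann`` is a raised-cosine bump peaking at the window centre
    (well-defined peak latency).
    """

    band_hz: tuple[float, float]
    source_channel: str
    erd_scale: float
    onset_s: float
    offset_s: float
    latency_jitter_sd_s: float = 0.0
    lateral_gain_left: float = 1.0
    lateral_gain_right: float = 1.0
    spatial_spread: float = 0.0
    shape: str = "plateau"
    ramp_s: float = 0.25
    amp_uv: float = 8.0

    def __post_init__(self):
        if self.erd_scale < 0:
            raise ConfigurationError("erd_scale must be non-negative")
        if not self.onset_s < self.offset_s:
            raise ConfigurationError("effect onset_s must precede offset_s")
        if self.lateral_gain_left < 0 or self.lateral_gain_right < 0:
            raise ConfigurationError("lateral gains must be non-negative")
        if not 0 <= self.spatial_spread <= 1:
            raise ConfigurationError("spatial_spread must lie in [0, 1]")
        if self.shape not in ("plateau", "hann"):
            raise ConfigurationError(f"unknown envelope shape {self.shape!r}")
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ConfigurationError("band_hz must be an increasing positive pair")

    def gain(self, label: str) -> float:
        return self.lateral_gain_left if label == "left" else self.lateral_gain_right


@dataclass(frozen=True)
class NoiseSpec:
    """Background 1/f noise and optional ocular (blink) artifacts."""

    pink_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    blink_rate_hz: float = 0.0
    blink_amp_uv: float = 80.0
    blink_duration_s: float = 0.3

    def __post_init__(self):
        if self.noise_rms_uv < 0:
            raise ConfigurationError("noise_rms_uv must be non-negative")
        if self.blink_rate_hz < 0:
            raise ConfigurationError("blink_rate_hz must be non-negative")


@dataclass
class Recording:
    """Continuous multichannel EEG with montage, events and reference tag."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    montage: MontageSpec
    events: list[tuple[int, str]]
    reference_tag: str = "linked-earlobe-raw"
    channel_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("recording data must be channels x samples")
        if not self.channel_names:
            self.channel_names = tuple(self.montage.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length does not match data rows")
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise DataError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise DataError("event sample indices must lie inside the data")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not present in recording"
            ) from None


def default_effects() -> list[EffectSpec]:
    """Default sensorimotor effect battery.

    Mirrors the qualitative structure of foot-imagery sensorimotor rhythms:
    mu (7-12 Hz) ERD through the imagery window, low-beta (13-24 Hz) ERD
    from cue onset, and a dominant ~1.2 s high-beta (25-35 Hz) rebound (ERS)
    after the imagined movement, peaking near 3.5 s from cue onset. Lateral
    gains follow a contralateral convention: the hemisphere opposite the
    imagined foot expresses the deeper ERD / stronger ERS, with the
    asymmetry largest for the high-beta rebound.
    """
    effects: list[EffectSpec] = []
    for ch, g_left, g_right in (("C3", 1.15, 0.80), ("Cz", 1.0, 1.0),
                                ("C4", 0.80, 1.15)):
        effects.append(EffectSpec(
            band_hz=(7.0, 12.0), source_channel=ch, erd_scale=0.55,
            onset_s=0.5, offset_s=5.0, latency_jitter_sd_s=0.15,
            lateral_gain_left=g_left, lateral_gain_right=g_right,
            spatial_spread=0.2, amp_uv=8.0))
    for ch, g_left, g_right in (("C3", 1.10, 0.90), ("Cz", 1.0, 1.0),
                                ("C4", 0.90, 1.10)):
        effects.append(EffectSpec(
            band_hz=(13.0, 24.0), source_channel=ch, erd_scale=0.60,
            onset_s=0.3, offset_s=4.0, latency_jitter_sd_s=0.15,
            lateral_gain_left=g_left, lateral_gain_right=g_right,
            spatial_spread=0.2, amp_uv=5.0))
    for ch, g_left, g_right in (("C3", 0.80, 1.25), ("Cz", 1.0, 1.0),
                                ("C4", 1.25, 0.80)):
        effects.append(EffectSpec(
            band_hz=(25.0, 35.0), source_channel=ch, erd_scale=1.9,
            onset_s=2.9, offset_s=4.1, latency_jitter_sd_s=0.20,
            lateral_gain_left=g_left, lateral_gain_right=g_right,
            spatial_spread=0.2, shape="hann", amp_uv=5.0))
    return effects


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f**exponent."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spectrum * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_limited_noise(rng: np.random.Generator, n: int, band_hz, fs: float
                        ) -> np.ndarray:
    """Unit-RMS white noise band-filtered to ``band_hz`` (the carrier process)."""
    lo, hi = band_hz
    numtaps = _fir_numtaps(fs, transition_hz=2.0)
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                         window="hamming")
    carrier = signal.fftconvolve(rng.standard_normal(n + numtaps), taps,
                                 mode="same")[numtaps // 2:numtaps // 2 + n]
    sd = carrier.std()
    return carrier / sd if sd > 0 else carrier


def _fir_numtaps(fs: float, transition_hz: float) -> int:
    # Hamming window: transition width ~ 3.3 / numtaps (normalized frequency)
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    return numtaps + 1 if numtaps % 2 == 0 else numtaps


def _window_profile(n: int, fs: float, shape: str, ramp_s: float) -> np.ndarray:
    """Envelope weight w(t) in [0, 1] over an active window of n samples."""
    if shape == "hann":
        return np.hanning(n)
    ramp = min(int(round(ramp_s * fs)), n // 2)
    w = np.ones(n)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = edge
        w[-ramp:] = edge[::-1]
    return w


def generate_session(schedule: TrialSchedule | None = None,
                     effects: list[EffectSpec] | None = None,
                     noise: NoiseSpec | None = None,
                     montage: MontageSpec | None = None,
                     seed: int = 0) -> Recording:
    """Generate one synthetic session as a continuous :class:`Recording`.

    The output is a pure function of the configuration and ``seed``: two
    calls with identical arguments return bit-identical sample arrays.
    Left/right cue labels are balanced (``n_trials_per_class`` each) in
    seeded-random order.
    """
    schedule = schedule or TrialSchedule()
    effects = default_effects() if effects is None else effects
    noise = noise or NoiseSpec()
    montage = montage or MontageSpec()
    fs = schedule.fs

    for eff in effects:
        montage.index(eff.source_channel)  # raises if unknown
        if eff.band_hz[1] >= fs / 2:
            raise ConfigurationError(
                f"band {eff.band_hz} exceeds the Nyquist frequency at fs={fs}")

    rng = np.random.default_rng(seed)

    n_per_class = schedule.n_trials_per_class
    labels = np.array(["left"] * n_per_class + ["right"] * n_per_class)
    rng.shuffle(labels)
    pauses = rng.uniform(*schedule.pause_range_s, size=2 * n_per_class)

    pad_s = 2.0
    trial_starts_s = np.empty(2 * n_per_class)
    t = pad_s
    for i in range(2 * n_per_class):
        trial_starts_s[i] = t
        t += schedule.trial_s + pauses[i]
    total_s = t + pad_s
    n_samples = int(round(total_s * fs))
    cue_samples = np.round((trial_starts_s + schedule.baseline_s) * fs).astype(int)
    events = [(int(s), str(lbl)) for s, lbl in zip(cue_samples, labels)]

    n_channels = len(montage.channel_names)
    data = np.zeros((n_channels, n_samples))

    # Background 1/f noise, independent per channel.
    if noise.noise_rms_uv > 0:
        for ci in range(n_channels):
            data[ci] += noise.noise_rms_uv * _pink_noise(
                rng, n_samples, noise.pink_exponent)

    # Oscillatory sources with per-trial amplitude modulation.
    for eff in effects:
        carrier = _band_limited_noise(rng, n_samples, eff.band_hz, fs)
        jitters = (rng.normal(0.0, eff.latency_jitter_sd_s, size=len(events))
                   if eff.latency_jitter_sd_s > 0 else np.zeros(len(events)))
        envelope = np.ones(n_samples)
        for (cue_sample, label), jitter in zip(events, jitters):
            scale = eff.erd_scale * eff.gain(label)
            a = cue_sample + int(round((eff.onset_s + jitter) * fs))
            b = cue_sample + int(round((eff.offset_s + jitter) * fs))
            a, b = max(a, 0), min(b, n_samples)
            if b <= a:
                continue
            w = _window_profile(b - a, fs, eff.shape, eff.ramp_s)
            envelope[a:b] = 1.0 + (scale - 1.0) * w
        source = eff.amp_uv * carrier * envelope
        data[montage.index(eff.source_channel)] += source
        if eff.spatial_spread > 0:
            for neighbour in _TRANSVERSE_NEIGHBOURS.get(eff.source_channel, ()):
                if neighbour in montage.channel_names:
                    data[montage.index(neighbour)] += eff.spatial_spread * source

    # Ocular artifacts: Poisson blink train projected onto frontal channels.
    blink_times = []
    if noise.blink_rate_hz > 0 and noise.blink_amp_uv > 0:
        n_blinks = rng.poisson(noise.blink_rate_hz * total_s)
        starts = np.sort(rng.uniform(0, total_s - noise.blink_duration_s,
                                     size=n_blinks))
        width = int(round(noise.blink_duration_s * fs))
        bump = np.hanning(width) ** 2
        for start in starts:
            a = int(round(start * fs))
            b = min(a + width, n_samples)
            for ch, gain in _BLINK_TOPOGRAPHY.items():
                if ch in montage.channel_names:
                    data[montage.index(ch)][a:b] += (
                        noise.blink_amp_uv * gain * bump[:b - a])
            blink_times.append((start, start + noise.blink_duration_s))

    meta = {
        "seed": int(seed),
        "generator_config": {
            "schedule": dataclasses.asdict(schedule),
            "effects": [dataclasses.asdict(e) for e in effects],
            "noise": dataclasses.asdict(noise),
        },
        "blink_windows_s": blink_times,
        "duration_s": total_s,
    }
    return Recording(data=data, fs=fs, montage=montage, events=events,
                     meta=meta)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def export_fixture(recording: Recording, path) -> tuple[pathlib.Path, pathlib.Path]:
    """Write a recording as a raw float32 array plus a JSON sidecar.

    The raw file is little-endian 32-bit float, channel-major
    (channels x samples); the sidecar carries montage, sampling rate,
    events and generator provenance. Round-trips bit-exactly through
    :func:`erdskit.pipeline_io.read_recording` (float32 precision).
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    raw_path = path / "recording.f32"
    sidecar_path = path / "recording.json"
    if not recording.events:
        logger.warning("exporting recording with no events: %s", path)
    recording.data.astype("<f4").tofile(raw_path)
    sidecar = {
        "format": "erdskit-fixture-v1",
        "dtype": "<f4",
        "order": "channel-major",
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "positions": {k: list(v) for k, v in recording.montage.positions.items()},
        "events": [{"sample": s, "label": l} for s, l in recording.events],
        "reference_tag": recording.reference_tag,
        "meta": _jsonable(recording.meta),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return raw_path, sidecar_path
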