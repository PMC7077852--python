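"""Shared fixtures: small synthetic sessions reused across test modules.

Sessions are generated once per test run (session scope) because signal
generation and filtering dominate the suite's runtime.
"""

import numpy as np
import pytest

import erdskit as ek
from erdskit.synthgen import POSITIONS_1020


@pytest.fixture(scope="session")
def sensorimotor_montage():
    """Minimal montage: just the sensorimotor strip C3/Cz/C4."""
    names = ("C3", "Cz", "C4")
    return ek.MontageSpec(names, {k: POSITIONS_1020[k] for k in names})


@pytest.fixture(scope="session")
def short_schedule():
    return ek.TrialSchedule(n_trials_per_class=20)


@pytest.fixture(scope="session")
def null_epochs(sensorimotor_montage, short_schedule):
    """Background-noise-only session (no injected effects), epoched."""
    rec = ek.generate_session(schedule=short_schedule, effects=[],
                              montage=sensorimotor_montage, seed=901)
    return ek.epoch(rec)


@pytest.fixture(scope="session")
def calibration_epochs(sensorimotor_montage):
    """Noiseless single mu source at Cz, amplitude scale 0.5 through the
    imagery window, no jitter: the band-power change converges to -75%."""
    eff = [ek.EffectSpec(band_hz=(7.0, 12.0), source_channel="Cz",
                         erd_scale=0.5, onset_s=0.5, offset_s=5.0)]
    rec = ek.generate_session(effects=eff,
                              noise=ek.NoiseSpec(noise_rms_uv=0.0),
                              montage=sensorimotor_montage, seed=902)
    return ek.epoch(rec)


@pytest.fixture(scope="session")
def effect_epochs(sensorimotor_montage, short_schedule):
    """Small session with the default effect battery, filtered and epoched."""
    rec = ek.generate_session(schedule=short_schedule,
                              montage=sensorimotor_montage, seed=903)
    return ek.epoch(ek.bandpass(rec))


@pytest.fixture(scope="session")
def default_session():
    """One full-size default session (19 channels, 80 trials/class)."""
    return ek.generate_session(seed=42)


def make_recording(data, fs=256.0, channel_names=("C3", "Cz", "C4"),
                   events=()):
    """Build a Recording around a plain array for toy-value tests."""
    names = tuple(channel_names)
    positions = {ch: POSITIONS_1020.get(ch, (0.0, 0.0)) for ch in names}
    montage = ek.MontageSpec(names, positions) if set(
        ("C3", "Cz", "C4")) <= set(names) else None
    if montage is None:
        base = dict(positions)
        base.update({c: POSITIONS_1020[c] for c in ("C3", "Cz", "C4")})
        montage = ek.MontageSpec(tuple(base), base)
    return ek.Recording(data=np.asarray(data, dtype=float), fs=fs,
                        montage=montage, events=list(events),
                        channel_names=names)
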