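"""ERD/ERS quantification: ITV, band power, percent change, TF maps,
bootstrap significance, time courses, peak latencies, topography."""

import numpy as np
import pytest

import erdskit as ek
from erdskit.erds import BANDS, PRIMARY_BINS
from erdskit.exceptions import ConfigurationError, DataError

from conftest import make_recording


def _sinusoid(freq, fs=256.0, seconds=4.0, phase=0.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestITV:
    def test_mean_across_trials_zero(self, effect_epochs):
        out = ek.itv_transform(effect_epochs, "left")
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-10)

    def test_identical_trials_zero_out(self):
        trial = np.random.default_rng(0).standard_normal((3, 800))
        eps = ek.Epochs(data=np.stack([trial, trial]),
                        times_s=np.arange(800) / 256.0 - 3.0,
                        labels=np.array(["left", "left"]),
                        channel_names=("C3", "Cz", "C4"), fs=256.0)
        out = ek.itv_transform(eps, "left")
        assert np.allclose(out.data, 0.0)

    def test_removes_evoked_keeps_induced(self):
        """A phase-locked (identical across trials) component is removed;
        a random-phase induced oscillation keeps its power."""
        fs, n = 256.0, 1024
        rng = np.random.default_rng(5)
        evoked = _sinusoid(10.0, fs, n / fs, amp=2.0)
        trials = []
        for _ in range(40):
            induced = _sinusoid(20.0, fs, n / fs,
                                phase=rng.uniform(0, 2 * np.pi))
            trials.append((evoked + induced)[None, :].repeat(3, axis=0))
        eps = ek.Epochs(data=np.stack(trials),
                        times_s=np.arange(n) / fs - 3.0,
                        labels=np.array(["left"] * 40),
                        channel_names=("C3", "Cz", "C4"), fs=fs)
        out = ek.itv_transform(eps, "left")
        bp = lambda data, band: np.mean(
            [ek.band_power(tr[0], fs, band) for tr in data])
        assert bp(out.data, "mu") < 0.1 * bp(eps.data, "mu")
        induced_before = bp(eps.data, "low_beta")
        induced_after = bp(out.data, "low_beta")
        assert abs(induced_after - induced_before) / induced_before < 0.10

    def test_absent_class_raises(self, effect_epochs):
        with pytest.raises(DataError):
            ek.itv_transform(effect_epochs, "tongue")


class TestBandPower:
    fs = 256.0

    def test_zero_signal_zero_power(self):
        assert ek.band_power(np.zeros(1024), self.fs, "mu") == 0.0

    def test_10hz_tone_lands_in_mu(self):
        x = _sinusoid(10.0, self.fs)
        mu = ek.band_power(x, self.fs, "mu")
        beta = ek.band_power(x, self.fs, "beta")
        assert mu > 100 * beta

    def test_quadratic_amplitude_scaling(self):
        x = _sinusoid(10.0, self.fs)
        assert ek.band_power(2 * x, self.fs, "mu") == pytest.approx(
            4 * ek.band_power(x, self.fs, "mu"), rel=0.02)

    def test_short_window_error_names_minimum(self):
        with pytest.raises(DataError, match="2 cycles"):
            ek.band_power(np.zeros(10), self.fs, "mu")


class TestPercentPowerChange:
    fs = 256.0

    def test_equal_power_gives_zero(self):
        x = _sinusoid(10.0, self.fs, 2.5)
        stat = ek.percent_power_change(x, [x, x], "mu", self.fs, 2.0, 4.5)
        assert stat.y == pytest.approx(0.0, abs=1e-9)

    def test_double_power_gives_plus_100(self):
        x = _sinusoid(10.0, self.fs, 2.5)
        stat = ek.percent_power_change(np.sqrt(2) * x, [x], "mu", self.fs,
                                       2.0, 4.5)
        assert stat.y == pytest.approx(100.0, abs=1.0)

    def test_half_amplitude_gives_minus_75(self):
        rng = np.random.default_rng(7)
        base = [ek.synthgen._band_limited_noise(rng, 640, (7, 12), self.fs)
                for _ in range(20)]
        ys = []
        for _ in range(20):
            task = 0.5 * ek.synthgen._band_limited_noise(rng, 640, (7, 12),
                                                         self.fs)
            ys.append(ek.percent_power_change(task, base, "mu", self.fs,
                                              2.0, 4.5).y)
        assert np.mean(ys) == pytest.approx(-75.0, abs=5.0)

    def test_window_constraint_enforced(self):
        x = _sinusoid(10.0, self.fs, 2.0)
        with pytest.raises(ConfigurationError):
            ek.percent_power_change(x, [x], "mu", self.fs, 0.5, 2.5)

    def test_zero_baseline_power_rejected(self):
        x = _sinusoid(10.0, self.fs, 2.5)
        with pytest.raises(DataError):
            ek.percent_power_change(x, [np.zeros(640)], "mu", self.fs,
                                    2.0, 4.5)

    def test_eq1_identity_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(768)
        base = [rng.standard_normal(768) for _ in range(5)]
        stat = ek.percent_power_change(x, base, "beta", self.fs, 2.0, 5.0)
        assert stat.y == pytest.approx(stat.recompute_y(), abs=1e-9)
        scaled = ek.percent_power_change(3.0 * x, [3.0 * b for b in base],
                                         "beta", self.fs, 2.0, 5.0)
        assert scaled.y == pytest.approx(stat.y, abs=1e-6)


class TestBandDefinitions:
    def test_primary_bins_tile_7_to_35(self):
        assert PRIMARY_BINS[0].lo_hz == 7 and PRIMARY_BINS[-1].hi_hz == 35
        for a, b in zip(PRIMARY_BINS, PRIMARY_BINS[1:]):
            assert a.hi_hz < b.lo_hz  # disjoint
        assert BANDS["beta"].lo_hz == 13 and BANDS["beta"].hi_hz == 35


@pytest.fixture(scope="module")
def erd_epochs(sensorimotor_montage):
    eff = [ek.EffectSpec(band_hz=(7.0, 12.0), source_channel="Cz",
                         erd_scale=0.5, onset_s=0.5, offset_s=5.0)]
    rec = ek.generate_session(
        schedule=ek.TrialSchedule(n_trials_per_class=20), effects=eff,
        noise=ek.NoiseSpec(noise_rms_uv=2.0),
        montage=sensorimotor_montage, seed=31)
    return ek.epoch(rec)


class TestTFMap:
    def test_injected_mu_erd_detected(self, erd_epochs):
        tm = ek.tf_map(erd_epochs, "Cz", "left")
        tm = ek.bootstrap_significance(tm, seed=1)
        window = (tm.times_s > 1.5) & (tm.times_s < 4.0)
        mu_vals = tm.values[0][window]
        assert mu_vals.mean() < -40.0
        assert tm.sig_mask[0][window].mean() > 0.5

    def test_post_task_ers_peaks_after_offset(self, sensorimotor_montage):
        eff = [ek.EffectSpec(band_hz=(25.0, 35.0), source_channel="Cz",
                             erd_scale=2.0, onset_s=5.5, offset_s=6.5,
                             shape="hann")]
        rec = ek.generate_session(
            schedule=ek.TrialSchedule(n_trials_per_class=20), effects=eff,
            noise=ek.NoiseSpec(noise_rms_uv=2.0),
            montage=sensorimotor_montage, seed=32)
        tm = ek.tf_map(ek.epoch(rec), "Cz", "left")
        peak_time = tm.times_s[np.argmax(tm.values[2])]
        assert peak_time > 5.0

    def test_shape_contract(self, erd_epochs):
        tm = ek.tf_map(erd_epochs, "Cz", "left")
        assert tm.values.shape == (3, 100)
        assert len(tm.times_s) == 100
        assert tm.times_s[0] > -3.0 and tm.times_s[-1] < 7.0

    def test_absent_channel_rejected(self, erd_epochs):
        with pytest.raises(ConfigurationError):
            ek.tf_map(erd_epochs, "F3", "left")

    def test_agrees_with_band_power_ratio(self, erd_epochs):
        """Wavelet-bin average and Welch band-power ratio estimate the
        same quantity; they agree within 15%."""
        tm = ek.tf_map(erd_epochs, "Cz", "left")
        window = (tm.times_s >= 2.0) & (tm.times_s < 4.5)
        wavelet_y = tm.values[0][window].mean()
        welch_y = ek.topography_values(erd_epochs, "mu", (2.0, 4.5),
                                       "left")["Cz"]
        assert abs(wavelet_y - welch_y) < 15.0


class TestBootstrap:
    def test_deterministic_given_seed(self, null_epochs):
        tm1 = ek.bootstrap_significance(
            ek.tf_map(null_epochs, "Cz", "left"), seed=3)
        tm2 = ek.bootstrap_significance(
            ek.tf_map(null_epochs, "Cz", "left"), seed=3)
        assert np.array_equal(tm1.sig_mask, tm2.sig_mask)

    def test_mask_nested_in_alpha(self, null_epochs):
        strict = ek.bootstrap_significance(
            ek.tf_map(null_epochs, "Cz", "left"), alpha=0.01, seed=4,
            n_boot=500)
        loose = ek.bootstrap_significance(
            ek.tf_map(null_epochs, "Cz", "left"), alpha=0.05, seed=4,
            n_boot=500)
        assert not np.any(strict.sig_mask & ~loose.sig_mask)

    def test_small_n_boot_rejected(self, null_epochs):
        tm = ek.tf_map(null_epochs, "Cz", "left")
        with pytest.raises(ConfigurationError):
            ek.bootstrap_significance(tm, n_boot=10)


class TestTimeCourseAndLatency:
    def test_baseline_mean_zero(self, effect_epochs):
        curve = ek.erds_time_course(effect_epochs, "Cz", "mu", "left")
        base = curve.values[curve.times_s < 0]
        assert abs(base.mean()) < 1e-6

    def test_null_curve_stays_near_zero(self, null_epochs):
        curve = ek.erds_time_course(null_epochs, "Cz", "beta", "left")
        interior = (curve.times_s > -2.5) & (curve.times_s < 6.5)
        assert np.all(np.abs(curve.values[interior])
                      < 3 * curve.sem[interior] + 15.0)

    def test_erd_minimum_at_injected_center(self, sensorimotor_montage):
        eff = [ek.EffectSpec(band_hz=(7.0, 12.0), source_channel="Cz",
                             erd_scale=0.5, onset_s=1.4, offset_s=3.4,
                             shape="hann")]
        rec = ek.generate_session(
            schedule=ek.TrialSchedule(n_trials_per_class=20), effects=eff,
            noise=ek.NoiseSpec(noise_rms_uv=2.0),
            montage=sensorimotor_montage, seed=33)
        curve = ek.erds_time_course(ek.epoch(ek.bandpass(rec)), "Cz", "mu",
                                    "left")
        peak = ek.peak_latency(curve, "mu_erd")
        assert peak is not None
        assert peak.latency_s == pytest.approx(2.4, abs=0.25)

    def test_ers_burst_found_in_post_imagery_window(self,
                                                    sensorimotor_montage):
        eff = [ek.EffectSpec(band_hz=(25.0, 35.0), source_channel="Cz",
                             erd_scale=2.0, onset_s=3.0, offset_s=4.2,
                             shape="hann")]
        rec = ek.generate_session(
            schedule=ek.TrialSchedule(n_trials_per_class=20), effects=eff,
            noise=ek.NoiseSpec(noise_rms_uv=2.0),
            montage=sensorimotor_montage, seed=34)
        curve = ek.erds_time_course(ek.epoch(ek.bandpass(rec)), "Cz",
                                    "high_beta", "left")
        peak = ek.peak_latency(curve, "beta_ers")
        assert peak is not None
        assert peak.polarity == "max"
        assert 2.0 < peak.latency_s < 7.0
        assert peak.latency_s == pytest.approx(3.6, abs=0.4)

    def test_flat_curve_yields_no_peak(self):
        curve = ek.ERDSCurve(values=np.zeros(100),
                             times_s=np.linspace(-3, 7, 100),
                             band=BANDS["mu"], channel="Cz",
                             class_label="left")
        assert ek.peak_latency(curve, "mu_erd") is None

    def test_unknown_feature_rejected(self):
        curve = ek.ERDSCurve(values=np.zeros(10),
                             times_s=np.linspace(0, 7, 10),
                             band=BANDS["mu"], channel="Cz",
                             class_label="left")
        with pytest.raises(ConfigurationError):
            ek.peak_latency(curve, "gamma_ers")


class TestTopography:
    def test_source_channel_is_extremal(self, sensorimotor_montage):
        eff = [ek.EffectSpec(band_hz=(7.0, 12.0), source_channel="Cz",
                             erd_scale=0.5, onset_s=0.5, offset_s=5.0)]
        rec = ek.generate_session(
            schedule=ek.TrialSchedule(n_trials_per_class=15), effects=eff,
            noise=ek.NoiseSpec(noise_rms_uv=2.0),
            montage=sensorimotor_montage, seed=35)
        topo = ek.topography_values(ek.epoch(rec), "mu", (2.0, 4.5), "left")
        assert max(topo, key=lambda ch: abs(topo[ch])) == "Cz"

    def test_no_effect_values_near_zero(self, null_epochs):
        topo = ek.topography_values(null_epochs, "mu", (2.0, 4.5), "left")
        assert all(abs(v) < 30.0 for v in topo.values())

    def test_contralateral_erd_deeper_for_left_class(self, effect_epochs):
        # default battery: left-class mu ERD is deeper at C4 than at C3
        topo = ek.topography_values(effect_epochs, "mu", (2.0, 4.5), "left")
        assert topo["C4"] < topo["C3"]

    def test_window_outside_epoch_rejected(self, null_epochs):
        with pytest.raises(ConfigurationError):
            ek.topography_values(null_epochs, "mu", (6.0, 9.0), "left")
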