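"""Quantification of event-related desynchronization and synchronization.

The central statistic is the percentage band-power change of a task-window
epoch relative to the mean band power of N pre-cue baseline segments:

    y(t0, tf) = 100 * (BP_MI(t0, tf) - mean_BP_baseline(t0, tf))
                    / mean_BP_baseline(t0, tf)

with negative y indicating ERD and positive y ERS. Induced (non
phase-locked) activity is isolated first by the inter-trial-variance (ITV)
transform: the class-average evoked potential is subtracted from every
trial before power estimation.

Time-frequency maps use complex Morlet wavelets averaged into three
sensorimotor bins (mu 7-12 Hz, low beta 13-24 Hz, high beta 25-35 Hz) on a
100-column time grid; their significance is assessed against a surrogate
baseline distribution built by drawing, per trial, a spectral estimate at a
random latency inside the baseline and averaging across trials (bootstrap
of the baseline, 200 resamples, two-sided 95% interval by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import trapezoid

from .exceptions import ConfigurationError, DataError
from .preprocess import Epochs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not self.lo_hz < self.hi_hz:
            raise ConfigurationError("band lo_hz must be below hi_hz")


#: Sensorimotor-rhythm bands. The three primary bins are disjoint and tile
#: 7-35 Hz; "beta" is the union of low and high beta.
BANDS = {
    "mu": BandDefinition("mu", 7.0, 12.0),
    "low_beta": BandDefinition("low_beta", 13.0, 24.0),
    "high_beta": BandDefinition("high_beta", 25.0, 35.0),
    "beta": BandDefinition("beta", 13.0, 35.0),
}

PRIMARY_BINS = (BANDS["mu"], BANDS["low_beta"], BANDS["high_beta"])


def get_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ConfigurationError(f"unknown band {band!r}") from None


@dataclass
class BandPowerStat:
    """One percentage band-power change (ERD/ERS) observation."""

    y: float
    band: BandDefinition
    channel: str
    t0_s: float
    tf_s: float
    bp_mi: float
    bp_baseline_mean: float
    n_baseline: int

    def recompute_y(self) -> float:
        return 100.0 * (self.bp_mi - self.bp_baseline_mean) / self.bp_baseline_mean


@dataclass
class TFMap:
    """Time x frequency-bin percentage power change with significance mask."""

    values: np.ndarray           # (n_bins, n_times), percent change
    times_s: np.ndarray          # n_times columns spanning the epoch
    bins: tuple[BandDefinition, ...]
    channel: str
    class_label: str
    sig_mask: np.ndarray | None = None
    alpha: float = 0.05
    n_boot: int = 200
    # Per-trial binned raw power (trials, bins, times) and the per-bin
    # baseline means; retained for the bootstrap surrogate construction.
    trial_power: np.ndarray | None = field(default=None, repr=False)
    baseline_mean: np.ndarray | None = field(default=None, repr=False)
    baseline_window_s: tuple[float, float] = (-3.0, 0.0)


@dataclass
class ERDSCurve:
    """Percentage power change versus time for one band/channel/class."""

    values: np.ndarray
    times_s: np.ndarray
    band: BandDefinition
    channel: str
    class_label: str
    sem: np.ndarray | None = None


@dataclass
class PeakLatency:
    latency_s: float
    feature: str
    polarity: str  # "min" for ERD features, "max" for ERS
    value_pct: float


def itv_transform(epochs: Epochs, class_label: str) -> Epochs:
    """Subtract the class-average evoked potential from each trial.

    Returns only the trials of ``class_label``; at every channel and sample
    the mean across the returned trials is zero, so subsequent power
    estimates reflect induced (non phase-locked) activity only. Squaring
    happens in the power-estimation step, not here.
    """
    mask = epochs.class_mask(class_label)
    if mask.sum() < 2:
        raise DataError(f"need at least 2 trials of class {class_label!r}")
    data = epochs.data[mask]
    erp = data.mean(axis=0, keepdims=True)
    return epochs.copy_with(data - erp, labels=epochs.labels[mask])


def band_power(x: np.ndarray, fs: float, band) -> float:
    """Band power of a 1-D signal: Welch PSD integrated over [lo, hi].

    Welch settings: 1 s Hann segments with 50% overlap (shorter signals use
    a single full-length segment). Scales quadratically with amplitude.
    """
    band = get_band(band)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise DataError("band_power expects a 1-D signal")
    min_len = int(np.ceil(2 * fs / band.lo_hz))
    if len(x) < min_len:
        raise DataError(
            f"signal too short for {band.name} band power: need >= {min_len} "
            f"samples (2 cycles of {band.lo_hz} Hz), got {len(x)}")
    nperseg = min(len(x), int(round(fs)))
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="constant")
    in_band = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    if in_band.sum() < 2:
        return float(psd[in_band].sum() * (freqs[1] - freqs[0]))
    return float(trapezoid(psd[in_band], freqs[in_band]))


def percent_power_change(task_epoch: np.ndarray, baseline_segments,
                         band, fs: float, t0_s: float, tf_s: float,
                         channel: str = "") -> BandPowerStat:
    """Percentage band-power change of a task epoch vs N baseline segments.

    ``task_epoch`` is the signal over the analysis window [t0, tf] (with
    2 <= t0 < tf <= 7 in the cue-locked convention); ``baseline_segments``
    are N pre-cue segments of the same duration whose band powers are
    averaged to form the reference.
    """
    if not (2.0 - 1e-9 <= t0_s < tf_s <= 7.0 + 1e-9):
        raise ConfigurationError(
            f"analysis window must satisfy 2 <= t0 < tf <= 7, got "
            f"({t0_s}, {tf_s})")
    segments = list(baseline_segments)
    if not segments:
        raise DataError("need at least one baseline segment")
    band = get_band(band)
    bp_mi = band_power(task_epoch, fs, band)
    bp_base = float(np.mean([band_power(s, fs, band) for s in segments]))
    if bp_base <= 0:
        raise DataError("zero baseline band power (degenerate input)")
    y = 100.0 * (bp_mi - bp_base) / bp_base
    return BandPowerStat(y=y, band=band, channel=channel, t0_s=t0_s,
                         tf_s=tf_s, bp_mi=bp_mi, bp_baseline_mean=bp_base,
                         n_baseline=len(segments))


def _morlet_n_cycles(freqs: np.ndarray) -> np.ndarray:
    # 3 cycles at 9.5 Hz (mu-bin midpoint) rising linearly to 7 at 30 Hz
    # (high-beta midpoint); clipped below at 2.
    return np.clip(3.0 + 4.0 * (freqs - 9.5) / (30.0 - 9.5), 2.0, None)


def _bin_freq_grid(bins) -> tuple[np.ndarray, list[np.ndarray]]:
    freqs, owners = [], []
    for b in bins:
        grid = np.linspace(b.lo_hz + 0.5, b.hi_hz - 0.5, 4)
        owners.append(np.arange(len(freqs), len(freqs) + len(grid)))
        freqs.extend(grid)
    return np.array(freqs), owners


def _resample_columns(arr: np.ndarray, n_out: int) -> np.ndarray:
    """Average the last axis into ``n_out`` equal-width time blocks."""
    n_in = arr.shape[-1]
    edges = np.floor(np.linspace(0, n_in, n_out + 1)).astype(int)
    out = np.empty(arr.shape[:-1] + (n_out,))
    for j in range(n_out):
        out[..., j] = arr[..., edges[j]:max(edges[j + 1], edges[j] + 1)].mean(axis=-1)
    return out


def tf_map(epochs: Epochs, channel: str, class_label: str,
           n_times: int = 100, bins=PRIMARY_BINS,
           itv: bool = True) -> TFMap:
    """Time-frequency map of percentage power change for one channel/class.

    Per trial, complex Morlet wavelet energy is averaged within each
    frequency bin and resampled to ``n_times`` columns; the trial average
    is expressed as percentage change from the per-bin baseline-window
    mean. Call :func:`bootstrap_significance` to populate the significance
    mask.
    """
    from mne.time_frequency import tfr_array_morlet

    ep = itv_transform(epochs, class_label) if itv else epochs
    ci = ep.channel_index(channel)
    data = ep.data[:, ci:ci + 1, :]
    freqs, owners = _bin_freq_grid(bins)
    # Reflection-pad before the transform: the convolution otherwise
    # zero-pads, biasing wavelet energy low near the epoch edges.
    pad = int(round(0.5 * ep.fs))
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(padded, sfreq=ep.fs, freqs=freqs,
                             n_cycles=_morlet_n_cycles(freqs),
                             output="power", zero_mean=True)
    power = power[:, 0, :, pad:-pad]  # (trials, freqs, times)
    binned = np.stack([power[:, idx, :].mean(axis=1) for idx in owners],
                      axis=1)  # (trials, bins, times)
    trial_power = _resample_columns(binned, n_times)
    times = _resample_columns(ep.times_s[None, :], n_times)[0]
    base_mask = ((times >= ep.baseline_window_s[0]) &
                 (times < ep.baseline_window_s[1]))
    mean_power = trial_power.mean(axis=0)  # (bins, times)
    baseline_mean = mean_power[:, base_mask].mean(axis=1)
    if np.any(baseline_mean <= 0):
        raise DataError("zero baseline power in a frequency bin")
    values = 100.0 * (mean_power - baseline_mean[:, None]) / baseline_mean[:, None]
    return TFMap(values=values, times_s=times, bins=tuple(bins),
                 channel=channel, class_label=class_label,
                 trial_power=trial_power, baseline_mean=baseline_mean,
                 baseline_window_s=ep.baseline_window_s)


def bootstrap_significance(tfmap: TFMap, n_boot: int = 200,
                           alpha: float = 0.05, seed: int = 0) -> TFMap:
    """Mark map pixels outside the surrogate-baseline percentile interval.

    The surrogate distribution is built exactly as the map statistic, but
    with the task structure destroyed: for each of ``n_boot`` resamples,
    every trial contributes its binned spectral estimate at one random
    latency drawn from its own baseline window; the across-trial average
    forms one surrogate value per bin. Pixels whose percentage change lies
    outside the two-sided [alpha/2, 1 - alpha/2] surrogate percentiles are
    flagged significant.
    """
    if n_boot < 20:
        raise ConfigurationError("n_boot must be at least 20")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if tfmap.trial_power is None:
        raise DataError("TFMap lacks per-trial power; recompute with tf_map")
    rng = np.random.default_rng(seed)
    base_cols = np.flatnonzero(
        (tfmap.times_s >= tfmap.baseline_window_s[0]) &
        (tfmap.times_s < tfmap.baseline_window_s[1]))
    if base_cols.size == 0:
        raise DataError("empty baseline window")
    n_trials = tfmap.trial_power.shape[0]
    picks = rng.choice(base_cols, size=(n_boot, n_trials))
    trial_idx = np.arange(n_trials)
    # surrogate (n_boot, bins): trial-average of one random baseline column
    surrogate = tfmap.trial_power[trial_idx[None, :, None],
                                  np.arange(len(tfmap.bins))[None, None, :],
                                  picks[:, :, None]].mean(axis=1)
    surrogate_pct = 100.0 * (surrogate - tfmap.baseline_mean[None, :]) \
        / tfmap.baseline_mean[None, :]
    # Order-statistic percentile selection ("lower"/"higher") keeps the
    # per-tail exceedance at alpha/2 with a finite surrogate count; linear
    # interpolation would be anti-conservative at n_boot = 200.
    lo = np.percentile(surrogate_pct, 100 * alpha / 2, axis=0,
                       method="lower")
    hi = np.percentile(surrogate_pct, 100 * (1 - alpha / 2), axis=0,
                       method="higher")
    tfmap.sig_mask = ((tfmap.values < lo[:, None]) |
                      (tfmap.values > hi[:, None]))
    tfmap.alpha = alpha
    tfmap.n_boot = n_boot
    return tfmap


def erds_time_course(epochs: Epochs, channel: str, band, class_label: str,
                     smooth_s: float = 0.25, itv: bool = True) -> ERDSCurve:
    """Percentage power change versus time (classic band-power envelope).

    Trials of the class are (optionally) ITV-transformed, band-filtered,
    squared, smoothed with a moving average, averaged over trials, and
    normalized so the baseline-window mean is zero.
    """
    band = get_band(band)
    ep = itv_transform(epochs, class_label) if itv else epochs
    ci = ep.channel_index(channel)
    x = ep.data[:, ci, :]
    numtaps = max(int(round(3.3 * ep.fs / 2.0)) | 1, 3)
    taps = signal.firwin(numtaps, [band.lo_hz, band.hi_hz], pass_zero=False,
                         fs=ep.fs, window="hamming")
    filtered = signal.filtfilt(taps, [1.0], x, axis=1)
    inst_power = filtered ** 2
    win = max(int(round(smooth_s * ep.fs)), 1)
    kernel = np.ones(win) / win
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, inst_power)
    mean_curve = smoothed.mean(axis=0)
    base_mask = ((ep.times_s >= ep.baseline_window_s[0]) &
                 (ep.times_s < ep.baseline_window_s[1]))
    base = mean_curve[base_mask].mean()
    if base <= 0:
        raise DataError("zero baseline power in time course")
    values = 100.0 * (mean_curve - base) / base
    sem = (100.0 / base) * smoothed.std(axis=0, ddof=1) / np.sqrt(len(smoothed))
    return ERDSCurve(values=values, times_s=ep.times_s.copy(), band=band,
                     channel=channel, class_label=class_label, sem=sem)


#: Feature names recognised by peak_latency, with extremum polarity.
PEAK_FEATURES = {"mu_erd": "min", "beta_erd": "min", "beta_ers": "max"}


def peak_latency(curve: ERDSCurve, feature: str,
                 smooth_s: float = 0.25, flat_eps_pct: float = 5.0,
                 ers_window_start_s: float = 2.0) -> PeakLatency | None:
    """Latency (from cue onset) of the smoothed curve's extremum.

    ERD features take the minimum over [0 s, curve end]; the post-imagery
    beta rebound (``beta_ers``) takes the maximum over
    [``ers_window_start_s``, curve end]. A curve whose range inside the
    search window is below ``flat_eps_pct`` yields ``None`` (no peak).
    """
    if feature not in PEAK_FEATURES:
        raise ConfigurationError(f"unknown peak feature {feature!r}")
    polarity = PEAK_FEATURES[feature]
    fs = 1.0 / np.median(np.diff(curve.times_s))
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win
    smoothed = np.convolve(curve.values, kernel, mode="same")
    start = ers_window_start_s if feature == "beta_ers" else 0.0
    mask = curve.times_s >= start
    if not mask.any():
        raise DataError("curve does not cover the search window")
    seg = smoothed[mask]
    if seg.max() - seg.min() < flat_eps_pct:
        return None
    idx = np.argmin(seg) if polarity == "min" else np.argmax(seg)
    return PeakLatency(latency_s=float(curve.times_s[mask][idx]),
                       feature=feature, polarity=polarity,
                       value_pct=float(seg[idx]))


def topography_values(epochs: Epochs, band, window_s, class_label: str,
                      n_baseline: int | None = None,
                      itv: bool = True) -> dict[str, float]:
    """Per-channel percentage band-power change over a task window.

    Returns a channel -> value mapping suitable for export to any
    topographic plotting tool. The baseline reference per channel is the
    mean band power over the class trials' pre-cue segments of matching
    duration (the last ``tf - t0`` seconds before the cue).
    """
    t0, tf = window_s
    if t0 < epochs.times_s[0] or tf > epochs.times_s[-1] + 1.0 / epochs.fs:
        raise ConfigurationError("analysis window lies outside the epoch")
    band = get_band(band)
    ep = itv_transform(epochs, class_label) if itv else epochs
    task_mask = ep.time_mask(t0, tf)
    base_mask = ep.time_mask(ep.baseline_window_s[1] - (tf - t0),
                             ep.baseline_window_s[1])
    n_base = len(ep.data) if n_baseline is None else min(n_baseline, len(ep.data))
    out = {}
    for ci, ch in enumerate(ep.channel_names):
        task_bp = float(np.mean([band_power(trial[ci, task_mask], ep.fs, band)
                                 for trial in ep.data]))
        base_bp = float(np.mean([band_power(trial[ci, base_mask], ep.fs, band)
                                 for trial in ep.data[:n_base]]))
        if base_bp <= 0:
            raise DataError(f"zero baseline power at channel {ch}")
        out[ch] = 100.0 * (task_bp - base_bp) / base_bp
    return out
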