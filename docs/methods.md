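# Methods

## Analysis model

The pipeline assumes cue-locked trials with a pre-cue fixation baseline
(−3–0 s), a 2 s visual cue at t = 0, and an imagery window ending at t = 7 s,
recorded from a 10–20 montage at 256 Hz. All ERD/ERS quantities are ratio
statistics: a task-window band power divided by the mean band power of
equally long pre-cue segments, expressed as a percentage change. Ratio
statistics make the analysis invariant to global amplitude rescaling
(amplifier gain, unit changes), which the test suite asserts.

Stages, in execution order:

1. **Re-referencing.** Common average (subtract the instantaneous
   cross-channel mean; idempotent, zero-sum output) or transverse bipolar
   derivations (anode − cathode; defaults C3-Cz and Cz-C4). Both are linear,
   so they commute with filtering and epoching.
2. **Band-pass 7–35 Hz.** Windowed-sinc FIR (Hamming), order chosen so the
   transition band is ≈ 2 Hz (423 taps at 256 Hz), applied
   forward–backward. Zero-phase filtering is used because any group delay
   would bias the peak-latency estimates; the doubled attenuation is
   harmless here.
3. **Epoching** at −3–7 s around each cue. Trials overlapping a recording
   edge are dropped with a logged count rather than zero-padded, since
   padding would bias baseline power.
4. **Artifact removal** is pluggable: `none` (default in tests, since the
   generator can simply be run without artifacts), `regression` on a
   designated frontal channel, or `ica-template` (FastICA; components whose
   mixing column correlates with a frontal blink topography above a
   threshold, default 0.8, are dropped). ICA runs on the epoched data; the
   threshold and template are configuration, not fixed science.
5. **ITV transform.** Per class, the trial-average evoked potential is
   subtracted from each trial before any power estimate, so the statistics
   capture induced activity. The squaring lives in the power estimators;
   the transform itself only centres (its across-trial mean is exactly 0).
6. **Band power.** Welch PSD (1 s Hann segments, 50% overlap; a single
   full-length segment for shorter windows) integrated over the band by the
   trapezoid rule. Windows shorter than two cycles of the band's lower edge
   are rejected.
7. **Percentage power change.** Eq. above with N baseline segments; the
   baseline segment of each trial is the final (t_f − t₀) seconds before
   the cue, so task and baseline durations always match while staying
   maximally pre-cue (the 3 s baseline cannot host every admissible task
   window at its native latency). N defaults to 20 per class.
8. **Time–frequency maps.** Complex Morlet wavelets at four frequencies per
   bin (mu 7–12, low beta 13–24, high beta 25–35 Hz), cycles rising
   linearly from 3 at 9.5 Hz to 7 at 30 Hz (clipped below at 2), trial
   energy averaged per bin and block-averaged to 100 time columns. Epochs
   are reflection-padded by 0.5 s before the transform because zero padding
   depresses energy near the epoch edges.
9. **Bootstrap significance.** For each of 200 resamples, every trial
   contributes its binned estimate at one uniformly random baseline column;
   the across-trial averages form the surrogate distribution, and map
   pixels outside its two-sided [α/2, 1−α/2] percentiles are flagged. The
   percentiles use order-statistic selection (`lower`/`higher`) rather than
   interpolation: with 200 resamples, interpolated quantiles are
   anti-conservative by about a point per tail. The procedure is a
   percentile surrogate test; no studentization is applied. Measured type-I
   rate on stationary-noise sessions is ≈ 6–7% at α = 5% — the small excess
   is inherent to the surrogate's reuse of the baseline that also defines
   the normalization, and is within the tolerance the tests assert.
10. **Time courses and peak latencies.** Band-filtered, squared, 250 ms
    moving-average power per trial, trial-averaged and normalized to zero
    baseline mean. Peak latency takes the smoothed extremum: minimum over
    [0 s, epoch end] for ERD features, maximum over [2 s, epoch end] for
    the beta rebound (reported rebound latencies fall inside the imagery
    period when measured from cue onset). A curve whose range is below 5
    percentage points yields "no peak" instead of a spurious latency.
11. **Features and classification.** Per-trial percentage power changes at
    C3/Cz/C4 (or the two bipolar channels): mu ERD in 2–5 s, beta ERD in
    the low-beta bin in 2–4 s, beta ERS in the high-beta bin in 3–4.5 s.
    These windows bracket where each phenomenon is expressed; all satisfy
    the 2 ≤ t₀ < t_f ≤ 7 constraint. Classifiers: LDA (pooled covariance,
    SVD solver), linear SVM with C = 10, and weighted KNN with k = 10,
    Euclidean metric and squared-inverse-distance votes. A zero distance
    receives weight 1/ε² (ε = √machine-epsilon) and exact vote ties go to
    the nearest neighbour's class. Stratified 5-fold cross-validation is
    repeated over 30 seeded shuffles; standardization (z-scoring) is
    fitted on the training fold only; zero-variance columns are centred
    with a warning. The reported SD is taken across the 30 randomization
    means (stabler than fold-level SD and the interpretation documented
    here). AUC per randomization comes from pooled out-of-fold scores (LDA
    discriminant, SVM margin, KNN vote fraction); the choice of score is a
    design decision, since any strictly monotone transform leaves AUC
    unchanged.
12. **Multiplicity.** Left-vs-right feature tests use the pooled-variance
    two-sample t-test (a Welch flag exists) with a Bonferroni threshold
    α/c, c = 3 comparisons per channel scheme; thresholds are reported at
    3 decimals (0.05/3 → 0.017). Model comparisons use paired t-tests
    across participants pooled into N = features × references × 3 pairs
    hypotheses and corrected with the Benjamini–Hochberg step-up rule at
    q = 0.05; the implementation is checked against a brute-force step-up
    oracle and against statsmodels.
13. **Chance level.** The two-class bound is the (1−α) binomial quantile at
    success probability ½ divided by the trial count (47/80 = 58.75% at
    α = 0.05). The widely cited 57.5%/60.0% constants for 80 trials come
    from a published reference table whose exact derivation is not
    reproducible from a formula; they are carried as reporting references
    next to, never instead of, the computed bound.

## Synthetic data generator

Each oscillatory source is white noise band-filtered to its band (Hamming
FIR, 2 Hz transition) and unit-RMS normalized — not a sinusoid — so PSD
estimates of the output have EEG-like variability. Inside a per-trial
active window (jittered by Gaussian latency noise) the source amplitude is
multiplied by `erd_scale` times a class-conditional lateral gain; a scale s
yields an expected power change of (s² − 1)·100%, which the tests verify to
within 5 points at 80 trials/class against a brute-force periodogram
oracle. Two envelope shapes exist: `plateau` (raised-cosine ramps, flat
middle — calibrated power change) and `hann` (single bump — well-defined
peak latency). Background noise is 1/f (exponent 1) at 10 µV RMS per
channel, independent across channels; optional blinks are a Poisson train
of 0.3 s bumps projected onto the frontal channels.

Default effect battery (the conditions under which the acceptance run and
the end-to-end tests operate): mu ERD (scale 0.55, 0.5–5 s) and low-beta
ERD (scale 0.6, 0.3–4 s) at C3/Cz/C4 with mild contralateral gain
asymmetry (±15% and ±10%), and a dominant high-beta rebound (scale 1.9,
Hann bump over 2.9–4.1 s, ±25% asymmetry, 8 and 5 µV source amplitudes).
The rebound is placed inside the imagery window, peaking near 3.5 s from
cue onset, matching where reported group-mean rebound latencies fall; its
≈1.2 s duration matches the described one-second burst. The convention is
contralateral dominance: the hemisphere opposite the imagined foot shows
the deeper ERD and the stronger rebound, with the asymmetry largest for
the rebound — hence the beta-ERS feature classifies best, and accuracy
ordering beta-ERS ≥ beta-ERD, mu-ERD emerges on average.

Trial counts default to 80 per class (four sessions of 20, as in the
emulated protocol); a published trial-count figure of 95/class is
internally inconsistent with that protocol and with 5-fold arithmetic, so
the generator exposes `n_trials_per_class` instead of guessing.

What the generator does **not** emulate: volume conduction through a head
model (spatial spread is a fixed mixing fraction into the transverse
neighbours C3↔Cz↔C4 only — the minimum structure that makes common-average
vs bipolar comparisons meaningful), non-stationary background rhythms,
electrode drift or impedance artifacts, and real ocular/EMG waveforms.
Passing tests therefore demonstrate that the analysis recovers known
ground truth under EEG-like spectra and trial structure, not that it is
robust to every artifact of real recordings.

## Problem sizes

The test suite uses reduced-size sessions (20 trials/class, a 3-channel
sensorimotor montage) wherever the property under test does not depend on
the full design, and full-size sessions (80 trials/class, 19 channels) for
the calibration and end-to-end discrimination checks. The acceptance
script runs ten full-size sessions. These sizes are the package's chosen
study conditions and keep a complete run in the low minutes on one core.

## Known limitations

- The ICA blink rejection is template-correlation based; it does not
  reproduce any particular toolbox's manual "reject by map" decisions.
- The surrogate significance test is slightly anti-conservative (see
  above); a studentized variant is not implemented because the emulated
  procedure is a percentile method.
- Latency tables use one representative channel per reference (Cz for
  common average, Cz-C4 for bipolar); per-channel latency extraction is
  available through the library API.
- EDF reading maps annotations to events by an explicit label map; EDF
  export is not implemented (the fixture format plus reader covers
  round-tripping).
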