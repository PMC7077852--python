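"""Study orchestration, file I/O, and table aggregation.

Runs the full analysis — reference conversion (common average and
transverse bipolar), 7-35 Hz band-pass, cue-locked epoching, per-trial
band-power features for the three sensorimotor phenomena (mu ERD, beta
ERD, post-imagery beta ERS), repeated cross-validated classification with
LDA / linear SVM / weighted KNN — over a cohort of sessions, and
aggregates the results into the study's table layouts (peak latencies,
accuracies with AUC, left-vs-right test statistics, and FDR-corrected
model comparisons).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import classify, erds, preprocess, stats, synthgen
from .exceptions import ConfigurationError, DataError
from .synthgen import MontageSpec, NoiseSpec, Recording, TrialSchedule

logger = logging.getLogger(__name__)

#: Feature definitions: analysis band and task window (seconds from cue).
#: mu ERD spans the imagery window; beta ERD is taken in the low-beta bin
#: during cue + early imagery; the beta rebound (ERS) is taken in the
#: high-beta bin around its post-movement burst.
FEATURE_DEFS = {
    "mu_erd": ("mu", (2.0, 5.0)),
    "beta_erd": ("low_beta", (2.0, 4.0)),
    "beta_ers": ("high_beta", (3.0, 4.5)),
}

#: Band used for the ERD/ERS time course of each feature.
FEATURE_CURVE_BANDS = {"mu_erd": "mu", "beta_erd": "low_beta",
                       "beta_ers": "high_beta"}

REFERENCE_CHANNELS = {
    "car": ("C3", "Cz", "C4"),
    "bipolar": ("C3-Cz", "Cz-C4"),
}

#: Representative channel for latency curves, per reference.
LATENCY_CHANNEL = {"car": "Cz", "bipolar": "Cz-C4"}

MODEL_SPECS = {
    "lda": classify.ModelSpec("lda"),
    "linear_svm": classify.ModelSpec("linear_svm"),
    "weighted_knn": classify.ModelSpec("weighted_knn"),
}

MODEL_PAIRS = (("lda", "linear_svm"), ("lda", "weighted_knn"),
               ("weighted_knn", "linear_svm"))


@dataclass
class StudyConfig:
    references: tuple[str, ...] = ("car", "bipolar")
    bipolar_pairs: tuple = preprocess.DEFAULT_BIPOLAR_PAIRS
    features: tuple[str, ...] = ("mu_erd", "beta_erd", "beta_ers")
    models: tuple[str, ...] = ("lda", "linear_svm", "weighted_knn")
    n_participants: int = 9
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    effects: list | None = None          # None -> generator defaults
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    montage: MontageSpec = field(default_factory=MontageSpec)
    filter_spec: preprocess.FilterSpec = field(
        default_factory=preprocess.FilterSpec)
    epoch_window_s: tuple[float, float] = (-3.0, 7.0)
    artifact_method: str = "none"
    n_baseline: int = 20
    k_folds: int = 5
    n_randomizations: int = 30
    fdr_q: float = 0.05
    bonferroni_alpha: float = 0.05
    seed: int = 0
    compute_latencies: bool = True

    def __post_init__(self):
        if not self.references or not self.features or not self.models:
            raise ConfigurationError(
                "need at least one reference, feature, and model")
        for ref in self.references:
            if ref not in REFERENCE_CHANNELS:
                raise ConfigurationError(f"unknown reference {ref!r}")
        for feat in self.features:
            if feat not in FEATURE_DEFS:
                raise ConfigurationError(f"unknown feature {feat!r}")
        for model in self.models:
            if model not in MODEL_SPECS:
                raise ConfigurationError(f"unknown model {model!r}")


@dataclass
class StudyResults:
    latency_table: pd.DataFrame
    accuracy_table: pd.DataFrame
    comparison_table: pd.DataFrame
    model_comparison: pd.DataFrame
    provenance: dict


def _canonical_channel(name: str) -> str:
    upper = name.strip().upper()
    for ch in synthgen.CHANNELS_1020:
        if ch.upper() == upper:
            return ch
    return name.strip()


def read_recording(path, label_map=None) -> Recording:
    """Read a recording from the fixture format or an EDF file.

    ``path`` may be a fixture directory, a fixture JSON sidecar, or an EDF
    file. EDF annotations are mapped to left/right cue events through
    ``label_map`` (annotation description -> class label); unmapped
    annotations are ignored.
    """
    path = pathlib.Path(path)
    if path.is_dir():
        path = path / "recording.json"
    if path.suffix == ".json":
        return _read_fixture(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, label_map)
    raise ConfigurationError(f"unknown recording format: {path}")


def _read_fixture(sidecar_path: pathlib.Path) -> Recording:
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read fixture sidecar {sidecar_path}: {exc}")
    raw_path = sidecar_path.with_name("recording.f32")
    data = np.fromfile(raw_path, dtype=sidecar.get("dtype", "<f4"))
    n_ch, n_samp = sidecar["n_channels"], sidecar["n_samples"]
    if data.size != n_ch * n_samp:
        raise DataError(f"raw file size mismatch in {raw_path}")
    data = data.reshape(n_ch, n_samp).astype(np.float64)
    events = [(e["sample"], e["label"]) for e in sidecar["events"]]
    if not events:
        logger.warning("fixture %s contains no events", sidecar_path)
    montage = MontageSpec(tuple(sidecar["channel_names"]),
                          {k: tuple(v) for k, v in sidecar["positions"].items()})
    return Recording(data=data, fs=float(sidecar["fs"]), montage=montage,
                     events=events,
                     reference_tag=sidecar.get("reference_tag",
                                               "linked-earlobe-raw"),
                     channel_names=tuple(sidecar["channel_names"]),
                     meta=sidecar.get("meta", {}))


def _read_edf(path: pathlib.Path, label_map) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise DataError(f"cannot read EDF file {path}: {exc}") from exc
    names = tuple(_canonical_channel(ch) for ch in raw.ch_names)
    positions = {}
    for ch in names:
        positions[ch] = synthgen.POSITIONS_1020.get(ch, (0.0, 0.0))
    data = raw.get_data() * 1e6  # volts -> microvolts
    events: list[tuple[int, str]] = []
    label_map = label_map or {}
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in label_map:
            events.append((int(round(onset * raw.info["sfreq"])),
                           label_map[desc]))
    events.sort(key=lambda e: e[0])
    if not events:
        logger.warning("EDF %s yielded no mapped events", path)
    montage = MontageSpec(names, positions)
    return Recording(data=data, fs=float(raw.info["sfreq"]), montage=montage,
                     events=events, channel_names=names)


def _referenced(recording: Recording, reference: str,
                pairs) -> Recording:
    if reference == "car":
        return preprocess.common_average(recording)
    return preprocess.bipolar(recording, pairs)


def analyse_session(recording: Recording, config: StudyConfig,
                    participant: str) -> dict:
    """Analyse one session: features, CV accuracies, latencies, t-tests."""
    filtered = preprocess.bandpass(recording, config.filter_spec)
    rows_acc, rows_lat, rows_cmp = [], [], []
    for reference in config.references:
        ref_rec = _referenced(filtered, reference, config.bipolar_pairs)
        epochs = preprocess.epoch(ref_rec, *config.epoch_window_s)
        if config.artifact_method != "none":
            epochs, _ = preprocess.remove_artifacts(
                epochs, method=config.artifact_method)
        channels = REFERENCE_CHANNELS[reference]
        for feature in config.features:
            band, window = FEATURE_DEFS[feature]
            table = classify.assemble_features(
                epochs, channels, [band], [window],
                n_baseline=config.n_baseline)
            # left-vs-right test statistic per channel (pooled features)
            for ci, ch in enumerate(channels):
                left = table.features[table.labels == "left", ci]
                right = table.features[table.labels == "right", ci]
                res = stats.ttest_two_sample(left, right, feature=feature,
                                             channel=ch)
                rows_cmp.append({
                    "participant": participant, "reference": reference,
                    "feature": feature, "channel": ch,
                    "t": res.t_value, "p": res.p_value, "df": res.df})
            for model in config.models:
                cv = classify.CVConfig(
                    k_folds=config.k_folds,
                    n_randomizations=config.n_randomizations,
                    seed=config.seed)
                result = classify.cross_validate(table, MODEL_SPECS[model],
                                                 cv)
                rows_acc.append({
                    "participant": participant, "reference": reference,
                    "feature": feature, "model": model,
                    "acc_pct": result.mean_accuracy_pct,
                    "sd_pct": result.sd_accuracy_pct,
                    "auc_pct": result.auc_pct})
            if config.compute_latencies:
                channel = LATENCY_CHANNEL[reference]
                for class_label in synthgen.LABELS:
                    curve = erds.erds_time_course(
                        epochs, channel, FEATURE_CURVE_BANDS[feature],
                        class_label)
                    peak = erds.peak_latency(curve, feature)
                    rows_lat.append({
                        "participant": participant, "reference": reference,
                        "feature": feature, "class": class_label,
                        "latency_s": np.nan if peak is None
                        else peak.latency_s})
    return {"accuracy": rows_acc, "latency": rows_lat,
            "comparisons": rows_cmp}


def run_study(config: StudyConfig | None = None,
              recordings: list[Recording] | None = None) -> StudyResults:
    """Execute the full study over a cohort and aggregate the tables.

    ``recordings`` supplies one session per participant; when omitted,
    sessions are generated synthetically with the configured (or default)
    effect battery, one seeded session per participant. Output is a pure
    function of (config, seeds).
    """
    config = config or StudyConfig()
    if recordings is None:
        rng = np.random.default_rng(config.seed)
        session_seeds = rng.integers(0, 2 ** 31 - 1,
                                     size=config.n_participants)
        recordings = [
            synthgen.generate_session(
                schedule=config.schedule, effects=config.effects,
                noise=config.noise, montage=config.montage, seed=int(s))
            for s in session_seeds]
    rows_acc, rows_lat, rows_cmp = [], [], []
    for p, recording in enumerate(recordings, start=1):
        participant = f"P{p}"
        logger.info("analysing session %s", participant)
        out = analyse_session(recording, config, participant)
        rows_acc.extend(out["accuracy"])
        rows_lat.extend(out["latency"])
        rows_cmp.extend(out["comparisons"])

    accuracy = pd.DataFrame(rows_acc)
    latency = pd.DataFrame(rows_lat)
    comparisons = pd.DataFrame(rows_cmp)
    if not comparisons.empty:
        corr = stats.bonferroni(config.bonferroni_alpha, 3)
        comparisons["bonferroni_threshold"] = corr.thresholds_rounded[0]
        comparisons["significant"] = (
            comparisons["p"] < config.bonferroni_alpha / 3)
    model_cmp = (compare_models(accuracy, q=config.fdr_q)
                 if len(recordings) >= 2 and len(config.models) >= 2
                 else pd.DataFrame())
    provenance = {
        "config": _config_dict(config),
        "n_participants": len(recordings),
        "package": "erdskit",
    }
    return StudyResults(latency_table=latency, accuracy_table=accuracy,
                        comparison_table=comparisons,
                        model_comparison=model_cmp, provenance=provenance)


def _config_dict(config: StudyConfig) -> dict:
    out = dataclasses.asdict(config)
    out["bipolar_pairs"] = [p.name for p in config.bipolar_pairs]
    return synthgen._jsonable(out)


def summarize_latencies(table: pd.DataFrame) -> pd.DataFrame:
    """Append Mean and S.D. rows (2-decimal, sample SD) to a latency table.

    ``table`` has one row per participant and one numeric column per
    (feature, reference, class) combination.
    """
    return _summarize(table, decimals=2)


def summarize_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Append Mean and S.D. rows (1-decimal) to an accuracy/AUC table."""
    return _summarize(table, decimals=1)


def _summarize(table: pd.DataFrame, decimals: int) -> pd.DataFrame:
    numeric = table.select_dtypes("number")
    if len(numeric) < 2:
        raise DataError("need at least 2 participants to summarize")
    mean_row, sd_row = {}, {}
    for col in table.columns:
        if col in numeric.columns:
            vals = numeric[col].dropna()
            if vals.empty:
                logger.warning("column %r is empty; leaving summary blank",
                               col)
                mean_row[col] = np.nan
                sd_row[col] = np.nan
                continue
            mean_row[col] = round(float(vals.mean()), decimals)
            sd_row[col] = round(float(vals.std(ddof=1)), decimals)
        else:
            mean_row[col] = "Mean"
            sd_row[col] = "S.D."
    out = pd.concat([table, pd.DataFrame([mean_row, sd_row])],
                    ignore_index=True)
    return out


def compare_models(accuracy_table: pd.DataFrame,
                   q: float = 0.05) -> pd.DataFrame:
    """Pairwise model comparison with Benjamini-Hochberg FDR control.

    For every (feature, reference) cell and every model pair, a paired
    t-test across participants compares the accuracy columns; the pooled
    hypotheses (3 features x 2 references x 3 pairs = 18 with the default
    design) are corrected with the step-up rule at level ``q``.
    """
    rows = []
    for (feature, reference), group in accuracy_table.groupby(
            ["feature", "reference"], sort=True):
        pivot = group.pivot(index="participant", columns="model",
                            values="acc_pct")
        for a, b in MODEL_PAIRS:
            if a not in pivot.columns or b not in pivot.columns:
                continue
            paired = pivot[[a, b]].dropna()
            if paired[a].shape != paired[b].shape or paired.isna().any().any():
                raise DataError("mismatched participant sets for "
                                f"{a} vs {b} at {feature}/{reference}")
            if np.allclose(paired[a], paired[b]):
                t_val, p_val = 0.0, 1.0
            else:
                t_val, p_val = sps.ttest_rel(paired[a], paired[b])
            rows.append({"feature": feature, "reference": reference,
                         "pair": f"{a}-{b}", "t": float(t_val),
                         "p": float(p_val)})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    corr = stats.bh_fdr(df["p"].to_numpy(), q=q)
    df["critical_value"] = corr.thresholds_rounded
    df["rejected"] = corr.rejected
    return df


def write_results(results: StudyResults, out_dir) -> dict[str, pathlib.Path]:
    """Write all tables as CSV plus a JSON provenance sidecar."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("latency", results.latency_table),
                     ("accuracy", results.accuracy_table),
                     ("comparisons", results.comparison_table),
                     ("model_comparison", results.model_comparison)):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(results.provenance, indent=1,
                                    sort_keys=True))
    paths["provenance"] = prov_path
    return paths
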