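"""Band-power feature tables and repeated cross-validated classification.

Per-trial percentage band-power changes (one column per channel/band/
window) feed three classifiers — LDA, a linear soft-margin SVM (C = 10),
and a distance-weighted KNN (k = 10, Euclidean metric, squared-inverse
weights) — evaluated with stratified 5-fold cross-validation repeated over
30 seeded shuffles. Feature standardization is fitted on each training
fold only and applied unchanged to the held-out fold, so no test
information leaks into the scaler or the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .erds import BandPowerStat, get_band, percent_power_change
from .exceptions import ConfigurationError, DataError
from .preprocess import Epochs

logger = logging.getLogger(__name__)

#: The class treated as "positive" in decision scores and ROC analysis.
POSITIVE_LABEL = "right"


@dataclass
class FeatureTable:
    features: np.ndarray          # trials x d
    labels: np.ndarray            # per-trial class label
    feature_names: list[str]
    stats: list[list[BandPowerStat]] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise DataError("feature matrix must be trials x d with d >= 1")
        if len(self.labels) != len(self.features):
            raise DataError("labels length must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise DataError("feature matrix contains missing values")
        if len(np.unique(self.labels)) < 2:
            raise DataError("both classes must be present")


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    n_randomizations: int = 30
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.n_randomizations < 1:
            raise ConfigurationError("n_randomizations must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "lda"  # lda | linear_svm | weighted_knn
    svm_c: float = 10.0
    knn_k: int = 10
    knn_metric: str = "euclidean"
    knn_weight: str = "squared-inverse"

    def __post_init__(self):
        if self.kind not in ("lda", "linear_svm", "weighted_knn"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if self.svm_c <= 0:
            raise ConfigurationError("svm_c must be positive")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")


@dataclass
class CVResult:
    model: str
    fold_accuracies: np.ndarray       # (n_randomizations, k_folds), percent
    mean_accuracy_pct: float
    sd_accuracy_pct: float
    auc_pct: float
    randomization_means_pct: np.ndarray
    n_trials: int


def assemble_features(epochs: Epochs, channels, bands, windows_s,
                      n_baseline: int = 20) -> FeatureTable:
    """Build the trials x d table of percentage band-power changes.

    One row per trial, one column per (channel, band, window); the
    baseline reference of each trial is the mean band power over the
    pre-cue segments (matching window duration, anchored at the cue) of
    ``n_baseline`` same-class trials. Column order is channels outermost,
    then bands, then windows, recorded in ``feature_names``.
    """
    windows_s = [tuple(w) for w in np.atleast_2d(windows_s)]
    bands = [get_band(b) for b in np.atleast_1d(bands)]
    labels = epochs.labels
    columns = []
    names = []
    all_stats: list[list[BandPowerStat]] = [[] for _ in range(epochs.n_trials)]
    for ch in channels:
        ci = epochs.channel_index(ch)
        for band in bands:
            for (t0, tf) in windows_s:
                task_mask = epochs.time_mask(t0, tf)
                base_mask = epochs.time_mask(
                    epochs.baseline_window_s[1] - (tf - t0),
                    epochs.baseline_window_s[1])
                base_bp_per_label = {}
                for label in np.unique(labels):
                    idx = np.flatnonzero(labels == label)[:n_baseline]
                    base_bp_per_label[label] = [
                        epochs.data[i, ci, base_mask] for i in idx]
                col = np.empty(epochs.n_trials)
                for i in range(epochs.n_trials):
                    stat = percent_power_change(
                        epochs.data[i, ci, task_mask],
                        base_bp_per_label[labels[i]],
                        band, epochs.fs, t0, tf, channel=ch)
                    col[i] = stat.y
                    all_stats[i].append(stat)
                columns.append(col)
                names.append(f"{ch}:{band.name}:{t0:g}-{tf:g}s")
    return FeatureTable(features=np.column_stack(columns), labels=labels,
                        feature_names=names, stats=all_stats)


def standardize(train: np.ndarray, test: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Z-score features using training-fold mean/SD only."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(train) == 0:
        raise DataError("empty training set")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("zero-variance feature column(s) %s: centred only",
                       np.flatnonzero(zero_var).tolist())
    sd_safe = np.where(zero_var, 1.0, sd)
    return ((train - mean) / sd_safe, (test - mean) / sd_safe,
            {"mean": mean, "sd": sd})


def _knn_fit_predict(spec: ModelSpec, x_train, y_train, x_test):
    """Distance-weighted KNN with squared-inverse weights.

    A zero distance receives a large finite weight (1/eps^2); class-vote
    ties are broken toward the nearest neighbour's class.
    """
    if len(x_train) < spec.knn_k:
        raise DataError(
            f"training set smaller than knn_k={spec.knn_k}")
    eps = np.sqrt(np.finfo(float).eps)
    dists = cdist(x_test, x_train, metric=spec.knn_metric)
    scores = np.empty(len(x_test))
    preds = np.empty(len(x_test), dtype=object)
    pos = y_train == POSITIVE_LABEL
    for i in range(len(x_test)):
        nn = np.argsort(dists[i], kind="stable")[:spec.knn_k]
        w = 1.0 / np.maximum(dists[i][nn], eps) ** 2
        w_pos = w[pos[nn]].sum()
        frac = w_pos / w.sum()
        scores[i] = frac
        if frac > 0.5:
            preds[i] = POSITIVE_LABEL
        elif frac < 0.5:
            preds[i] = [l for l in np.unique(y_train)
                        if l != POSITIVE_LABEL][0]
        else:
            preds[i] = y_train[nn[0]]
    return preds.astype(y_train.dtype), scores


def fit_predict(spec: ModelSpec, x_train, y_train, x_test
                ) -> tuple[np.ndarray, np.ndarray]:
    """Fit one model on (standardized) training data; predict the test fold.

    Returns predicted labels and a continuous decision score per test
    trial (LDA discriminant value, SVM signed margin, or KNN weighted vote
    fraction for the positive class).
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise DataError("training fold must contain both classes")
    if spec.kind == "weighted_knn":
        return _knn_fit_predict(spec, np.asarray(x_train), y_train,
                                np.asarray(x_test))
    if spec.kind == "lda":
        model = LinearDiscriminantAnalysis(solver="svd")
    else:
        model = SVC(kernel="linear", C=spec.svm_c)
    model.fit(x_train, y_train)
    preds = model.predict(x_test)
    scores = model.decision_function(x_test)
    # decision_function is oriented toward classes_[1]; flip if needed so
    # larger scores always mean "more positive-class".
    if model.classes_[1] != POSITIVE_LABEL:
        scores = -scores
    return preds, scores


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as a fraction in [0, 1].

    Equals the probability that a random positive-class trial scores above
    a random negative-class trial (ties counted half).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels == POSITIVE_LABEL, scores))


def cross_validate(table: FeatureTable, model: ModelSpec,
                   cv: CVConfig) -> CVResult:
    """Repeated stratified k-fold cross-validation of one model.

    For each of ``n_randomizations`` seeded shuffles the trials are split
    into stratified folds; per fold the features are standardized on the
    training part, the model fitted, and the held-out fold scored. The
    grand mean accuracy pools all folds of all randomizations; the SD is
    taken over the randomization means; AUC is computed per randomization
    from the pooled out-of-fold scores, then averaged.
    """
    n = len(table.features)
    if n < 2 * cv.k_folds:
        raise DataError("need at least 2 trials per fold")
    rng = np.random.default_rng(cv.seed)
    fold_acc = np.empty((cv.n_randomizations, cv.k_folds))
    aucs = np.empty(cv.n_randomizations)
    for r in range(cv.n_randomizations):
        splitter = StratifiedKFold(
            n_splits=cv.k_folds, shuffle=True,
            random_state=int(rng.integers(2 ** 31 - 1)))
        oof_scores = np.empty(n)
        for f, (tr, te) in enumerate(
                splitter.split(table.features, table.labels)):
            x_tr, x_te, _ = standardize(table.features[tr],
                                        table.features[te])
            preds, scores = fit_predict(model, x_tr, table.labels[tr], x_te)
            fold_acc[r, f] = 100.0 * np.mean(preds == table.labels[te])
            oof_scores[te] = scores
        aucs[r] = 100.0 * roc_auc(oof_scores, table.labels)
    rand_means = fold_acc.mean(axis=1)
    return CVResult(model=model.kind, fold_accuracies=fold_acc,
                    mean_accuracy_pct=float(fold_acc.mean()),
                    sd_accuracy_pct=float(rand_means.std(ddof=1))
                    if cv.n_randomizations > 1 else 0.0,
                    auc_pct=float(aucs.mean()),
                    randomization_means_pct=rand_means, n_trials=n)
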