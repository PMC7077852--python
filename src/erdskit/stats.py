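"""Left-vs-right inference and multiple-comparison control.

Two-sample t-tests compare the left- and right-imagery feature groups;
family-wise error is controlled with the Bonferroni division (three
comparisons per channel scheme: one reference channel against the two
bipolar derivations), and model comparisons are controlled at the false
discovery rate with the Benjamini-Hochberg step-up rule. A binomial upper
confidence bound gives the chance level of a two-class classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError, DataError


@dataclass
class ComparisonResult:
    t_value: float
    p_value: float
    df: float
    group_sizes: tuple[int, int]
    feature: str = ""
    channel: str = ""


@dataclass
class CorrectionResult:
    method: str
    n_comparisons: int
    alpha: float
    thresholds: np.ndarray            # per-hypothesis critical value(s)
    rejected: np.ndarray | None = None
    p_values: np.ndarray | None = None
    notes: dict = field(default_factory=dict)

    @property
    def thresholds_rounded(self) -> np.ndarray:
        """Critical values at the 3-decimal reporting precision."""
        return np.round(self.thresholds, 3)


def ttest_two_sample(group_a, group_b, feature: str = "", channel: str = "",
                     welch: bool = False) -> ComparisonResult:
    """Two-sample t-test (pooled variance by default; Welch by flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else len(a) + len(b) - 2
    return ComparisonResult(t_value=float(res.statistic),
                            p_value=float(res.pvalue), df=df,
                            group_sizes=(len(a), len(b)),
                            feature=feature, channel=channel)


def bonferroni(alpha_pc: float, c: int,
               p_values=None) -> CorrectionResult:
    """Bonferroni correction: per-comparison threshold alpha_pc / c.

    With the study's scheme of c = 3 comparisons per channel at
    alpha_pc = 0.05 the threshold is 0.0167, reported as 0.017 at the
    3-decimal table precision.
    """
    if c < 1:
        raise ConfigurationError("number of comparisons c must be >= 1")
    if not 0 < alpha_pc < 1:
        raise ConfigurationError("alpha_pc must lie in (0, 1)")
    threshold = alpha_pc / c
    result = CorrectionResult(method="bonferroni", n_comparisons=c,
                              alpha=alpha_pc,
                              thresholds=np.full(c, threshold))
    if p_values is not None:
        p = np.asarray(p_values, dtype=float)
        result.p_values = p
        result.rejected = p < threshold
    return result


def bh_fdr(p_values, q: float = 0.05) -> CorrectionResult:
    """Benjamini-Hochberg step-up FDR control at level q.

    P-values are ranked ascending; the rank-i critical value is i*q/N. The
    largest rank k with P(k) <= k*q/N is found (scanning from the largest
    p-value down) and hypotheses of rank 1..k are rejected. The returned
    thresholds and rejection mask are in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ConfigurationError("q must lie in (0, 1)")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    crit = ranks * q / n
    sorted_p = p[order]
    sorted_crit = np.arange(1, n + 1) * q / n
    passing = np.flatnonzero(sorted_p <= sorted_crit)
    k = passing[-1] + 1 if passing.size else 0
    rejected = np.zeros(n, dtype=bool)
    rejected[order[:k]] = True
    return CorrectionResult(method="bh_fdr", n_comparisons=n, alpha=q,
                            thresholds=crit, rejected=rejected, p_values=p,
                            notes={"k": int(k)})


@dataclass
class ChanceLevel:
    n_trials: int
    n_classes: int
    alpha: float
    bound_fraction: float
    #: Published reference thresholds for n = 80, 2 classes (reporting only).
    paper_constant: dict = field(default_factory=lambda: {
        0.05: 0.575, 0.01: 0.600})


def chance_level(n_trials: int, n_classes: int = 2,
                 alpha: float = 0.05) -> ChanceLevel:
    """Upper confidence bound on a random classifier's accuracy.

    The bound is the (1 - alpha) quantile of Binomial(n_trials,
    1/n_classes) divided by n_trials: accuracies above it are unlikely to
    arise from guessing. The commonly cited 57.5% (p < 0.05) and 60.0%
    (p < 0.01) constants for 80 trials are carried alongside for reporting;
    they come from a published reference table rather than this formula.
    """
    if n_trials < 1 or n_classes < 2:
        raise ConfigurationError("need n_trials >= 1 and n_classes >= 2")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    k = sps.binom.ppf(1 - alpha, n_trials, 1.0 / n_classes)
    return ChanceLevel(n_trials=n_trials, n_classes=n_classes, alpha=alpha,
                       bound_fraction=float(k) / n_trials)
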