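"""Accuracy-ratio and image-level agreement statistics for two classifiers.

Two systems (an artificial classifier ``c`` and a human observer ``h``)
answer the same two-alternative question. Their accuracies at a matched
degradation level are compared as a ratio of proportions with the Katz log
method: the log ratio is approximately normal with

    SE(ln R) = sqrt(1/k_c - 1/n_c + 1/k_h - 1/n_h)

giving a 95% CI of exp(ln R +/- 1.96 SE) and a two-sided p-value from the
normal deviate ln(R)/SE. Image-level agreement is assessed against the
chance agreement implied by the two accuracies,

    E = a_c * a_h + (1 - a_c) * (1 - a_h),

as the ratio observed/expected; values above 1 mean the two systems err on
the *same* images more often than their accuracies alone predict. The
variance of ln(expected) is propagated from the two accuracy proportions by
the delta method. p-values are Bonferroni-corrected for the four matched
degradation levels by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CountPair",
    "RatioResult",
    "AgreementResult",
    "accuracy_ratio",
    "expected_agreement",
    "observed_agreement",
    "agreement_ratio",
    "bonferroni",
    "aggregate_predictions",
]

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CountPair:
    """Correct/total counts for the artificial (c) and human (h) systems."""

    k_c: float
    n_c: float
    k_h: float
    n_h: float

    def __post_init__(self) -> None:
        for k, n in ((self.k_c, self.n_c), (self.k_h, self.n_h)):
            if n <= 0:
                raise ValueError("totals must be positive")
            if not 0 <= k <= n:
                raise ValueError("correct counts must lie in [0, n]")

    @property
    def w_c(self) -> float:
        return self.n_c - self.k_c

    @property
    def w_h(self) -> float:
        return self.n_h - self.k_h


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    ci95: tuple[float, float]
    p_raw: float
    p_corrected: float
    m_comparisons: int


@dataclass(frozen=True)
class AgreementResult:
    observed: float
    expected: float
    ratio: float
    ci95: tuple[float, float]
    p_raw: float
    p_corrected: float
    m_comparisons: int


def _haldane(pair: CountPair) -> CountPair:
    """Add 0.5 to all four cells when any correct/wrong cell is empty."""
    cells = (pair.k_c, pair.w_c, pair.k_h, pair.w_h)
    if min(cells) > 0:
        return pair
    return CountPair(pair.k_c + 0.5, pair.n_c + 1.0,
                     pair.k_h + 0.5, pair.n_h + 1.0)


def _log_ratio_result(log_ratio: float, se: float, m: int) -> tuple:
    ci = (float(np.exp(log_ratio - Z95 * se)), float(np.exp(log_ratio + Z95 * se)))
    z = log_ratio / se if se > 0 else np.inf * np.sign(log_ratio)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if log_ratio == 0.0:
        p = 1.0
    return ci, p, float(min(1.0, m * p))


def accuracy_ratio(pair: CountPair, m_comparisons: int = 4) -> RatioResult:
    """Artificial-to-human accuracy ratio with Katz log-method inference.

    Ratio > 1 means the artificial classifier is more accurate. Zero cells
    get the Haldane-Anscombe +0.5 continuity correction before the log
    method is applied.
    """
    pair = _haldane(pair)
    ratio = (pair.k_c / pair.n_c) / (pair.k_h / pair.n_h)
    se = np.sqrt(1.0 / pair.k_c - 1.0 / pair.n_c
                 + 1.0 / pair.k_h - 1.0 / pair.n_h)
    ci, p, p_corr = _log_ratio_result(float(np.log(ratio)), float(se), m_comparisons)
    return RatioResult(float(ratio), ci, p, p_corr, m_comparisons)


def expected_agreement(pair: CountPair) -> float:
    """Chance image-level agreement implied by the two accuracies:
    accuracy product plus error product."""
    a_c, a_h = pair.k_c / pair.n_c, pair.k_h / pair.n_h
    return float(a_c * a_h + (1.0 - a_c) * (1.0 - a_h))


def observed_agreement(decisions_h, decisions_c) -> tuple[float, int]:
    """Fraction (and count) of stimuli on which the two decision vectors match.

    The two sequences must already be aligned by stimulus id and have equal
    length.
    """
    decisions_h = np.asarray(decisions_h)
    decisions_c = np.asarray(decisions_c)
    if decisions_h.shape != decisions_c.shape or decisions_h.ndim != 1:
        raise ValueError("decision vectors must be 1-D and of equal length")
    if decisions_h.size == 0:
        raise ValueError("empty decision vectors")
    matches = int(np.sum(decisions_h == decisions_c))
    return matches / decisions_h.size, matches


def agreement_ratio(observed_count: int, n_images: int, pair: CountPair,
                    m_comparisons: int = 4) -> AgreementResult:
    """Observed/expected agreement ratio with log-method inference.

    The observed agreement is treated as a binomial proportion over the
    ``n_images`` compared stimuli; the expected agreement's variance is
    propagated from the two accuracy proportions by the delta method
    (dE/da_c = 2 a_h - 1, dE/da_h = 2 a_c - 1), and the two log-variances
    add. Ratios above 1 indicate systematic agreement, below 1 systematic
    disagreement.
    """
    if n_images <= 0:
        raise ValueError("need a positive number of compared images")
    if not 0 <= observed_count <= n_images:
        raise ValueError("observed count out of range")
    pair = _haldane(pair)
    expected = expected_agreement(pair)
    if expected <= 0:
        raise ValueError("expected agreement must be positive")
    # continuity correction enters the variance only; the point estimate
    # stays the raw observed proportion
    k_o = observed_count + 0.5 if observed_count in (0, n_images) else observed_count
    n_o = n_images + 1.0 if observed_count in (0, n_images) else float(n_images)
    observed = observed_count / n_images
    a_c, a_h = pair.k_c / pair.n_c, pair.k_h / pair.n_h
    var_obs_log = 1.0 / k_o - 1.0 / n_o
    var_exp = ((2.0 * a_h - 1.0) ** 2 * a_c * (1.0 - a_c) / pair.n_c
               + (2.0 * a_c - 1.0) ** 2 * a_h * (1.0 - a_h) / pair.n_h)
    var_exp_log = var_exp / expected ** 2
    se = float(np.sqrt(var_obs_log + var_exp_log))
    ratio = observed / expected
    log_ratio = np.log(ratio) if ratio > 0 else np.log((k_o / n_o) / expected)
    ci, p, p_corr = _log_ratio_result(float(log_ratio), se, m_comparisons)
    return AgreementResult(float(observed), float(expected), float(ratio),
                           ci, p, p_corr, m_comparisons)


def bonferroni(p_values, m: int = 4):
    """Multiply each p by the number of comparisons, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def aggregate_predictions(scores: np.ndarray, labels: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Turn a stimulus x run grid of [0, 1] scores into decisions and accuracies.

    Each run's score is rounded half-up to a binary decision; the group
    accuracy is the mean of per-run accuracies and the group image-level
    decision is the majority vote across runs (ties resolved by rounding the
    mean score).

    Returns ``(per_run_decisions, per_run_accuracies, group_decisions,
    group_accuracy)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] == 0:
        raise ValueError("scores must be a non-empty stimulus x run grid")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    labels = np.asarray(labels)
    decisions = np.floor(scores + 0.5).astype(int)  # 0.5 rounds up
    per_run_acc = (decisions == labels[:, None]).mean(axis=0)
    votes = decisions.mean(axis=1)
    group = np.where(votes > 0.5, 1,
                     np.where(votes < 0.5, 0,
                              np.floor(scores.mean(axis=1) + 0.5))).astype(int)
    return decisions, per_run_acc, group, float(per_run_acc.mean())
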