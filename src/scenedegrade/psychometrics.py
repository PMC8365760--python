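"""Weibull psychometric fitting for two-alternative categorization data.

Accuracy as a function of stimulus clarity is modeled by a Weibull function

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / alpha)^beta))

with the guess rate gamma fixed at 0.5 (two-choice task), the lapse rate
lambda free but capped at 0.05, and (alpha, beta) estimated by maximizing
the Bernoulli log-likelihood. Each degradation axis is first mapped to a
*clarity* axis along which accuracy increases: the low-pass cutoff itself,
the reciprocal of the high-pass cutoff, and the retained phase proportion
1 - w for phase scrambling. Thresholds (level at 80% correct) are solved in
closed form on the clarity axis and mapped back to original units; 95%
confidence intervals come from a parametric bootstrap that redraws each
level's correct-count from the fitted curve and refits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "TRIAL_COLUMNS",
    "PsychometricFit",
    "weibull",
    "clarity_axis",
    "clarity_inverse",
    "fit_psychometric",
    "threshold_at",
    "bootstrap_ci",
    "fit_table",
]

TRIAL_COLUMNS = ("observer_id", "stimulus_id", "true_category",
                 "degradation_kind", "level", "decision", "correct")

GUESS_RATE = 0.5
LAPSE_CAP = 0.05
_EPS = 1e-12


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted Weibull parameters plus threshold and bootstrap interval.

    ``alpha``/``beta`` live on the clarity axis; ``threshold80`` is mapped
    back to the original degradation units (cpi or phase weight).
    """

    alpha: float
    beta: float
    gamma: float
    lam: float
    kind: str
    threshold80: float
    ci95: tuple[float, float] | None
    n_boot: int
    converged: bool
    levels: np.ndarray
    n_per_level: np.ndarray
    k_per_level: np.ndarray
    axis: str = "linear-clarity"
    n_boot_failed: int = 0
    ci_flagged: bool = False


def weibull(x, alpha: float, beta: float, gamma: float = GUESS_RATE,
            lam: float = 0.0):
    """Weibull accuracy function on the clarity axis; strictly increasing."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if gamma < 0 or lam < 0 or gamma + lam >= 1:
        raise ValueError("need 0 <= gamma, lambda and gamma + lambda < 1")
    x = np.asarray(x, dtype=float)
    p = gamma + (1.0 - gamma - lam) * (1.0 - np.exp(-((x / alpha) ** beta)))
    return p if p.ndim else float(p)


def clarity_axis(kind: str, level):
    """Map a degradation level onto the axis along which accuracy increases.

    lowpass: clarity = F1 (more passband = clearer); highpass: 1/F1 (a lower
    cutoff removes less); phase_scramble: 1 - w (proportion of original
    phase retained).
    """
    level = np.asarray(level, dtype=float)
    if kind == "lowpass":
        out = level
    elif kind == "highpass":
        out = 1.0 / level
    elif kind == "phase_scramble":
        out = 1.0 - level
    else:
        raise ValueError(f"unknown degradation kind {kind!r}")
    return out if out.ndim else float(out)


def clarity_inverse(kind: str, clarity):
    """Inverse of :func:`clarity_axis` (same formulas for these involutions)."""
    clarity = np.asarray(clarity, dtype=float)
    if kind == "lowpass":
        out = clarity
    elif kind == "highpass":
        out = 1.0 / clarity
    elif kind == "phase_scramble":
        out = 1.0 - clarity
    else:
        raise ValueError(f"unknown degradation kind {kind!r}")
    return out if out.ndim else float(out)


def _aggregate(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a trial table slice to (level, n, k) arrays."""
    grouped = trials.groupby("level")["correct"]
    levels = np.array(sorted(grouped.groups))
    n = grouped.count().loc[levels].to_numpy(dtype=float)
    k = grouped.sum().loc[levels].to_numpy(dtype=float)
    return levels, n, k


def _negloglik(params: np.ndarray, x: np.ndarray, n: np.ndarray,
               k: np.ndarray) -> float:
    return _negloglik_grad(params, x, n, k)[0]


def _negloglik_grad(params: np.ndarray, x: np.ndarray, n: np.ndarray,
                    k: np.ndarray) -> tuple[float, np.ndarray]:
    """Bernoulli NLL and its gradient in (log alpha, log beta, lambda)."""
    log_alpha, log_beta, lam = params
    beta = np.exp(log_beta)
    span = 1.0 - GUESS_RATE - lam
    log_t = beta * (np.log(x) - log_alpha)
    t = np.exp(np.clip(log_t, -700, 700))
    e = np.exp(-t)
    p = np.clip(GUESS_RATE + span * (1.0 - e), _EPS, 1.0 - _EPS)
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    dnll_dp = -(k / p - (n - k) / (1.0 - p))
    dp_dt = span * e
    dt_dla = -beta * t
    dt_dlb = t * log_t  # t * ln(x/alpha) * beta
    g = np.array([
        np.sum(dnll_dp * dp_dt * dt_dla),
        np.sum(dnll_dp * dp_dt * dt_dlb),
        np.sum(dnll_dp * -(1.0 - e)),
    ])
    return nll, g


def _fit_counts(x: np.ndarray, n: np.ndarray, k: np.ndarray,
                starts: Sequence[tuple[float, float, float]]) -> tuple[np.ndarray, bool]:
    """L-BFGS-B over (log alpha, log beta, lambda) from multiple starts."""
    lo, hi = np.log(x.min()) - 3.0, np.log(x.max()) + 3.0
    bounds = [(lo, hi), (np.log(0.1), np.log(20.0)), (0.0, LAPSE_CAP)]
    best, best_val, ok = None, np.inf, False
    for s in starts:
        res = minimize(_negloglik_grad, np.asarray(s), args=(x, n, k),
                       jac=True, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best, best_val, ok = res.x, res.fun, bool(res.success)
    return best, ok


def _default_starts(x: np.ndarray) -> list[tuple[float, float, float]]:
    qs = np.quantile(np.log(x), [0.25, 0.5, 0.75])
    return [(la, lb, 0.0) for la in qs for lb in np.log([1.0, 3.0])]


def fit_psychometric(trials: pd.DataFrame, kind: str | None = None) -> PsychometricFit:
    """Maximum-likelihood Weibull fit for one observer x degradation kind.

    ``trials`` needs columns ``level`` and ``correct`` (optionally
    ``degradation_kind``, used to infer ``kind``). Requires >= 3 distinct
    levels. Degenerate data (at ceiling or at chance everywhere) return a
    fit with ``converged=False`` and an out-of-range threshold.
    """
    if kind is None:
        kinds = trials["degradation_kind"].unique()
        if len(kinds) != 1:
            raise ValueError("pass kind= when the table mixes degradation kinds")
        kind = str(kinds[0])
    levels, n, k = _aggregate(trials)
    if len(levels) < 3:
        raise ValueError("need trials at >= 3 distinct levels to fit")
    x = np.asarray(clarity_axis(kind, levels), dtype=float)
    order = np.argsort(x)
    x, n, k, levels = x[order], n[order], k[order], levels[order]
    if np.any(x <= 0):
        # clarity 0 (e.g. w = 1) carries no information about the curve rise
        keep = x > 0
        x, n, k, levels = x[keep], n[keep], k[keep], levels[keep]

    acc = k / n
    params, ok = _fit_counts(x, n, k, _default_starts(x))
    alpha, beta, lam = float(np.exp(params[0])), float(np.exp(params[1])), float(params[2])

    degenerate = bool(np.all(acc >= 0.99) or np.all(np.abs(acc - GUESS_RATE) < 0.02))
    # alpha escaping the tested range means the rise was never sampled
    out_of_range = not (x.min() / 8 <= alpha <= x.max() * 8)
    converged = ok and not degenerate and not out_of_range

    thr_clarity = _threshold_clarity(alpha, beta, lam, 0.80)
    threshold = float(clarity_inverse(kind, thr_clarity))
    return PsychometricFit(
        alpha=alpha, beta=beta, gamma=GUESS_RATE, lam=lam, kind=kind,
        threshold80=threshold, ci95=None, n_boot=0, converged=converged,
        levels=levels, n_per_level=n.astype(int), k_per_level=k.astype(int))


def _threshold_clarity(alpha: float, beta: float, lam: float,
                       criterion: float) -> float:
    span = 1.0 - GUESS_RATE - lam
    q = (criterion - GUESS_RATE) / span
    if not 0.0 < q < 1.0:
        raise ValueError(
            f"criterion {criterion} unreachable for gamma={GUESS_RATE}, lambda={lam}")
    return alpha * (-np.log1p(-q)) ** (1.0 / beta)


def threshold_at(fit: PsychometricFit, criterion: float = 0.80) -> float:
    """Stimulus level (original units) where the fitted curve crosses ``criterion``."""
    thr = _threshold_clarity(fit.alpha, fit.beta, fit.lam, criterion)
    return float(clarity_inverse(fit.kind, thr))


def bootstrap_ci(fit: PsychometricFit, n_boot: int = 2000,
                 seed: int = 0) -> PsychometricFit:
    """Coin-flip parametric bootstrap 95% CI for the 80% threshold.

    Each replicate redraws every level's correct count from a binomial with
    the fitted curve's probability and the original n, refits (warm-started
    at the point estimate), and records the threshold. Replicates that fail
    to refit are dropped and counted; the interval is flagged when more than
    10% fail. Fixed ``seed`` gives a reproducible interval.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    x = np.asarray(clarity_axis(fit.kind, fit.levels), dtype=float)
    p_hat = weibull(x, fit.alpha, fit.beta, fit.gamma, fit.lam)
    n = fit.n_per_level.astype(int)
    rng = np.random.default_rng(seed)
    warm = [(np.log(fit.alpha), np.log(fit.beta), fit.lam)]
    thresholds, failed = [], 0
    for _ in range(n_boot):
        k_rep = rng.binomial(n, p_hat).astype(float)
        params, ok = _fit_counts(x, n.astype(float), k_rep, warm)
        a, b, lam = np.exp(params[0]), np.exp(params[1]), params[2]
        if not ok or not (x.min() / 8 <= a <= x.max() * 8):
            failed += 1
            continue
        thresholds.append(_threshold_clarity(a, b, lam, 0.80))
    if not thresholds:
        raise RuntimeError("every bootstrap replicate failed to converge")
    lo_c, hi_c = np.percentile(thresholds, [2.5, 97.5])
    ends = sorted((float(clarity_inverse(fit.kind, lo_c)),
                   float(clarity_inverse(fit.kind, hi_c))))
    return replace(fit, ci95=(ends[0], ends[1]), n_boot=n_boot,
                   n_boot_failed=failed, ci_flagged=failed > 0.1 * n_boot)


def fit_table(trials: pd.DataFrame, n_boot: int = 2000,
              seed: int = 0) -> pd.DataFrame:
    """Fit every observer x kind slice of a trial table; one row per fit."""
    rows = []
    for i, ((obs, kind), grp) in enumerate(
            trials.groupby(["observer_id", "degradation_kind"], sort=True)):
        fit = fit_psychometric(grp, kind=str(kind))
        if fit.converged and n_boot > 0:
            fit = bootstrap_ci(fit, n_boot=n_boot, seed=seed + i)
        lo, hi = fit.ci95 if fit.ci95 is not None else (np.nan, np.nan)
        rows.append({"observer_id": obs, "degradation_kind": kind,
                     "alpha": fit.alpha, "beta": fit.beta, "lambda": fit.lam,
                     "threshold80": fit.threshold80, "ci_low": lo,
                     "ci_high": hi, "n_boot": fit.n_boot, "axis": fit.axis,
                     "converged": fit.converged})
    return pd.DataFrame(rows)
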