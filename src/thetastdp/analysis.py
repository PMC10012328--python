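"""Read-outs and statistics over simulation output.

The memory read-out is the mean plastic efficacy between hippocampal
subgroups over the last theta cycle of the stimulus (2.75-3 s after
onset); the auditory->visual direction is the headline measure (recall
was cued with the sound).  A per-trial recalled/forgotten call is made by
thresholding that value at the 10th percentile of the pooled trial
distribution.  Model variants are compared to a 4-condition behavioural
accuracy table by linear least squares, with a nested-RSS F ratio and a
Gaussian BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .engine import TrialResult

__all__ = [
    "mean_weight_window", "memory_decision_index",
    "percent_baseline_change", "normalize_accuracy",
    "compare_models", "ComparisonResult",
]


def mean_weight_window(result: TrialResult,
                       window_ms: Tuple[float, float] = (2750.0, 3000.0),
                       pre: str = "auditory", post: str = "visual") -> float:
    """Mean inter-subgroup efficacy over a closed window (ms, relative to
    stimulus onset; negative values reach into the prestimulus baseline).

    Raises if the window is not covered by the recorded trajectory.
    Returns 0 (with a warning, from the trajectory accessor) when the
    network draw produced no plastic pair in the requested direction.
    """
    lo = int(round((result.onset_ms + window_ms[0]) / result.dt_ms))
    hi = int(round((result.onset_ms + window_ms[1]) / result.dt_ms))
    if lo < 0 or hi > result.n_steps or lo >= hi:
        raise ValueError(f"window {window_ms} ms outside the recorded "
                         f"trajectory (0..{result.n_steps * result.dt_ms} ms)")
    series = result.mean_rho_series(pre, post)
    return float(series[lo:hi + 1 if hi < result.n_steps else hi].mean())


def memory_decision_index(per_trial_means: Sequence[float],
                          percentile: float = 10.0,
                          method: str = "linear") -> np.ndarray:
    """Recalled/forgotten call per trial by thresholding at a percentile
    of the pooled distribution (pool trials across the theta, delta,
    alpha and no-flicker conditions as one distribution).

    ``method``: 'linear' interpolation between order statistics (default)
    or 'nearest_rank'.  A trial is recalled iff its value is strictly
    above the threshold, so a fully degenerate pool recalls nothing.
    """
    x = np.asarray(per_trial_means, dtype=float)
    if x.size < 10:
        raise ValueError("memory_decision_index: need at least 10 pooled "
                         f"trials, got {x.size}")
    interp = {"linear": "linear", "nearest_rank": "inverted_cdf"}
    if method not in interp:
        raise ValueError(f"unknown percentile method '{method}'")
    threshold = np.percentile(x, percentile, method=interp[method])
    return x > threshold


def percent_baseline_change(baseline_mean: float, post_mean: float) -> float:
    """Synaptic change as a percentage of the baseline-period mean."""
    if baseline_mean <= 0:
        warnings.warn("percent_baseline_change: non-positive baseline; "
                      "change undefined, reported as NaN")
        return float("nan")
    return 100.0 * (post_mean - baseline_mean) / baseline_mean


def normalize_accuracy(per_condition: Dict[float, float] | Sequence[float]
                       ) -> np.ndarray:
    """Centre a 4-offset-condition accuracy (or weight) vector by
    subtracting its mean, so studies with different absolute performance
    are comparable; output sums to zero."""
    if isinstance(per_condition, dict):
        if len(per_condition) != 4:
            raise ValueError("normalize_accuracy: exactly the four phase "
                             "offset conditions are required")
        vals = np.array([per_condition[k] for k in sorted(per_condition)])
    else:
        vals = np.asarray(per_condition, dtype=float)
        if vals.size != 4:
            raise ValueError("normalize_accuracy: exactly four values "
                             "are required")
    return vals - vals.mean()


@dataclass
class ComparisonResult:
    """Least-squares fits of simulated condition means to behavioural
    accuracy, with the variant-vs-full F ratio and per-model BIC."""

    rss: Dict[str, float]
    scale: Dict[str, float]       # fitted a in  accuracy ~ a * sim + b
    intercept: Dict[str, float]
    bic: Dict[str, float]
    f_statistic: Dict[str, float]  # variant name -> F(1, 3) against 'full'
    df: Tuple[int, int] = (1, 3)


def _lstsq_fit(sim: np.ndarray, emp: np.ndarray) -> Tuple[float, float, float]:
    A = np.column_stack([sim, np.ones_like(sim)])
    coef, *_ = np.linalg.lstsq(A, emp, rcond=None)
    resid = emp - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def compare_models(sim_values: Dict[str, Dict[float, float]],
                   empirical: Dict[float, float],
                   full_model: str = "full") -> ComparisonResult:
    """Fit each model's 4-condition means to the empirical accuracies.

    ``sim_values``: model name -> {offset_deg: simulated mean};
    ``empirical``: {offset_deg: accuracy}.  Each model is fit by ordinary
    least squares (accuracy = a*sim + b).  Variants are compared against
    the designated full model with F = (RSS_variant - RSS_full) / (RSS_full/3),
    df (1, 3); BIC = n ln(RSS/n) + k ln n with n = 4 points and k = 2
    fitted parameters.  Invariant to affine rescaling of the simulated
    weights (absorbed by a and b).
    """
    offsets = sorted(empirical)
    if len(offsets) != 4:
        raise ValueError("compare_models: empirical table must cover "
                         "exactly 4 phase-offset conditions")
    emp = np.array([empirical[o] for o in offsets], dtype=float)
    rss, scale, intercept, bic = {}, {}, {}, {}
    for name, vals in sim_values.items():
        if sorted(vals) != offsets:
            raise ValueError(f"model '{name}': condition set {sorted(vals)} "
                             f"does not match empirical {offsets}")
        sim = np.array([vals[o] for o in offsets], dtype=float)
        a, b, r = _lstsq_fit(sim, emp)
        scale[name], intercept[name], rss[name] = a, b, r
        n, k = 4, 2
        with np.errstate(divide="ignore"):
            bic[name] = float(n * np.log(max(r, 1e-300) / n) + k * np.log(n))
    if full_model not in rss:
        raise ValueError(f"full model '{full_model}' missing from sim_values")
    f_stat = {}
    for name in sim_values:
        if name == full_model:
            continue
        denom = rss[full_model] / 3.0
        f_stat[name] = float((rss[name] - rss[full_model]) / denom) \
            if denom > 0 else float("inf")
    return ComparisonResult(rss=rss, scale=scale, intercept=intercept,
                            bic=bic, f_statistic=f_stat)
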