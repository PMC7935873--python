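"""Performance indices and estimation statistics for the conditioning assay.

A trial's half performance index is the mean, over the final test window,
of 0.5 x (n_unconditioned - n_conditioned) / n_total per video frame; the
two reciprocal trials of a unit sum to a full PI in [-1, +1].  Group
comparisons are reported as effect sizes: the mean PI difference with a
bias-corrected-and-accelerated (BCa) bootstrap 95% CI, plus a two-tailed
Mann-Whitney p-value for legacy reporting.  Precision-planning helpers
give the large-sample margin of error and power of the two-group design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def half_pi(
    trace: pd.DataFrame, fps: float, window_seconds: float = 30.0
) -> float:
    """Half PI of one trial from its per-frame side counts.

    Uses the last ``window_seconds`` of the trace.  Frames where no fly is
    in either counted zone are skipped rather than zero-filled.
    """
    frames = trace.sort_values("frame")
    n_window = int(round(window_seconds * fps))
    if n_window > len(frames):
        raise ValueError("trace shorter than the analysis window")
    tail = frames.iloc[len(frames) - n_window:]
    nu = tail["n_unconditioned_side"].to_numpy(dtype=float)
    nc = tail["n_conditioned_side"].to_numpy(dtype=float)
    total = nu + nc
    keep = total > 0
    if not keep.any():
        raise ValueError("no frames with flies in the analysis window")
    s = 0.5 * (nu[keep] - nc[keep]) / total[keep]
    return float(s.mean())


def full_pi(half_oct: float, half_mch: float) -> float:
    """Full PI = half PI (OCT-conditioned) + half PI (MCH-conditioned);
    the reciprocal design cancels innate odor bias."""
    return half_oct + half_mch


def pi_table(
    traces: pd.DataFrame, fps: float, window_seconds: float = 30.0
) -> pd.DataFrame:
    """Per-unit PI records from a long-format trace table.

    Expects columns unit, trial_odor, frame, n_conditioned_side,
    n_unconditioned_side (plus optional group).  Units missing either
    reciprocal trial are dropped.
    """
    rows = []
    has_group = "group" in traces.columns
    for unit, sub in traces.groupby("unit", sort=True):
        odors = set(sub["trial_odor"])
        if {"OCT", "MCH"} - odors:
            continue
        h_oct = half_pi(sub[sub["trial_odor"] == "OCT"], fps, window_seconds)
        h_mch = half_pi(sub[sub["trial_odor"] == "MCH"], fps, window_seconds)
        row = {
            "unit": unit,
            "half_pi_oct": h_oct,
            "half_pi_mch": h_mch,
            "full_pi": full_pi(h_oct, h_mch),
        }
        if has_group:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EffectSize:
    delta_pi: float
    ci_low: float
    ci_high: float
    p_mw: float
    n_test: int
    n_control: int


def effect_size(
    test_pis: Sequence[float],
    control_pis: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "bca",
) -> EffectSize:
    """Mean-difference effect size (test - control) with a bootstrap CI.

    The CI is BCa by default (percentile by ``method="percentile"``); the
    Mann-Whitney p-value is exact by enumeration when both groups have at
    most 8 values, and uses the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(test_pis, dtype=float)
    y = np.asarray(control_pis, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values for a CI")
    delta = float(x.mean() - y.mean())

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        ci_low = ci_high = delta  # degenerate: no resampling variance
    else:
        res = stats.bootstrap(
            (x, y),
            statistic=lambda a, b, axis: np.mean(a, axis=axis)
            - np.mean(b, axis=axis),
            n_resamples=n_boot,
            confidence_level=ci_level,
            method="BCa" if method == "bca" else "percentile",
            rng=np.random.default_rng(seed),
        )
        ci_low = float(res.confidence_interval.low)
        ci_high = float(res.confidence_interval.high)

    mw_method = "exact" if max(x.size, y.size) <= 8 else "asymptotic"
    p_mw = float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=mw_method
        ).pvalue
    )
    return EffectSize(
        delta_pi=delta,
        ci_low=min(ci_low, delta),
        ci_high=max(ci_high, delta),
        p_mw=p_mw,
        n_test=int(x.size),
        n_control=int(y.size),
    )


def margin_of_error(n: int, alpha: float = 0.05) -> float:
    """Large-sample CI half-width of a standardized two-group mean
    difference at equal per-group n, in SD units:
    z_{1-alpha/2} * sqrt(2/n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(z * np.sqrt(2.0 / n))


def power_two_group(
    n: int,
    d: float,
    alpha: float = 0.05,
    method: str = "analytic",
    test: str = "t",
    n_sims: int = 10000,
    seed: int = 0,
) -> float:
    """Power of a two-sided two-group comparison at per-group size ``n``
    against a standardized shift ``d``.

    analytic: the two-sided normal approximation
    Phi(delta - z) + Phi(-delta - z) with delta = d sqrt(n/2), which
    reduces exactly to alpha at d = 0.  simulate: fraction of seeded
    replicates (normal data, one group shifted by d SD) rejected at
    ``alpha`` by the chosen test ("t" or "mann_whitney").
    """
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if method == "analytic":
        delta = abs(d) * np.sqrt(n / 2.0)
        return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))
    if method != "simulate":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n))
    y = rng.standard_normal((n_sims, n)) + d
    if test == "t":
        p = stats.ttest_ind(x, y, axis=1).pvalue
    elif test == "mann_whitney":
        p = stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic"
        ).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(np.mean(p < alpha))
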