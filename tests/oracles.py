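"""Independent brute-force oracles used to check the library's fast paths.

Everything here is written position-by-position / threshold-by-threshold,
deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

from typing import List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_cims(
    seq: str,
    k: Sequence[int],
    m: Sequence[int],
    m_min: int = 1,
    ratio_lo: float = 0.01,
    ratio_hi: float = 0.5,
) -> Set[Tuple[int, str]]:
    """Position-by-position re-evaluation of every filter clause."""
    hits = set()
    n = len(seq)
    for i in range(n):
        if k[i] == 0 or m[i] <= m_min:
            continue
        ratio = m[i] / k[i]
        if not (ratio_lo < ratio < ratio_hi):
            continue
        if i >= 1 and seq[i] == "C" and seq[i - 1] == "A":
            hits.add((i, "+"))
        # minus strand: transcript C is reference G, preceding A is reference T at i+1
        if i + 1 < n and seq[i] == "G" and seq[i + 1] == "T":
            hits.add((i, "-"))
    return hits


def brute_force_regions(
    llr: Sequence[float], cutoff: float, g: int, l: int
) -> List[Tuple[int, int]]:
    """Threshold -> merge -> length-filter, via explicit scanning."""
    passing = [i for i, v in enumerate(llr) if v >= cutoff]
    if not passing:
        return []
    runs = [[passing[0], passing[0] + 1]]
    for i in passing[1:]:
        if i == runs[-1][1]:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1])
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= g:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= l]


def poisson_llr(x_ip: float, x_in: float) -> float:
    """Two-hypothesis Poisson log10 LR evaluated through scipy's logpmf,
    treating the (possibly fractional) observations via the gamma form."""
    from scipy.special import gammaln

    def logpmf(x, lam):
        return x * np.log(lam) - lam - gammaln(x + 1)

    lam0 = 0.5 * (x_ip + x_in)
    ll_sep = logpmf(x_ip, x_ip) + logpmf(x_in, x_in)
    ll_common = logpmf(x_ip, lam0) + logpmf(x_in, lam0)
    return (ll_sep - ll_common) / np.log(10.0)


def brute_force_ks_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Sup over every observed threshold of |ECDF_x - ECDF_y|."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def brute_force_summits(signal: Sequence[float]) -> List[int]:
    """Local maxima by direct neighbor comparison (plateau -> midpoint)."""
    sig = list(signal)
    n = len(sig)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sig[j + 1] == sig[i]:
            j += 1
        left = i == 0 or sig[i - 1] < sig[i]
        right = j == n - 1 or sig[j + 1] < sig[i]
        if left and right:
            out.append((i + j) // 2)
        i = j + 1
    return out


def mann_whitney_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed exact Mann-Whitney p by enumerating all group
    assignments of the pooled sample (no ties assumed)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    n_total = 0
    n_extreme = 0
    mu = nx * len(y) / 2
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        n_total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total
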