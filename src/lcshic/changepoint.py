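"""Recursive binary segmentation with a permutation stop rule.

Used both for copy-number segmentation of coverage tracks and as the
alternative segmentation engine for compartment-repositioning calling.
At each segment the breakpoint maximising the standardised two-sample
mean-difference statistic is proposed and accepted when the observed
statistic exceeds the 99th percentile of the max statistic over
within-segment permutations (alpha = 0.01, 1,000 permutations by
default); accepted breakpoints are recursed on both sides.
"""

from __future__ import annotations

import numpy as np


def max_t_statistic(values: np.ndarray) -> tuple[int, float]:
    """Best single breakpoint of a vector by the two-sample t statistic.

    Returns ``(k, t)`` where the split is values[:k] | values[k:], with
    at least two points per side. ``t`` is 0 when no admissible split
    exists or the vector is constant.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        return 0, 0.0
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(2, n - 1)
    n_l, n_r = k, n - k
    sum_l = cs[k - 1]
    sum_r = cs[-1] - sum_l
    mean_l, mean_r = sum_l / n_l, sum_r / n_r
    ss_l = cs2[k - 1] - sum_l ** 2 / n_l
    ss_r = (cs2[-1] - cs2[k - 1]) - sum_r ** 2 / n_r
    pooled = (ss_l + ss_r) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_l - mean_r) / np.sqrt(pooled * (1 / n_l + 1 / n_r))
    t[np.isnan(t)] = 0.0
    zero_var = (pooled <= 0) & (mean_l != mean_r)
    t[zero_var] = np.inf
    best = int(np.argmax(t))
    return int(k[best]), float(t[best])


def max_arc_statistic(values: np.ndarray) -> tuple[int, int, float]:
    """Best arc (interior segment vs complement) by the t statistic.

    Considers every contiguous segment [i, j) with at least two points
    on each side of the comparison and returns ``(i, j, t)``. Arcs
    anchored at either end reduce to plain binary splits; interior
    arcs capture bump-shaped changes (the circular test geometry).
    ``t`` is 0 when no admissible arc exists or the vector is constant.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        return 0, 0, 0.0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n + 1)
    sum_s = cs[None, :] - cs[:, None]          # sum of x[i:j] at [i, j]
    cnt_s = i[None, :] - i[:, None]
    ss_s = cs2[None, :] - cs2[:, None]
    valid = (cnt_s >= 2) & (cnt_s <= n - 2)
    cnt_c = n - cnt_s
    sum_c = cs[-1] - sum_s
    ss_c = cs2[-1] - ss_s
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_s = sum_s / cnt_s
        mean_c = sum_c / cnt_c
        within = (ss_s - sum_s * mean_s) + (ss_c - sum_c * mean_c)
        pooled = within / (n - 2)
        t = np.abs(mean_s - mean_c) / np.sqrt(pooled * (1 / cnt_s + 1 / cnt_c))
    t[~valid] = 0.0
    t[~np.isfinite(t)] = 0.0
    zero_var = valid & (pooled <= 0) & (mean_s != mean_c)
    t[zero_var] = np.inf
    flat = int(np.argmax(t))
    bi, bj = divmod(flat, n + 1)
    return bi, bj, float(t[bi, bj])


def segment(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    max_depth: int = 30,
) -> list[tuple[int, int]]:
    """Partition a vector into change-point segments.

    Each recursion proposes the max-t arc; it is accepted when the
    observed statistic exceeds the ``1 - alpha`` quantile of the max
    statistic over within-segment permutations, splitting the segment
    into up to three parts. Returns half-open ``(start, end)`` index
    pairs covering the vector; a constant vector yields one segment.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("segment() requires finite values")
    rng = rng or np.random.default_rng()
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        seg = x[lo:hi]
        i, j, t_obs = max_arc_statistic(seg)
        if t_obs == 0.0 or depth >= max_depth:
            out.append((lo, hi))
            return
        perm_stats = np.empty(n_perm)
        for p in range(n_perm):
            perm_stats[p] = max_arc_statistic(rng.permutation(seg))[2]
        if t_obs <= np.quantile(perm_stats, 1 - alpha):
            out.append((lo, hi))
            return
        for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
            if b > a:
                recurse(a, b, depth + 1)

    recurse(0, x.size, 0)
    return sorted(out)


def segment_means(values: np.ndarray, segments: list[tuple[int, int]]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return np.array([x[lo:hi].mean() for lo, hi in segments])
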