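"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own optimized code paths: plain
loops, naive scans, and direct formula evaluation.
"""

from __future__ import annotations

import math

import numpy as np


def arc_t_statistic(x, i, j):
    """Direct two-sample t for arc x[i:j] vs complement (plain arithmetic)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    arc = x[i:j]
    comp = np.concatenate([x[:i], x[j:]])
    k, m = len(arc), len(comp)
    mA, mB = arc.mean(), comp.mean()
    ssw = ((arc - mA) ** 2).sum() + ((comp - mB) ** 2).sum()
    if ssw <= 1e-9 * max(1.0, float((x * x).sum())):
        return math.inf if abs(mA - mB) > 1e-9 else 0.0
    s2 = ssw / (n - 2)
    return abs(mA - mB) / math.sqrt(s2 * (1 / k + 1 / m))


def exhaustive_best_arc(x, min_width=1):
    """Scan every admissible arc; k-ascending then i-ascending tie order."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (0.0, None, None)
    for k in range(min_width, n - min_width + 1):
        for i in range(0, n - k + 1):
            j = i + k
            left_ok = i == 0 or i >= min_width
            right_ok = (n - j) == 0 or (n - j) >= min_width
            if not (left_ok and right_ok):
                continue
            s = arc_t_statistic(x, i, j)
            # same epsilon tie rule as the implementation: first-seen wins
            if s > best[0] + 1e-9 * max(1.0, best[0]):
                best = (s, i, j)
    return best


def exhaustive_max_stat_fast(x, min_width=1):
    """Vectorized but structurally independent max-|T| over arcs.

    Builds the full (i, j) grid from cumulative sums — no sliding-window
    monotonicity shortcut.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    ssq = float((x * x).sum())
    best = 0.0
    for k in range(min_width, n - min_width + 1):
        m = n - k
        A = S[k:] - S[:-k]
        i = np.arange(len(A))
        ok = ((i == 0) | (i >= min_width)) & ((i + k == n) | (n - i - k >= min_width))
        if not ok.any():
            continue
        mA = A / k
        mB = (S[-1] - A) / m
        ssw = ssq - k * mA**2 - m * mB**2
        diff = np.abs(mA - mB)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(np.maximum(ssw, 0) / (n - 2) * (1 / k + 1 / m))
        t = np.where((ssw <= 1e-9 * max(1.0, ssq)) & (diff > 1e-9), np.inf, t)
        t = np.where((ssw <= 1e-9 * max(1.0, ssq)) & (diff <= 1e-9), 0.0, t)
        best = max(best, float(np.where(ok, t, -np.inf).max()))
    return best


def oracle_segment(x, alpha, n_perm, min_width, node_seed):
    """Recursive segmentation by exhaustive search + the same permutation rule.

    Permutations are drawn from the same per-node seeded streams the
    implementation declares (seed entropy + (lo, hi) spawn key), but the
    maximal statistic of each permutation is recomputed by the
    independent exhaustive scan above.
    """
    cuts = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * min_width:
            return
        stat, i, j = exhaustive_best_arc(x[lo:hi], min_width)
        if i is None or stat <= 0:
            return
        rng = np.random.default_rng(np.random.SeedSequence(node_seed, spawn_key=(lo, hi)))
        exceed = 0
        for _ in range(n_perm):
            xp = rng.permutation(x[lo:hi])
            if exhaustive_max_stat_fast(xp, min_width) >= stat:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        if p >= alpha:
            return
        local = sorted({i, j} - {0, n})
        pieces = [lo] + [lo + c for c in local] + [hi]
        cuts.extend(pieces[1:-1])
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(cuts)


def naive_overlap(intervals, qstart, qend, qchrom):
    """All intervals overlapping [qstart, qend) on qchrom, by full scan."""
    return sorted(
        (c, s, e) for (c, s, e, *_) in intervals
        if c == qchrom and s < qend and qstart < e
    )


def naive_containment(point, qchrom, intervals):
    return sorted(
        (c, s, e) for (c, s, e, *_) in intervals if c == qchrom and s <= point < e
    )


def welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def bh_adjust(p):
    """Textbook Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
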