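"""Circular binary segmentation (CBS) of per-sample log2 profiles.

The algorithm recursively searches each chromosome's probe sequence for
the "arc" of the circularized sequence whose mean differs most from its
complement, measured by a pooled-variance two-sample t statistic.  The
best arc is accepted as a changepoint pair when a permutation test on
the probe values yields p < alpha; accepted splits are recursed until no
further split is accepted or the pieces are too short.  When the best
arc touches the sequence edge the procedure degenerates to an ordinary
two-way split.

No merge/undo post-processing is applied: downstream breakpoint calling
uses a log2 shift threshold (delta) which already suppresses small
spurious steps.

Reproducibility: the permutation stream of every recursion node is
derived from ``(master seed, sample index, chromosome index, node start,
node end)`` via :class:`numpy.random.SeedSequence`, so results are
independent of the order in which samples or chromosomes are processed
and of whether earlier nodes stopped their permutation loop early.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ProbeGrid, _chrom_key

logger = logging.getLogger("icna")

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_WIDTH = 3

# relative tolerance deciding that within-group variance is numerically zero
_ZERO_VAR_RTOL = 1e-9
_PERM_BATCH = 128


@dataclass
class Segment:
    """One piecewise-constant piece of a sample's chromosome profile.

    ``start_idx``/``end_idx`` are inclusive indices into the sample's
    finite-valued probe subsequence for the chromosome; ``start_bp`` /
    ``end_bp`` are the (1-based) positions of the first and last probe.
    """

    sample_id: str
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    mean_log2: float
    n_probes: int


@dataclass
class SegmentSet:
    """Segments for one or many samples plus the parameters that made them."""

    segments: list[Segment]
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    min_width: int = DEFAULT_MIN_WIDTH
    seed: int | None = None

    def for_sample_chrom(self, sample_id: str, chrom: str) -> list[Segment]:
        segs = [s for s in self.segments if s.sample_id == sample_id and s.chrom == chrom]
        return sorted(segs, key=lambda s: s.start_idx)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.sample_id, None)
        return list(seen)

    def sample_baseline(self, sample_id: str) -> float:
        """Per-sample baseline log2: median of the sample's segment means."""
        means = [s.mean_log2 for s in self.segments if s.sample_id == sample_id]
        return float(np.median(means)) if means else 0.0


# ---------------------------------------------------------------------------
# the arc statistic
# ---------------------------------------------------------------------------

def split_statistic(values, i: int, j: int) -> float:
    """Two-sample t-like statistic for arc ``values[i:j]`` vs its complement.

    The complement is the wrap-around arc of the circularized sequence,
    so the statistic is symmetric under swapping arc and complement.
    Returns ``+inf`` when the pooled within-group variance is zero but
    the means differ, and ``0.0`` for an all-equal sequence.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not (0 <= i < j <= n):
        raise ValueError(f"invalid arc ({i},{j}) for n={n}")
    k, m = j - i, n - (j - i)
    if k < 1 or m < 1:
        raise ValueError("arc and complement must each contain at least one probe")
    arc = x[i:j]
    mA = arc.mean()
    mB = (x.sum() - arc.sum()) / m
    ssw = float((x * x).sum() - k * mA * mA - m * mB * mB)
    scale = max(1.0, float((x * x).sum()))
    if ssw <= _ZERO_VAR_RTOL * scale:
        return math.inf if abs(mA - mB) > _ZERO_VAR_RTOL * max(1.0, abs(mA) + abs(mB)) else 0.0
    if n <= 2:
        return math.inf if abs(mA - mB) > 0 else 0.0
    s2 = ssw / (n - 2)
    return abs(mA - mB) / math.sqrt(s2 * (1.0 / k + 1.0 / m))


def _arc_valid_mask(n: int, k: int, min_width: int) -> np.ndarray:
    """Which arc start positions yield pieces all >= min_width wide.

    An arc ``[i, i+k)`` splits the linear sequence into pieces
    ``[0,i) [i,i+k) [i+k,n)``; empty edge pieces are allowed.
    """
    i = np.arange(n - k + 1)
    left_ok = (i == 0) | (i >= min_width)
    right = n - (i + k)
    right_ok = (right == 0) | (right >= min_width)
    return left_ok & right_ok


def max_arc_statistic(values, min_width: int = 1):
    """Exhaustive scan of all arcs: returns (stat, i, j) maximizing |T|.

    Only arcs whose induced pieces are all at least ``min_width`` probes
    wide are considered.  Ties break toward the smallest (k, i) in scan
    order.  Returns ``(0.0, None, None)`` when no arc is admissible.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return 0.0, None, None
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    ssq = float((x * x).sum())
    scale = max(1.0, ssq)
    best_stat, best_i, best_j = 0.0, None, None
    for k in range(min_width, n - min_width + 1):
        valid = _arc_valid_mask(n, k, min_width)
        if not valid.any():
            continue
        m = n - k
        A = S[k:] - S[:-k]           # arc sums for each start i
        mA = A / k
        mB = (total - A) / m
        ssw = ssq - k * mA * mA - m * mB * mB
        diff = np.abs(mA - mB)
        with np.errstate(divide="ignore", invalid="ignore"):
            if n > 2:
                t = diff / np.sqrt(np.maximum(ssw, 0.0) / (n - 2) * (1.0 / k + 1.0 / m))
            else:
                t = np.full_like(diff, np.nan)
        zero_var = ssw <= _ZERO_VAR_RTOL * scale
        t = np.where(zero_var & (diff > _ZERO_VAR_RTOL * scale), np.inf, t)
        t = np.where(zero_var & ~(diff > _ZERO_VAR_RTOL * scale), 0.0, t)
        t = np.where(valid, t, -np.inf)
        i_best = int(np.argmax(t))
        # ties (e.g. an arc vs its complement) keep the first-seen arc;
        # the epsilon guards against last-ulp differences between k-passes
        if t[i_best] > best_stat + 1e-9 * max(1.0, best_stat):
            best_stat = float(t[i_best])
            best_i, best_j = i_best, i_best + k
    return best_stat, best_i, best_j


def _batch_max_stats(X: np.ndarray, min_width: int) -> np.ndarray:
    """Max |T| over admissible arcs for each row of ``X`` (P, n).

    Uses the identity ``SSW = SS_total - (km/n) * d^2`` (d = arc mean -
    complement mean): for fixed arc length the statistic is monotone in
    the between-group sum of squares ``u = (km/n) d^2``, so only the
    extreme window sums per arc length need evaluating.
    """
    P, n = X.shape
    S = np.concatenate([np.zeros((P, 1)), np.cumsum(X, axis=1)], axis=1)
    total = S[:, -1]
    ssq = (X * X).sum(axis=1)
    ss_tot = ssq - total * total / n
    scale = np.maximum(1.0, ssq)
    best_u = np.zeros(P)
    for k in range(min_width, n - min_width + 1):
        m = n - k
        A = S[:, k:] - S[:, :-k]        # window sums, start i = 0..m
        # admissible starts: 0, [min_width, m-min_width], m
        pieces = [A[:, :1], A[:, -1:]]
        if m - min_width >= min_width:
            pieces.append(A[:, min_width: m - min_width + 1])
        Acand = np.concatenate(pieces, axis=1)
        w = 1.0 / k + 1.0 / m
        d_hi = Acand.max(axis=1) * w - total / m
        d_lo = Acand.min(axis=1) * w - total / m
        d2 = np.maximum(d_hi * d_hi, d_lo * d_lo)
        np.maximum(best_u, d2 * (k * m / n), out=best_u)
    ssw = ss_tot - best_u
    out = np.zeros(P)
    zero_var = ssw <= _ZERO_VAR_RTOL * scale
    pos = best_u > _ZERO_VAR_RTOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = best_u * max(n - 2, 1) / np.maximum(ssw, 0.0)
    out = np.where(zero_var & pos, np.inf, np.sqrt(np.maximum(t2, 0.0)))
    out = np.where(zero_var & ~pos, 0.0, out)
    return out


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------

def permutation_pvalue(values, observed_max_stat: float, n_perm: int, seed,
                       min_width: int = 1) -> float:
    """Permutation p-value for the maximal arc statistic.

    ``p = (1 + #{permuted max stat >= observed}) / (n_perm + 1)``; the
    add-one form never returns 0 and is exact for the permutation null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        X = np.empty((b, len(x)))
        for r in range(b):
            X[r] = rng.permutation(x)
        exceed += int((_batch_max_stats(X, min_width) >= observed_max_stat).sum())
        done += b
    return (1 + exceed) / (n_perm + 1)


def _accept_split(x: np.ndarray, observed: float, alpha: float, n_perm: int,
                  min_width: int, rng: np.random.Generator) -> bool:
    """Permutation test with early rejection.

    The loop stops as soon as enough exceedances have accumulated that
    the final p-value is guaranteed to be >= alpha; because each node
    owns an independent seeded stream, early stopping cannot perturb any
    other node's draws.
    """
    if observed <= 0:
        return False
    stop_at = math.ceil(alpha * (n_perm + 1) - 1 - 1e-9)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(32 if done == 0 else _PERM_BATCH, n_perm - done)
        X = np.empty((b, len(x)))
        for r in range(b):
            X[r] = rng.permutation(x)
        exceed += int((_batch_max_stats(X, min_width) >= observed).sum())
        done += b
        if exceed >= stop_at:
            return False
    return (1 + exceed) / (n_perm + 1) < alpha


# ---------------------------------------------------------------------------
# recursive segmentation
# ---------------------------------------------------------------------------

def _segment_bounds(x: np.ndarray, alpha: float, n_perm: int, min_width: int,
                    node_seed) -> list[int]:
    """Sorted interior changepoint indices (cut before index c) for ``x``."""
    cuts: list[int] = []

    def recurse(lo: int, hi: int):
        n = hi - lo
        if n < 2 * min_width:
            return
        stat, i, j = max_arc_statistic(x[lo:hi], min_width)
        if i is None or stat <= 0:
            return
        rng = np.random.default_rng(
            np.random.SeedSequence(node_seed, spawn_key=(lo, hi))
        )
        if not _accept_split(x[lo:hi], stat, alpha, n_perm, min_width, rng):
            return
        local_cuts = sorted({i, j} - {0, n})
        pieces = [lo] + [lo + c for c in local_cuts] + [hi]
        cuts.extend(pieces[1:-1])
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(cuts)


def segment_sample(grid: ProbeGrid, sample_id: str, alpha: float = DEFAULT_ALPHA,
                   n_perm: int = DEFAULT_N_PERM, min_width: int = DEFAULT_MIN_WIDTH,
                   seed: int = 0) -> SegmentSet:
    """Segment every chromosome of one sample into a tiling SegmentSet."""
    if sample_id not in grid.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    s_idx = grid.sample_index(sample_id)
    segments: list[Segment] = []
    for c_idx, chrom in enumerate(grid.chroms):
        pos, vals = grid.sample_chrom(sample_id, chrom)
        n = len(vals)
        if n == 0:
            continue
        if n < 2 * min_width:
            logger.warning("%s/%s has %d probes < 2*min_width; single segment",
                           sample_id, chrom, n)
            cuts: list[int] = []
        else:
            node_seed = _node_entropy(seed, s_idx, c_idx)
            cuts = _segment_bounds(vals, alpha, n_perm, min_width, node_seed)
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_idx=a,
                    end_idx=b - 1,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b - 1]),
                    mean_log2=float(vals[a:b].mean()),
                    n_probes=b - a,
                )
            )
    return SegmentSet(segments, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)


def _node_entropy(seed: int, sample_idx: int, chrom_idx: int) -> list[int]:
    # entropy list for SeedSequence: stable across processing order
    return [int(seed), int(sample_idx), int(chrom_idx)]


def segment_cohort(grid: ProbeGrid, sample_ids=None, alpha: float = DEFAULT_ALPHA,
                   n_perm: int = DEFAULT_N_PERM, min_width: int = DEFAULT_MIN_WIDTH,
                   seed: int = 0) -> SegmentSet:
    """Segment many samples; results are independent of the order given."""
    ids = list(sample_ids) if sample_ids is not None else list(grid.sample_ids)
    by_sample = {
        sid: segment_sample(grid, sid, alpha=alpha, n_perm=n_perm,
                            min_width=min_width, seed=seed).segments
        for sid in ids
    }
    # canonical order regardless of input order
    segments: list[Segment] = []
    for sid in sorted(by_sample, key=lambda s: grid.sample_index(s)):
        segments.extend(by_sample[sid])
    return SegmentSet(segments, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=seed)
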