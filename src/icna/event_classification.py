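"""Event classification and fusion-candidate nomination.

Direction and truncated-portion labels are resolved against a per-sample
baseline (median segment log2) and the gene strand: the aberrant segment
is the flank deviating more from baseline, and the gene end it covers is
read off strand-aware (a minus-strand gene losing its genomically
rightmost part loses its 5' end).

A fusion candidate is a same-sample pair of amplified gene fragments —
one gene retaining its 5' portion, the other its 3' portion — at similar
log2 level, joined by a chain of amplified segments.  Nomination is
copy-number geometry only: orientation and inversions are not modelled,
and interchromosomal pairing is behind an opt-in flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel
from .icna_detection import BreakpointCall, ICNAEvent, GAIN, LOSS
from .segmentation import SegmentSet

logger = logging.getLogger("icna")

DEFAULT_AMP_THRESHOLD = 0.8
DEFAULT_LEVEL_TOL = 0.3
DEFAULT_MAX_SPAN_BP = 10_000_000

CLASS_5P_LOSS = "5prime_loss"
CLASS_3P_LOSS = "3prime_loss"
CLASS_INTERNAL = "internal"
CLASS_FLANK_5P = "flank_5p_amplified"
CLASS_FLANK_3P = "flank_3p_amplified"


class ClassificationError(ValueError):
    pass


@dataclass(eq=False)
class FusionCandidate:
    sample_id: str
    gene_5p: str
    gene_3p: str
    level_5p: float
    level_3p: float
    level_difference: float
    genomic_span_bp: int
    bp_5p: BreakpointCall
    bp_3p: BreakpointCall
    retained_exons_5p: str = ""
    retained_exons_3p: str = ""
    complexity_flag: str = "simple"


@dataclass
class FusionStructure:
    retained_5p: list[int]
    ambiguous_5p: list[int]
    retained_3p: list[int]
    ambiguous_3p: list[int]
    undetermined: bool
    text: str


# ---------------------------------------------------------------------------
# truncation classification
# ---------------------------------------------------------------------------

def _gene_end_of_side(strand: str, side: str) -> str:
    """Which gene end ('5' or '3') lies on the given genomic side of a break."""
    if strand == "+":
        return "3" if side == "right" else "5"
    return "5" if side == "right" else "3"


def classify_event(event: ICNAEvent, gene: GeneModel, sample_baseline: float = 0.0) -> ICNAEvent:
    """Assign direction, truncation class and aberrant level in place.

    Single-break events: the aberrant flank is the one deviating more
    from the sample baseline; direction is gain when it is the higher
    flank.  Two-break events with a distinct interior level are
    ``internal``, directed by the interior relative to baseline.
    """
    bps = sorted(event.breakpoints, key=lambda b: b.boundary_bp)
    if len(bps) == 1:
        bp = bps[0]
        left_m, right_m = bp.left_segment.mean_log2, bp.right_segment.mean_log2
        if abs(right_m - left_m) < 1e-12:
            raise ClassificationError(
                f"{event.sample_id}/{gene.gene_id}: flank levels indistinguishable"
            )
        dev_l, dev_r = abs(left_m - sample_baseline), abs(right_m - sample_baseline)
        # equal deviations: prefer the higher flank (mirror-symmetric tie-break)
        if dev_r > dev_l or (dev_r == dev_l and right_m > left_m):
            side, aberrant, other = "right", right_m, left_m
        else:
            side, aberrant, other = "left", left_m, right_m
        event.direction = GAIN if aberrant > other else LOSS
        end = _gene_end_of_side(gene.strand, side)
        if event.direction == LOSS:
            event.truncation_class = CLASS_5P_LOSS if end == "5" else CLASS_3P_LOSS
        else:
            event.truncation_class = CLASS_FLANK_5P if end == "5" else CLASS_FLANK_3P
        event.level = float(aberrant)
    elif len(bps) == 2:
        interior = bps[0].right_segment.mean_log2
        flank_l = bps[0].left_segment.mean_log2
        flank_r = bps[1].right_segment.mean_log2
        if abs(interior - flank_l) < 1e-12 or abs(interior - flank_r) < 1e-12:
            raise ClassificationError(
                f"{event.sample_id}/{gene.gene_id}: interior level not distinct from flanks"
            )
        event.direction = GAIN if interior > sample_baseline else LOSS
        event.truncation_class = CLASS_INTERNAL
        event.level = float(interior)
    else:
        raise ClassificationError(
            f"{event.sample_id}/{gene.gene_id}: events carry 1 or 2 breaks, got {len(bps)}"
        )
    return event


# ---------------------------------------------------------------------------
# fusion nomination
# ---------------------------------------------------------------------------

def _distinct_levels(levels: list[float], tol: float) -> int:
    """Number of level clusters separated by more than ``tol``."""
    if not levels:
        return 0
    levels = sorted(levels)
    clusters = 1
    for a, b in zip(levels[:-1], levels[1:]):
        if b - a > tol:
            clusters += 1
    return clusters


def nominate_fusions(events: list[ICNAEvent], segments: SegmentSet,
                     amp_threshold: float = DEFAULT_AMP_THRESHOLD,
                     level_tol: float = DEFAULT_LEVEL_TOL,
                     max_span_bp: int = DEFAULT_MAX_SPAN_BP,
                     require_contiguous: bool = True,
                     allow_interchromosomal: bool = False) -> list[FusionCandidate]:
    """Pair 5'-retaining with 3'-retaining amplified gene fragments.

    For each sample, every ``flank_5p_amplified`` gene is paired with
    every ``flank_3p_amplified`` gene at similar level (difference <=
    ``level_tol``) with both levels >= ``amp_threshold``.  By default
    both breakpoints must lie on one chromosome within ``max_span_bp``
    and every segment strictly between them must itself be amplified
    (one contiguous amplicon chain); ``multi_amplicon`` flags chains
    whose amplified segments sit at two or more distinct levels.
    """
    by_sample: dict[str, list[ICNAEvent]] = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)

    candidates: list[FusionCandidate] = []
    for sample_id in sorted(by_sample):
        evs = by_sample[sample_id]
        fives = [e for e in evs if e.truncation_class == CLASS_FLANK_5P and e.level >= amp_threshold]
        threes = [e for e in evs if e.truncation_class == CLASS_FLANK_3P and e.level >= amp_threshold]
        for e5 in fives:
            for e3 in threes:
                if e5.gene_id == e3.gene_id:
                    continue
                if not allow_interchromosomal and e5.chrom != e3.chrom:
                    continue
                b5 = e5.breakpoints[0]
                b3 = e3.breakpoints[0]
                span = abs(b5.boundary_bp - b3.boundary_bp) if e5.chrom == e3.chrom else 0
                if e5.chrom == e3.chrom and span > max_span_bp:
                    continue
                if abs(e5.level - e3.level) > level_tol:
                    continue
                complexity = "simple"
                if e5.chrom == e3.chrom:
                    lo = min(b5.boundary_bp, b3.boundary_bp)
                    hi = max(b5.boundary_bp, b3.boundary_bp)
                    between = [
                        s for s in segments.for_sample_chrom(sample_id, e5.chrom)
                        if s.start_bp - 1 > lo and s.end_bp - 1 < hi
                    ]
                    if require_contiguous and any(s.mean_log2 < amp_threshold for s in between):
                        continue
                    amp_levels = [s.mean_log2 for s in between if s.mean_log2 >= amp_threshold]
                    if _distinct_levels(amp_levels, level_tol) >= 2:
                        complexity = "multi_amplicon"
                candidates.append(
                    FusionCandidate(
                        sample_id=sample_id,
                        gene_5p=e5.gene_id,
                        gene_3p=e3.gene_id,
                        level_5p=float(e5.level),
                        level_3p=float(e3.level),
                        level_difference=abs(e5.level - e3.level),
                        genomic_span_bp=int(span),
                        bp_5p=b5,
                        bp_3p=b3,
                        complexity_flag=complexity,
                    )
                )
    return candidates


# ---------------------------------------------------------------------------
# fusion structure prediction
# ---------------------------------------------------------------------------

def _rank_partition(gene: GeneModel, ci_low: int, ci_high: int, keep_5p: bool):
    """Split a gene's exon ranks into (retained, ambiguous, dropped).

    ``keep_5p=True`` retains exons wholly 5' of the breakpoint CI;
    ``False`` retains exons wholly 3' of it.  Exons overlapping the CI
    are ambiguous.
    """
    retained, ambiguous, dropped = [], [], []
    for rank, s, e in gene.exons_by_rank():
        if e <= ci_low:
            side = "left"
        elif s >= ci_high:
            side = "right"
        else:
            ambiguous.append(rank)
            continue
        genomic_5p = "left" if gene.strand == "+" else "right"
        is_5p = side == genomic_5p
        (retained if is_5p == keep_5p else dropped).append(rank)
    return sorted(retained), sorted(ambiguous), sorted(dropped)


def format_ranks(ranks: list[int]) -> str:
    """Compact 1-based rank list: [1,2,3,7] -> '1-3,7'."""
    if not ranks:
        return "-"
    out = []
    start = prev = ranks[0]
    for r in ranks[1:]:
        if r == prev + 1:
            prev = r
            continue
        out.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = r
    out.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ",".join(out)


def predict_fusion_structure(candidate: FusionCandidate,
                             gene_models: dict[str, GeneModel]) -> FusionStructure:
    """Predict retained exons on both sides of a fusion candidate.

    The 5' partner keeps exons wholly 5' of its breakpoint CI; the 3'
    partner keeps exons wholly 3' of its CI; exons overlapping a CI are
    reported ambiguous.  A CI spanning an entire gene leaves the
    structure undetermined.
    """
    g5 = gene_models[candidate.gene_5p]
    g3 = gene_models[candidate.gene_3p]
    r5, a5, _ = _rank_partition(g5, candidate.bp_5p.ci_low_bp, candidate.bp_5p.ci_high_bp, True)
    r3, a3, _ = _rank_partition(g3, candidate.bp_3p.ci_low_bp, candidate.bp_3p.ci_high_bp, False)
    undetermined = (
        (candidate.bp_5p.ci_low_bp <= g5.tx_start and candidate.bp_5p.ci_high_bp >= g5.tx_end)
        or (candidate.bp_3p.ci_low_bp <= g3.tx_start and candidate.bp_3p.ci_high_bp >= g3.tx_end)
    )
    text = (
        f"{candidate.gene_5p} exons {format_ranks(r5)}"
        + (f" (ambiguous {format_ranks(a5)})" if a5 else "")
        + f" :: {candidate.gene_3p} exons {format_ranks(r3)}"
        + (f" (ambiguous {format_ranks(a3)})" if a3 else "")
        + (" [undetermined]" if undetermined else "")
    )
    candidate.retained_exons_5p = format_ranks(r5)
    candidate.retained_exons_3p = format_ranks(r3)
    return FusionStructure(r5, a5, r3, a3, undetermined, text)


def exon_partition(gene: GeneModel, ci_low: int, ci_high: int, keep_5p: bool):
    """Public helper exposing (retained, ambiguous, dropped) rank sets."""
    return _rank_partition(gene, ci_low, ci_high, keep_5p)
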