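"""The filter funnel: ordered exclusion stages with full provenance.

Raw intragenic events pass through five stages in fixed order — known
germline CNV polymorphism overlap, matched/unmatched normal-sample
subtraction, gene-level significance, high-confidence requirement, and
an automated probe-coverage rule standing in for manual plot
inspection.  Every event carries its complete (stage, verdict, reason)
trail, and the report satisfies conservation at every stage:
``events_in = retained + excluded`` and ``events_out(k) =
events_in(k+1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .icna_detection import GeneBreakStat, ICNAEvent
from .io_formats import IntervalSet, ProbeGrid

logger = logging.getLogger("icna")

STAGE_CNV = "cnv_polymorphism"
STAGE_NORMALS = "normal_subtraction"
STAGE_SIGNIFICANCE = "significance"
STAGE_CONFIDENCE = "high_confidence"
STAGE_COVERAGE = "probe_coverage"

DEFAULT_SIG_THRESHOLD = 0.05
DEFAULT_MAX_GAP_BP = 100_000
DEFAULT_MIN_FLANK_PROBES = 3
DEFAULT_FLANK_BP = 50_000


@dataclass
class FunnelStage:
    name: str
    events_in: int
    events_out: int
    excluded: list[tuple[tuple, str]]  # (event key, reason)


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)

    def validate(self):
        for st in self.stages:
            assert st.events_in == st.events_out + len(st.excluded), st.name
        for a, b in zip(self.stages[:-1], self.stages[1:]):
            assert a.events_out == b.events_in, (a.name, b.name)

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.events_in, s.events_out) for s in self.stages]


@dataclass
class FunnelParams:
    sig_threshold: float = DEFAULT_SIG_THRESHOLD
    cnv_mode: str = "ci"               # 'ci' (breakpoint CI overlap) or 'gene' (whole gene)
    direction_agnostic_normals: bool = False
    max_gap_bp: int = DEFAULT_MAX_GAP_BP
    min_flank_probes: int = DEFAULT_MIN_FLANK_PROBES
    flank_bp: int = DEFAULT_FLANK_BP


def _mark(events, stage, retained, reasons):
    kept = {id(ev) for ev in retained}
    for ev in events:
        if id(ev) in kept:
            ev.filter_status.append((stage, "pass", ""))
        else:
            ev.filter_status.append((stage, "fail", reasons.get(id(ev), "")))


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def exclude_cnv_overlap(events: list[ICNAEvent], cnv: IntervalSet,
                        mode: str = "ci", genes=None):
    """Drop events overlapping known germline CNV polymorphism regions.

    ``mode='ci'`` excludes when any breakpoint CI overlaps a CNV region
    by at least 1 bp; ``mode='gene'`` requires the gene body to overlap.
    """
    retained, excluded, reasons = [], [], {}
    gene_bounds = {g.gene_id: (g.chrom, g.tx_start, g.tx_end) for g in (genes or [])}
    for ev in events:
        if mode == "gene":
            chrom, lo, hi = gene_bounds[ev.gene_id]
            hits = cnv.overlapping(chrom, lo, hi)
        else:
            hits = []
            for bp in ev.breakpoints:
                hits.extend(cnv.overlapping(bp.chrom, bp.ci_low_bp, bp.ci_high_bp))
        if hits:
            excluded.append(ev)
            h = hits[0]
            reasons[id(ev)] = f"overlaps_cnv:{h[0]}-{h[1]}"
        else:
            retained.append(ev)
    _mark(events, STAGE_CNV, retained, reasons)
    return retained, excluded


def exclude_normal_matches(events: list[ICNAEvent], normal_events: list[ICNAEvent],
                           direction_agnostic: bool = False):
    """Drop tumour aberrations also seen in any profiled normal sample.

    A tumour event is excluded when a normal carries a break in the same
    gene with the same direction (or any direction when
    ``direction_agnostic``).
    """
    if direction_agnostic:
        normal_keys = {ev.gene_id for ev in normal_events}
        key = lambda ev: ev.gene_id
    else:
        normal_keys = {(ev.gene_id, ev.direction) for ev in normal_events}
        key = lambda ev: (ev.gene_id, ev.direction)
    retained, excluded, reasons = [], [], {}
    for ev in events:
        if key(ev) in normal_keys:
            excluded.append(ev)
            reasons[id(ev)] = "seen_in_normal"
        else:
            retained.append(ev)
    _mark(events, STAGE_NORMALS, retained, reasons)
    return retained, excluded


def apply_significance_filter(events: list[ICNAEvent], stats: list[GeneBreakStat],
                              threshold: float = DEFAULT_SIG_THRESHOLD):
    """Retain events whose gene has corrected p strictly below threshold."""
    q_by_gene = {s.gene_id: s.q for s in stats}
    retained, excluded, reasons = [], [], {}
    for ev in events:
        q = q_by_gene.get(ev.gene_id)
        if q is not None and q < threshold:
            retained.append(ev)
        else:
            excluded.append(ev)
            reasons[id(ev)] = f"q={q:.3g}" if q is not None else "no_statistic"
    _mark(events, STAGE_SIGNIFICANCE, retained, reasons)
    return retained, excluded


def apply_confidence_filter(events: list[ICNAEvent]):
    """Keep gene-level aberrations with >= 1 high-confidence sample.

    Aberrations are grouped by (gene, direction); if any constituent
    sample's event is high confidence, all samples of that aberration
    survive.
    """
    groups: dict[tuple, list[ICNAEvent]] = {}
    for ev in events:
        groups.setdefault((ev.gene_id, ev.direction), []).append(ev)
    keep_group = {k: any(e.high_confidence for e in g) for k, g in groups.items()}
    retained, excluded, reasons = [], [], {}
    for ev in events:
        if keep_group[(ev.gene_id, ev.direction)]:
            retained.append(ev)
        else:
            excluded.append(ev)
            reasons[id(ev)] = "no_high_confidence_sample"
    _mark(events, STAGE_CONFIDENCE, retained, reasons)
    return retained, excluded


def apply_coverage_filter(events: list[ICNAEvent], grid: ProbeGrid,
                          max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                          min_flank_probes: int = DEFAULT_MIN_FLANK_PROBES,
                          flank_bp: int = DEFAULT_FLANK_BP):
    """Automated proxy for manual plot inspection of probe coverage.

    An event is excluded when the flanking-probe gap of any of its
    breakpoints exceeds ``max_gap_bp``, or when either flank holds fewer
    than ``min_flank_probes`` probes within ``flank_bp`` of the boundary.
    """
    pos_by_chrom = {c: grid.pos0()[grid.chrom_slice(c)] for c in grid.chroms}
    retained, excluded, reasons = [], [], {}
    for ev in events:
        reason = None
        for bp in ev.breakpoints:
            if bp.probes_gap_bp > max_gap_bp:
                reason = f"gap={bp.probes_gap_bp}"
                break
            pos0 = pos_by_chrom[bp.chrom]
            b = bp.boundary_bp
            n_left = int(((pos0 >= b - flank_bp) & (pos0 <= b)).sum())
            n_right = int(((pos0 > b) & (pos0 <= b + flank_bp)).sum())
            if n_left < min_flank_probes or n_right < min_flank_probes:
                reason = f"flank_probes={n_left},{n_right}"
                break
        if reason is None:
            retained.append(ev)
        else:
            excluded.append(ev)
            reasons[id(ev)] = reason
    _mark(events, STAGE_COVERAGE, retained, reasons)
    return retained, excluded


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

def run_funnel(events: list[ICNAEvent], cnv: IntervalSet,
               normal_events: list[ICNAEvent], stats: list[GeneBreakStat],
               params: FunnelParams | None = None, grid: ProbeGrid | None = None,
               genes=None):
    """Apply all stages in fixed order, returning (final_events, report)."""
    params = params or FunnelParams()
    report = FunnelReport()
    current = list(events)

    def record(name, retained, excluded):
        report.stages.append(
            FunnelStage(name, len(retained) + len(excluded), len(retained),
                        [(ev.key, ev.filter_status[-1][2]) for ev in excluded])
        )
        return retained

    r, x = exclude_cnv_overlap(current, cnv, mode=params.cnv_mode, genes=genes)
    current = record(STAGE_CNV, r, x)
    r, x = exclude_normal_matches(current, normal_events,
                                  direction_agnostic=params.direction_agnostic_normals)
    current = record(STAGE_NORMALS, r, x)
    r, x = apply_significance_filter(current, stats, threshold=params.sig_threshold)
    current = record(STAGE_SIGNIFICANCE, r, x)
    r, x = apply_confidence_filter(current)
    current = record(STAGE_CONFIDENCE, r, x)
    if grid is not None:
        r, x = apply_coverage_filter(current, grid, max_gap_bp=params.max_gap_bp,
                                     min_flank_probes=params.min_flank_probes,
                                     flank_bp=params.flank_bp)
        current = record(STAGE_COVERAGE, r, x)
    report.validate()
    return current, report
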