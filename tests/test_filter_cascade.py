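import numpy as np
import pytest

from icna.filter_cascade import (
    FunnelParams, apply_confidence_filter, apply_coverage_filter,
    apply_significance_filter, exclude_cnv_overlap, exclude_normal_matches,
    run_funnel,
)
from icna.icna_detection import BreakpointCall, GeneBreakStat, ICNAEvent
from icna.io_formats import IntervalSet
from icna.segmentation import Segment

from conftest import single_sample_grid


def _call(sample, chrom, boundary, ci_low, ci_high, gap=5000, high_conf=True, delta=1.0):
    left = Segment(sample, chrom, 0, 1, boundary - gap // 2 + 1, boundary - gap // 2 + 1, 0.0, 2)
    right = Segment(sample, chrom, 2, 3, boundary + gap // 2 + 1, boundary + gap // 2 + 1, delta, 2)
    return BreakpointCall((sample, chrom, boundary), sample, chrom, left, right,
                          boundary, delta, gap, ci_low, ci_high, high_conf)


def _event(sample, gene, boundary=50_000, ci=(45_000, 55_000), direction="loss",
           high_conf=True, chrom="chr1", gap=5000):
    bp = _call(sample, chrom, boundary, ci[0], ci[1], gap=gap, high_conf=high_conf)
    return ICNAEvent(gene_id=gene, sample_id=sample, chrom=chrom, breakpoints=[bp],
                     direction=direction, truncation_class="3prime_loss",
                     level=-1.0, high_confidence=high_conf)


def test_cnv_overlap_boundary_semantics():
    events = [_event("S1", "A", ci=(100, 200))]
    assert exclude_cnv_overlap(events, IntervalSet("cnv"))[1] == []

    cnv = IntervalSet("cnv", [("chr1", 199, 300)])
    retained, excluded = exclude_cnv_overlap([_event("S1", "A", ci=(100, 200))], cnv)
    assert len(excluded) == 1  # 1 bp of overlap suffices

    cnv2 = IntervalSet("cnv", [("chr1", 200, 300)])
    retained, excluded = exclude_cnv_overlap([_event("S1", "A", ci=(100, 200))], cnv2)
    assert len(retained) == 1  # half-open CI: [100,200) does not touch [200,300)


def test_cnv_partition_matches_naive_scan():
    rng = np.random.default_rng(8)
    events = [
        _event(f"S{i}", f"G{i}", boundary=int(b), ci=(int(b) - 3000, int(b) + 3000))
        for i, b in enumerate(rng.integers(0, 10**6, 200))
    ]
    ivs = [("chr1", int(s), int(s) + int(l)) for s, l in
           zip(rng.integers(0, 10**6, 200), rng.integers(1000, 20_000, 200))]
    cnv = IntervalSet("cnv", ivs)
    retained, excluded = exclude_cnv_overlap(events, cnv)
    naive_excluded = {
        id(ev) for ev in events
        if any(s < ev.breakpoints[0].ci_high_bp and ev.breakpoints[0].ci_low_bp < e
               for _, s, e in ivs)
    }
    assert {id(e) for e in excluded} == naive_excluded
    assert len(retained) + len(excluded) == len(events)


def test_normal_subtraction_direction_matching():
    assert exclude_normal_matches([_event("T1", "A")], [])[1] == []

    normal_ev = _event("N1", "A", direction="loss")
    retained, excluded = exclude_normal_matches(
        [_event("T1", "A", direction="loss"), _event("T2", "B", direction="loss")],
        [normal_ev],
    )
    assert [e.gene_id for e in excluded] == ["A"]
    assert [e.gene_id for e in retained] == ["B"]

    # gain in normals does not veto a loss unless direction-agnostic
    retained, excluded = exclude_normal_matches(
        [_event("T1", "A", direction="gain")], [normal_ev]
    )
    assert len(retained) == 1
    retained, excluded = exclude_normal_matches(
        [_event("T1", "A", direction="gain")], [normal_ev], direction_agnostic=True
    )
    assert len(excluded) == 1


def test_significance_filter_strict_inequality():
    stats = [GeneBreakStat("A", 3, 1, 1, 2, 0.01, q=0.05),
             GeneBreakStat("B", 3, 1, 1, 2, 0.01, q=0.049)]
    events = [_event("S1", "A"), _event("S2", "B")]
    retained, excluded = apply_significance_filter(events, stats)
    assert [e.gene_id for e in retained] == ["B"]      # q = 0.049 < 0.05
    assert [e.gene_id for e in excluded] == ["A"]      # q = 0.05 exactly: out

    # oracle recount on a mixed fixture
    rng = np.random.default_rng(1)
    qs = rng.uniform(0, 0.1, 20)
    stats = [GeneBreakStat(f"g{i}", 1, 1, 1, 0, 0.01, q=float(q)) for i, q in enumerate(qs)]
    events = [_event(f"S{i}", f"g{i}") for i in range(20)]
    retained, _ = apply_significance_filter(events, stats)
    assert {e.gene_id for e in retained} == {f"g{i}" for i in range(20) if qs[i] < 0.05}


def test_confidence_filter_keeps_whole_aberration():
    events = [
        _event("S1", "A", high_conf=True, direction="loss"),
        _event("S2", "A", high_conf=False, direction="loss"),
        _event("S3", "B", high_conf=False, direction="loss"),
    ]
    retained, excluded = apply_confidence_filter(events)
    assert sorted(e.sample_id for e in retained) == ["S1", "S2"]  # S2 rides along
    assert [e.gene_id for e in excluded] == ["B"]

    # randomized fixture equals a group-by-gene oracle
    rng = np.random.default_rng(2)
    events = [
        _event(f"S{i}", f"g{int(rng.integers(0, 5))}", high_conf=bool(rng.random() < 0.4))
        for i in range(40)
    ]
    retained, excluded = apply_confidence_filter(events)
    keep = {g for g in {e.gene_id for e in events}
            if any(e.high_confidence for e in events if e.gene_id == g)}
    assert {e.gene_id for e in retained} <= keep
    assert all(e.gene_id not in keep for e in excluded)


def test_coverage_filter_gap_rule_and_monotonicity():
    grid = single_sample_grid(np.zeros(100))  # dense 5 kb grid
    dense = [_event("S1", "A", boundary=250_000, ci=(245_000, 255_000))]
    retained, excluded = apply_coverage_filter(dense, grid)
    assert excluded == []

    desert = [_event("S1", "A", boundary=250_000, ci=(245_000, 255_000), gap=250_000)]
    retained, excluded = apply_coverage_filter(desert, grid)
    assert len(excluded) == 1

    rng = np.random.default_rng(3)
    events = [
        _event("S1", f"g{i}", boundary=int(rng.integers(50_000, 450_000)),
               gap=int(rng.integers(1000, 300_000)))
        for i in range(50)
    ]
    excluded_counts = []
    for max_gap in (300_000, 150_000, 75_000, 30_000):
        for e in events:
            e.filter_status.clear()
        _, excluded = apply_coverage_filter(events, grid, max_gap_bp=max_gap)
        excluded_counts.append(len(excluded))
    assert excluded_counts == sorted(excluded_counts)


def test_identity_funnel_and_conservation():
    stats = [GeneBreakStat(f"g{i}", 5, 1, 1, 4, 1e-6, q=1e-5) for i in range(5)]
    events = [_event(f"S{i}", f"g{i}") for i in range(5)]
    grid = single_sample_grid(np.zeros(100))
    final, report = run_funnel(events, IntervalSet("cnv"), [], stats,
                               FunnelParams(), grid=grid)
    assert len(final) == len(events)
    for st in report.stages:
        assert st.events_in == st.events_out + len(st.excluded)
    counts = [st.events_in for st in report.stages]
    assert counts == sorted(counts, reverse=True)
    # every survivor carries a full pass trail
    for ev in final:
        assert [v for _, v, _ in ev.filter_status] == ["pass"] * len(report.stages)


def test_independent_filters_commute_on_final_set():
    """Swapping stage order changes attribution, not the retained set."""
    cnv = IntervalSet("cnv", [("chr1", 40_000, 60_000)])
    stats = [GeneBreakStat("A", 1, 1, 1, 0, 0.5, q=0.6),
             GeneBreakStat("B", 5, 1, 1, 4, 1e-6, q=1e-5),
             GeneBreakStat("C", 5, 1, 1, 4, 1e-6, q=1e-5)]
    def fresh():
        return [
            _event("S1", "A", boundary=200_000, ci=(195_000, 205_000)),  # fails q
            _event("S2", "B", boundary=50_000, ci=(45_000, 55_000)),     # fails CNV
            _event("S3", "C", boundary=300_000, ci=(295_000, 305_000)),  # passes all
            _event("S4", "C", boundary=300_000, ci=(295_000, 305_000), high_conf=False),
        ]
    grid = single_sample_grid(np.zeros(100))

    final_ab, _ = run_funnel(fresh(), cnv, [], stats, FunnelParams(), grid=grid)

    evs = fresh()
    r, _ = apply_significance_filter(evs, stats)          # significance first
    r, _ = exclude_cnv_overlap(r, cnv)                    # then CNV
    r, _ = exclude_normal_matches(r, [])
    r, _ = apply_confidence_filter(r)
    r, _ = apply_coverage_filter(r, grid)
    assert {(e.sample_id, e.gene_id) for e in final_ab} == {(e.sample_id, e.gene_id) for e in r}


def test_planted_germline_cnvs_all_removed(small_run):
    res, _outdir, _cfg = small_run
    final_keys = {(e.sample_id, e.gene_id) for e in res.final_events}
    germ = res.truth.germline()
    assert len(germ) > 0
    assert all((r["sample"], r["gene"]) not in final_keys for _, r in germ.iterrows())
    # somatic-only planted events survive the CNV and normal-subtraction
    # stages (gene-level significance needs cohort-scale recurrence and is
    # exercised on the full-size cohort)
    som = res.truth.somatic()
    strong = som[abs(som["level"]) >= 0.9]
    assert len(strong) > 0
    trail = {}
    for ev in res.events:
        trail[(ev.sample_id, ev.gene_id)] = {
            stage: verdict for stage, verdict, _ in ev.filter_status
        }
    kept = 0
    for _, r in strong.iterrows():
        t = trail.get((r["sample"], r["gene"]), {})
        if t.get("cnv_polymorphism") == "pass" and t.get("normal_subtraction") == "pass":
            kept += 1
    assert kept / len(strong) >= 0.9
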