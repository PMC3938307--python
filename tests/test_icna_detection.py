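import math

import numpy as np
import pytest
from scipy import stats as sps

from icna.icna_detection import (
    adjust_pvalues, attach_confidence_intervals, call_breakpoints,
    gene_break_statistic, map_breaks_to_genes, randomized_null_pit,
)
from icna.io_formats import ConfigError, GeneModel
from icna.segmentation import Segment, SegmentSet, segment_sample

from _oracles import bh_adjust
from conftest import single_sample_grid


def _segments_from_means(means, probes_per_seg=5, spacing=5000, sample="S1", chrom="chr1"):
    segs, idx = [], 0
    for m in means:
        s_bp = idx * spacing + spacing // 2 + 1
        e_bp = (idx + probes_per_seg - 1) * spacing + spacing // 2 + 1
        segs.append(Segment(sample, chrom, idx, idx + probes_per_seg - 1, s_bp, e_bp, m, probes_per_seg))
        idx += probes_per_seg
    return SegmentSet(segs)


def _gene(gene_id, chrom, start, end, strand="+", n_exons=2):
    width = (end - start) // (2 * n_exons)
    exons = tuple((start + 2 * i * width, start + (2 * i + 1) * width) for i in range(n_exons))
    return GeneModel(gene_id, chrom, strand, start, end, exons)


# ---------------------------------------------------------------------------
# breakpoint calling
# ---------------------------------------------------------------------------

def test_delta_threshold_is_inclusive():
    calls = call_breakpoints(_segments_from_means([0.0, 0.45]), delta=0.4)
    assert len(calls) == 1 and calls[0].delta_log2 == pytest.approx(0.45)
    assert call_breakpoints(_segments_from_means([0.0, 0.39]), delta=0.4) == []


def test_calls_equal_bruteforce_adjacency_scan():
    rng = np.random.default_rng(3)
    means = rng.uniform(-1.5, 1.5, 10)
    calls = call_breakpoints(_segments_from_means(list(means)), delta=0.4)
    expected = [
        i for i in range(9) if abs(means[i + 1] - means[i]) >= 0.4 - 1e-12
    ]
    assert [c.left_segment.end_idx // 5 for c in calls] == expected
    for c in calls:
        assert c.ci_low_bp <= c.boundary_bp < c.ci_high_bp


def test_raising_delta_never_adds_calls():
    rng = np.random.default_rng(4)
    means = list(rng.uniform(-1.5, 1.5, 12))
    keys_04 = {c.uid for c in call_breakpoints(_segments_from_means(means), delta=0.4)}
    keys_08 = {c.uid for c in call_breakpoints(_segments_from_means(means), delta=0.8)}
    assert keys_08 <= keys_04


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def test_noiseless_ci_collapses_to_flanking_gap():
    x = np.zeros(60)
    x[30:] = 1.0
    grid = single_sample_grid(x)
    ss = segment_sample(grid, "S1", seed=0)
    calls = call_breakpoints(ss)
    attach_confidence_intervals(grid, calls, seed=0)
    c = calls[0]
    assert (c.ci_low_bp, c.ci_high_bp) == (c.left_probe0, c.right_probe0 + 1)
    assert c.high_confidence

    # determinism: same seed, same CI
    calls2 = call_breakpoints(ss)
    attach_confidence_intervals(grid, calls2, seed=0)
    assert (calls2[0].ci_low_bp, calls2[0].ci_high_bp) == (c.ci_low_bp, c.ci_high_bp)


def test_ci_falls_back_near_chromosome_edge():
    x = np.zeros(40)
    x[2:] = 1.0  # only 2 probes left of the shift
    grid = single_sample_grid(x)
    spacing = 5000
    left = Segment("S1", "chr1", 0, 1, spacing // 2 + 1, spacing + spacing // 2 + 1, 0.0, 2)
    right = Segment("S1", "chr1", 2, 39, 2 * spacing + spacing // 2 + 1,
                    39 * spacing + spacing // 2 + 1, 1.0, 38)
    calls = call_breakpoints(SegmentSet([left, right]))
    attach_confidence_intervals(grid, calls, seed=0)
    c = calls[0]
    assert not c.high_confidence
    assert (c.ci_low_bp, c.ci_high_bp) == (c.left_probe0, c.right_probe0 + 1)


def test_ci_covers_truth_in_noisy_replicates():
    hits = 0
    n_rep = 30
    for rep in range(n_rep):
        rng = np.random.default_rng(300 + rep)
        x = rng.normal(0, 0.15, 120)
        x[60:] += 1.0
        grid = single_sample_grid(x)
        ss = segment_sample(grid, "S1", seed=rep)
        calls = call_breakpoints(ss)
        attach_confidence_intervals(grid, calls, seed=rep)
        truth0 = 59 * 5000 + 2500  # between probes 59 and 60 (0-based)
        if any(c.ci_low_bp <= truth0 <= c.ci_high_bp for c in calls):
            hits += 1
    assert hits >= int(0.93 * n_rep)


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------

def test_mapping_respects_containment_and_overlap():
    segs = _segments_from_means([0.0, -1.0])
    calls = call_breakpoints(segs)
    b = calls[0].boundary_bp
    inside = _gene("IN", "chr1", b - 5000, b + 5000)
    also = _gene("ALSO", "chr1", b - 2000, b + 8000)
    outside = _gene("OUT", "chr1", b + 10_000, b + 30_000)
    events, intergenic = map_breaks_to_genes(calls, [inside, also, outside])
    assert sorted(ev.gene_id for ev in events) == ["ALSO", "IN"]
    assert intergenic == []

    events, intergenic = map_breaks_to_genes(calls, [outside])
    assert events == [] and len(intergenic) == 1


def test_mapping_equals_allpairs_containment_scan():
    rng = np.random.default_rng(11)
    means = []
    cur = 0.0
    for _ in range(101):
        means.append(cur)
        cur += rng.choice([-1, 1]) * rng.uniform(0.4, 1.5)
    segs = _segments_from_means(means, probes_per_seg=3)
    calls = call_breakpoints(segs)
    genes = []
    for k in range(50):
        s = int(rng.integers(0, 1_500_000))
        genes.append(_gene(f"g{k}", "chr1", s, s + int(rng.integers(5000, 60_000))))
    events, intergenic = map_breaks_to_genes(calls, genes)
    naive = sorted(
        (c.sample_id, g.gene_id, c.boundary_bp)
        for c in calls for g in genes
        if g.tx_start <= c.boundary_bp < g.tx_end
    )
    got = sorted((ev.sample_id, ev.gene_id, bp.boundary_bp) for ev in events for bp in ev.breakpoints)
    assert got == naive
    assert len(intergenic) == sum(
        1 for c in calls if not any(g.tx_start <= c.boundary_bp < g.tx_end for g in genes)
    )


def test_opposite_adjacent_calls_merge_into_internal_event():
    segs = _segments_from_means([0.0, -1.2, 0.0])
    calls = call_breakpoints(segs)
    gene = _gene("G", "chr1", 0, 100_000)
    events, _ = map_breaks_to_genes(calls, [gene])
    assert len(events) == 1
    assert events[0].truncation_class == "internal"
    assert len(events[0].breakpoints) == 2


# ---------------------------------------------------------------------------
# per-gene break statistic
# ---------------------------------------------------------------------------

def test_break_statistic_arithmetic_oracle():
    # genome 10 Mb, 10 samples, 5 total breaks, 100 kb gene with 2 breaks
    gene = _gene("G", "chr1", 0, 100_000)
    segs = _segments_from_means([0.0, -1.0, 0.0])
    calls = call_breakpoints(segs)  # 2 calls inside the gene, one sample
    events, _ = map_breaks_to_genes(calls, [gene])
    # fabricate 3 intergenic calls to reach 5 total
    far = _segments_from_means([0.0, 1.0, 0.0, -1.0], sample="S2")
    intergenic = call_breakpoints(far)
    stats = gene_break_statistic(events, intergenic, [gene], n_samples=10,
                                 genome_length=10_000_000, recurrence=False)
    s = stats[0]
    assert s.expected == pytest.approx(0.05)
    assert s.observed == 2
    assert s.z == pytest.approx((2 - 0.05) / math.sqrt(0.05))
    assert s.p == pytest.approx(float(sps.poisson.sf(1, 0.05)))

    # observed == expected -> z = 0 (force expected = 2 with a 4 Mb gene)
    gene2 = GeneModel("H", "chr1", "+", 0, 4_000_000, ((0, 1000),))
    events2, _ = map_breaks_to_genes(calls, [gene2])
    stats2 = gene_break_statistic(events2, intergenic, [gene2], n_samples=10,
                                  genome_length=10_000_000, recurrence=False)
    assert stats2[0].expected == pytest.approx(2.0)
    assert stats2[0].observed == 2
    assert stats2[0].z == pytest.approx(0.0)

    with pytest.raises(ConfigError):
        gene_break_statistic(events, intergenic, [gene], 10, genome_length=0)


def test_bh_and_bonferroni_match_hand_values():
    from icna.icna_detection import GeneBreakStat

    def mk(ps):
        return [GeneBreakStat(f"g{i}", 1, 1.0, 1.0, 0.0, p) for i, p in enumerate(ps)]

    single = adjust_pvalues(mk([0.03]))
    assert single[0].q == pytest.approx(0.03)

    bh = adjust_pvalues(mk([0.01, 0.02, 0.03]))
    assert [s.q for s in bh] == pytest.approx([0.03, 0.03, 0.03])

    bon = adjust_pvalues(mk([0.01, 0.5]), method="bonferroni")
    assert [s.q for s in bon] == pytest.approx([0.02, 1.0])

    rng = np.random.default_rng(0)
    ps = rng.uniform(size=40)
    ours = [s.q for s in adjust_pvalues(mk(ps))]
    assert ours == pytest.approx(list(bh_adjust(ps)))
    # q is monotone nondecreasing in p-rank order
    order = np.argsort(ps)
    assert all(np.diff(np.array(ours)[order]) >= -1e-12)


def test_null_calibration_of_randomized_pit():
    """Uniform break placement -> randomized PIT uniform, BH discoveries rare."""
    rng = np.random.default_rng(42)
    n_genes, gene_size = 2000, 100_000
    L = n_genes * gene_size
    n_breaks = 4000
    pos = rng.integers(0, L, n_breaks)
    counts = np.bincount(pos // gene_size, minlength=n_genes)
    expected = n_breaks / n_genes
    pit = np.array([
        randomized_null_pit(int(c), expected, float(u))
        for c, u in zip(counts, rng.uniform(size=n_genes))
    ])
    ks = sps.kstest(pit, "uniform")
    assert ks.pvalue > 0.01
    p_upper = sps.poisson.sf(counts - 1, expected)
    q = bh_adjust(p_upper)
    assert (q < 0.05).mean() <= 0.05
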