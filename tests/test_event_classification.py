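import numpy as np
import pytest

from icna.event_classification import (
    ClassificationError, classify_event, exon_partition, format_ranks,
    nominate_fusions, predict_fusion_structure, FusionCandidate,
)
from icna.icna_detection import BreakpointCall, ICNAEvent
from icna.io_formats import GeneModel
from icna.segmentation import Segment, SegmentSet


def _gene(gene_id="G", chrom="chr1", start=10_000, end=90_000, strand="+", exons=None):
    if exons is None:
        exons = ((start, start + 1000), (end - 1000, end))
    return GeneModel(gene_id, chrom, strand, start, end, tuple(exons))


def _bp(sample, chrom, boundary, left_mean, right_mean, ci=None):
    left = Segment(sample, chrom, 0, 5, boundary - 20_000 + 1, boundary - 2500 + 1, left_mean, 6)
    right = Segment(sample, chrom, 6, 11, boundary + 2500 + 1, boundary + 20_000 + 1, right_mean, 6)
    ci = ci or (boundary - 2500, boundary + 2501)
    return BreakpointCall((sample, chrom, boundary), sample, chrom, left, right,
                          boundary, right_mean - left_mean, 5000, ci[0], ci[1], True)


def _ev(gene, bps, sample="S1"):
    return ICNAEvent(gene_id=gene.gene_id, sample_id=sample, chrom=gene.chrom,
                     breakpoints=list(bps))


# ---------------------------------------------------------------------------
# truncation classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "strand,left_mean,right_mean,expected_class,expected_dir",
    [
        ("+", 0.0, -1.0, "3prime_loss", "loss"),      # loss right of break, plus strand
        ("-", 0.0, -1.0, "5prime_loss", "loss"),      # strand flip
        ("+", -1.0, 0.0, "5prime_loss", "loss"),      # loss left of break
        ("-", -1.0, 0.0, "3prime_loss", "loss"),
        ("+", 1.5, 0.0, "flank_5p_amplified", "gain"),  # amplified 5' portion
        ("-", 1.5, 0.0, "flank_3p_amplified", "gain"),
        ("+", 0.0, 1.5, "flank_3p_amplified", "gain"),
    ],
)
def test_single_break_classification(strand, left_mean, right_mean, expected_class, expected_dir):
    gene = _gene(strand=strand)
    ev = _ev(gene, [_bp("S1", "chr1", 50_000, left_mean, right_mean)])
    classify_event(ev, gene, sample_baseline=0.0)
    assert ev.truncation_class == expected_class
    assert ev.direction == expected_dir


def test_internal_microdeletion_classification():
    gene = _gene(exons=[(10_000, 12_000), (20_000, 22_000), (30_000, 32_000),
                        (40_000, 42_000), (50_000, 52_000)])
    down = _bp("S1", "chr1", 38_000, 0.0, -1.3)
    up = _bp("S1", "chr1", 44_000, -1.3, 0.0)
    # share the interior segment
    up.left_segment = down.right_segment
    ev = _ev(gene, [down, up])
    classify_event(ev, gene, 0.0)
    assert ev.truncation_class == "internal"
    assert ev.direction == "loss"
    # the deleted window [38k, 44k) spans exon 4 only
    deleted = [r for r, s, e in gene.exons_by_rank() if 38_000 <= s and e <= 44_000]
    assert deleted == [4]


def test_indistinguishable_flanks_rejected():
    gene = _gene()
    ev = _ev(gene, [_bp("S1", "chr1", 50_000, 0.7, 0.7)])
    with pytest.raises(ClassificationError):
        classify_event(ev, gene, 0.0)


def test_strand_flip_symmetry():
    """Mirroring all coordinates and strands yields mirrored classes."""
    rng = np.random.default_rng(0)
    M = 1_000_000
    for _ in range(30):
        strand = "+" if rng.random() < 0.5 else "-"
        left_mean, right_mean = rng.choice([-1.5, 0.0, 1.5], 2, replace=False)
        gene = _gene(strand=strand)
        ev = _ev(gene, [_bp("S1", "chr1", 50_000, left_mean, right_mean)])
        classify_event(ev, gene, 0.0)

        flipped = "-" if strand == "+" else "+"
        m_gene = GeneModel("G", "chr1", flipped, M - gene.tx_end, M - gene.tx_start,
                           tuple(sorted((M - e, M - s) for s, e in gene.exons)))
        m_ev = _ev(m_gene, [_bp("S1", "chr1", M - 50_000, right_mean, left_mean)])
        classify_event(m_ev, m_gene, 0.0)
        assert m_ev.truncation_class == ev.truncation_class
        assert m_ev.direction == ev.direction


# ---------------------------------------------------------------------------
# fusion nomination
# ---------------------------------------------------------------------------

def _fusion_fixture(level_a=1.6, level_b=1.6, contiguous=True, extra_3p=False):
    """Events + segments for gene A (3' amplified) and gene B (5' amplified)."""
    gA = _gene("A", start=100_000, end=180_000)
    gB = _gene("B", start=400_000, end=480_000)
    sample = "S1"
    mid_level = min(level_a, level_b) if contiguous else 0.0
    seg_means = [0.0, level_a, mid_level, level_b, 0.0]
    bounds = [(0, 150_000), (150_000, 250_000), (250_000, 350_000),
              (350_000, 440_000), (440_000, 600_000)]
    segs, idx = [], 0
    for m, (s, e) in zip(seg_means, bounds):
        npr = 10
        segs.append(Segment(sample, "chr1", idx, idx + npr - 1, s + 1, e, m, npr))
        idx += npr
    segset = SegmentSet(segs)
    bpA = _bp(sample, "chr1", 150_000, 0.0, level_a)
    bpB = _bp(sample, "chr1", 440_000, level_b, 0.0)
    evA = _ev(gA, [bpA])
    evA.direction, evA.truncation_class, evA.level = "gain", "flank_3p_amplified", level_a
    evB = _ev(gB, [bpB])
    evB.direction, evB.truncation_class, evB.level = "gain", "flank_5p_amplified", level_b
    events = [evA, evB]
    genes = {g.gene_id: g for g in (gA, gB)}
    if extra_3p:
        gC = _gene("C", start=700_000, end=780_000)
        bpC = _bp(sample, "chr1", 700_500, level_a, 0.0)
        evC = _ev(gC, [bpC])
        evC.direction, evC.truncation_class, evC.level = "gain", "flank_3p_amplified", level_a
        events.append(evC)
        genes["C"] = gC
    return events, segset, genes


def test_planted_pair_yields_one_candidate_with_correct_polarity():
    events, segs, _ = _fusion_fixture()
    cands = nominate_fusions(events, segs)
    assert len(cands) == 1
    c = cands[0]
    assert (c.gene_5p, c.gene_3p) == ("B", "A")
    assert c.complexity_flag == "simple"
    assert c.level_difference <= 0.3


def test_level_tolerance_gates_nomination():
    events, segs, _ = _fusion_fixture(level_a=1.6, level_b=2.1)
    assert nominate_fusions(events, segs) == []
    assert len(nominate_fusions(events, segs, level_tol=0.6)) == 1


def test_noncontiguous_chain_rejected_by_default():
    events, segs, _ = _fusion_fixture(contiguous=False)
    assert nominate_fusions(events, segs) == []
    assert len(nominate_fusions(events, segs, require_contiguous=False)) == 1


def test_multiple_partners_enumerated_like_bruteforce():
    events, segs, _ = _fusion_fixture(extra_3p=True)
    cands = nominate_fusions(events, segs, require_contiguous=False)
    fives = [e for e in events if e.truncation_class == "flank_5p_amplified"]
    threes = [e for e in events if e.truncation_class == "flank_3p_amplified"]
    expected = {
        (f.gene_id, t.gene_id) for f in fives for t in threes
        if abs(f.level - t.level) <= 0.3
    }
    assert {(c.gene_5p, c.gene_3p) for c in cands} == expected
    assert len(cands) == 2


def test_multi_amplicon_complexity_flag():
    events, segs, _ = _fusion_fixture()
    # push the interior chain to two distinct amplified levels
    segs.segments[2].mean_log2 = segs.segments[1].mean_log2 + 0.8
    cands = nominate_fusions(events, segs, level_tol=0.3)
    assert len(cands) == 1 and cands[0].complexity_flag == "multi_amplicon"


# ---------------------------------------------------------------------------
# fusion structure prediction
# ---------------------------------------------------------------------------

def _many_exon_gene(n_exons=34, strand="+"):
    exons = tuple((10_000 + 2000 * i, 10_000 + 2000 * i + 800) for i in range(n_exons))
    return GeneModel("M", "chr1", strand, 10_000, 10_000 + 2000 * (n_exons - 1) + 800, exons)


def test_break_in_intron_12_retains_exons_13_to_34():
    gene = _many_exon_gene(34)
    # intron 12 lies between exon 12 [32000+800) and exon 13 [34000,...)
    retained, ambiguous, dropped = exon_partition(gene, 33_000, 33_500, keep_5p=False)
    assert format_ranks(retained) == "13-34"
    assert ambiguous == []
    assert format_ranks(dropped) == "1-12"


def test_ci_overlapping_exon_reported_ambiguous():
    gene = _many_exon_gene(5)
    # exon 2 spans [12000, 12800); CI straddles it
    retained, ambiguous, dropped = exon_partition(gene, 12_400, 13_000, keep_5p=True)
    assert ambiguous == [2]
    assert retained == [1]
    assert dropped == [3, 4, 5]
    assert sorted(retained + ambiguous + dropped) == [1, 2, 3, 4, 5]


def test_exon_partition_matches_naive_comparison():
    rng = np.random.default_rng(7)
    for _ in range(100):
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _many_exon_gene(12, strand=strand)
        lo = int(rng.integers(gene.tx_start, gene.tx_end - 1))
        hi = lo + int(rng.integers(1, 5000))
        retained, ambiguous, dropped = exon_partition(gene, lo, hi, keep_5p=True)
        naive_r, naive_a, naive_d = [], [], []
        for rank, s, e in gene.exons_by_rank():
            if s < hi and lo < e:
                naive_a.append(rank)
            else:
                wholly_left = e <= lo
                is_5p = wholly_left if strand == "+" else not wholly_left
                (naive_r if is_5p else naive_d).append(rank)
        assert (retained, ambiguous, dropped) == (sorted(naive_r), sorted(naive_a), sorted(naive_d))
        assert sorted(retained + ambiguous + dropped) == list(range(1, 13))


def test_predict_structure_end_to_end():
    events, segs, genes = _fusion_fixture()
    cand = nominate_fusions(events, segs)[0]
    structure = predict_fusion_structure(cand, genes)
    assert not structure.undetermined
    assert cand.retained_exons_5p == "1"   # B keeps its first exon, 5' of the break
    assert cand.retained_exons_3p == "2"   # A keeps its last exon, 3' of the break
    assert "::" in structure.text


def test_ci_spanning_gene_flags_undetermined():
    events, segs, genes = _fusion_fixture()
    cand = nominate_fusions(events, segs)[0]
    cand.bp_5p.ci_low_bp = genes["B"].tx_start - 1
    cand.bp_5p.ci_high_bp = genes["B"].tx_end + 1
    structure = predict_fusion_structure(cand, genes)
    assert structure.undetermined
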