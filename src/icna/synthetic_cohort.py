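"""Synthetic tumour/normal probe cohorts with fully known planted truth.

The generator emulates the input structure of a SNP-array copy-number
study of paediatric high-grade glioma: ~100 tumour and 26 matched
normal profiles of log2 ratios on a jittered ~5 kb probe grid, a gene
annotation, and a catalogue of germline copy-number polymorphism
regions.  Planted aberrations cover every event geometry the pipeline
must recognise:

* ``3prime_loss`` — a deletion starting inside a gene and running out of
  its 3' end into intergenic space;
* ``internal_deletion`` — a deletion wholly within one gene body;
* ``amplicon_flank_5p`` / ``amplicon_flank_3p`` — a focal amplicon with
  one edge inside a gene, amplifying its 5' (resp. 3') portion;
* ``fusion_pair`` — a single amplified interval whose two edges fall
  inside two genes, amplifying the 3' portion of the left gene and the
  5' portion of the right gene at equal level;
* ``germline_cnv`` — an interval present at identical coordinates in a
  tumour and its matched normal.

Driver genes are recurrently targeted (events dealt round-robin over
small per-class gene pools), mirroring how recurrently broken genes
dominate a real cohort, and per-sample burden follows a three-group
design (a small zero-burden group, a small very-high-burden group, the
rest around a median of ~3) so that burden/survival correlates are
testable.  All randomness flows from one seed through named
substreams — the genomic layout is identical across noise levels, and
the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable, ConfigError, GeneModel, IntervalSet, ProbeGrid, NORMAL, TUMOUR,
)

logger = logging.getLogger("icna")


class _PlacementConflict(Exception):
    """Transient same-sample interval collision; retried on another sample."""

CLASS_3P_LOSS = "3prime_loss"
CLASS_INTERNAL = "internal_deletion"
CLASS_FLANK_5P = "amplicon_flank_5p"
CLASS_FLANK_3P = "amplicon_flank_3p"
CLASS_FUSION = "fusion_pair"
CLASS_GERMLINE = "germline_cnv"

SOMATIC_CLASSES = (CLASS_3P_LOSS, CLASS_INTERNAL, CLASS_FLANK_5P, CLASS_FLANK_3P, CLASS_FUSION)


@dataclass(frozen=True)
class EventSpec:
    event_class: str
    n_events: int
    level_low: float
    level_high: float
    n_target_genes: int


@dataclass(frozen=True)
class GermlineCNVSpec:
    n_regions: int = 6           # catalogued polymorphism regions (in the interval set)
    n_uncatalogued: int = 2      # low-frequency polymorphisms absent from the catalogue
    n_pairs_per_region: int = 3
    dup_level: float = 0.58      # log2(3/2): one extra copy
    del_level: float = -1.0      # log2(1/2): heterozygous loss
    n_decoy_regions: int = 4     # catalogued polymorphisms absent from the cohort


@dataclass(frozen=True)
class ClinicalSpec:
    prop_none: float = 0.07
    prop_high: float = 0.09
    high_burden_range: tuple[int, int] = (11, 16)
    rest_burden_max: int = 8
    grade_probs: tuple = (("III", 0.25), ("IV", 0.60), ("unknown", 0.15))
    infant_prob: float = 0.13
    prior_rt_prob: float = 0.13
    h3f3a_probs: tuple = (("K27M", 0.06), ("G34RV", 0.05), ("WT", 0.18), ("unknown", 0.71))


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.0525          # per month; exponential median ~13.2 mo
    multipliers: tuple = (("none", 0.55), ("rest", 1.0), ("high", 1.69))
    censor_rate: float = 0.2


def default_event_specs() -> tuple[EventSpec, ...]:
    return (
        EventSpec(CLASS_3P_LOSS, 162, -2.0, -0.5, 14),
        EventSpec(CLASS_INTERNAL, 80, -2.0, -0.5, 7),
        EventSpec(CLASS_FLANK_5P, 50, 0.8, 2.5, 5),
        EventSpec(CLASS_FLANK_3P, 50, 0.8, 2.5, 5),
        EventSpec(CLASS_FUSION, 24, 0.8, 2.5, 4),
    )


@dataclass(frozen=True)
class SimConfig:
    n_tumours: int = 100
    n_normals: int = 26
    chrom_lengths: tuple = tuple((f"chr{i}", 2_500_000) for i in range(1, 7))
    probe_spacing: int = 5_000
    probe_jitter_frac: float = 0.1
    noise_sd: float = 0.15
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (3, 12)
    gene_length_range: tuple[int, int] = (40_000, 100_000)
    planted_event_spec: tuple[EventSpec, ...] = field(default_factory=default_event_specs)
    germline_cnv_spec: GermlineCNVSpec = field(default_factory=GermlineCNVSpec)
    clinical_spec: ClinicalSpec = field(default_factory=ClinicalSpec)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    rng_seed: int = 0

    def __post_init__(self):
        if self.probe_spacing <= 0:
            raise ConfigError("probe_spacing must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_normals > self.n_tumours:
            raise ConfigError("cannot pair more normals than tumours")
        if self.rng_seed is None:
            raise ConfigError("rng_seed is mandatory for reproducibility")


@dataclass
class TruthTable:
    """One row per planted aberration instance.

    Columns: sample, event_class, chrom, gene (gene_3p for fusions),
    gene2 (gene_5p for fusions, else ''), break1_bp, break2_bp (0-based
    cut coordinates; -1 when the edge is off the covered genome or
    intergenic-only bookkeeping does not apply), interval_start,
    interval_end (the aberrant interval, 0-based half-open), level.
    """

    data: pd.DataFrame

    def somatic(self) -> pd.DataFrame:
        return self.data[self.data["event_class"] != CLASS_GERMLINE]

    def germline(self) -> pd.DataFrame:
        return self.data[self.data["event_class"] == CLASS_GERMLINE]

    def class_counts(self) -> dict[str, int]:
        return self.data["event_class"].value_counts().to_dict()

    def burden_per_sample(self, samples: list[str]) -> dict[str, int]:
        counts = self.somatic()["sample"].value_counts().to_dict()
        return {s: int(counts.get(s, 0)) for s in samples}


def sim_config_from_dict(overrides: dict, base: SimConfig | None = None) -> SimConfig:
    """Build a SimConfig from plain JSON/YAML data (nested dicts allowed)."""
    base = base or SimConfig()
    d = dict(overrides)
    if "chrom_lengths" in d:
        d["chrom_lengths"] = tuple((str(c), int(l)) for c, l in d["chrom_lengths"])
    if "planted_event_spec" in d:
        specs = []
        for s in d["planted_event_spec"]:
            specs.append(s if isinstance(s, EventSpec) else EventSpec(**s))
        d["planted_event_spec"] = tuple(specs)
    for key, cls in (("germline_cnv_spec", GermlineCNVSpec),
                     ("clinical_spec", ClinicalSpec),
                     ("survival_spec", SurvivalSpec)):
        if key in d and not isinstance(d[key], cls):
            sub = dict(d[key])
            for f in ("high_burden_range", "grade_probs", "h3f3a_probs", "multipliers"):
                if f in sub:
                    sub[f] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                                   for x in sub[f]) if f != "high_burden_range" else tuple(sub[f])
            d[key] = cls(**sub)
    for f in ("exon_count_range", "gene_length_range"):
        if f in d:
            d[f] = tuple(d[f])
    return replace(base, **d)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _make_probes(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    chroms, positions = [], []
    for chrom, length in cfg.chrom_lengths:
        n = int(length // cfg.probe_spacing)
        centers = (np.arange(n) + 0.5) * cfg.probe_spacing
        jitter = rng.uniform(-cfg.probe_jitter_frac, cfg.probe_jitter_frac, n) * cfg.probe_spacing
        pos0 = np.round(centers + jitter).astype(np.int64)
        chroms.extend([chrom] * n)
        positions.append(pos0 + 1)  # 1-based ingest convention
    return np.array(chroms, dtype=object), np.concatenate(positions)


def _make_genes(cfg: SimConfig, rng) -> list[GeneModel]:
    lo, hi = cfg.gene_length_range
    klo, khi = cfg.exon_count_range
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length in cfg.chrom_lengths:
        cursor = 60_000
        while cursor + hi + 60_000 < length and gid < cfg.n_genes:
            glen = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(klo, khi + 1))
            exons = _make_exons(cursor, cursor + glen, k, rng)
            gid += 1
            genes.append(GeneModel(f"G{gid:03d}", chrom, strand, cursor, cursor + glen, exons))
            cursor += glen + int(rng.integers(80_000, 220_000))
    if gid < cfg.n_genes:
        raise ConfigError(
            f"genome too small for {cfg.n_genes} genes; placed only {gid}"
        )
    return genes


def _make_exons(start: int, end: int, k: int, rng) -> tuple[tuple[int, int], ...]:
    length = end - start
    exon_sizes = rng.integers(200, 1500, k)
    total_exon = int(exon_sizes.sum())
    if total_exon > 0.5 * length:
        exon_sizes = np.maximum((exon_sizes * (0.5 * length / total_exon)).astype(int), 50)
        total_exon = int(exon_sizes.sum())
    intron_total = length - total_exon
    if k > 1:
        w = rng.dirichlet(np.ones(k - 1))
        introns = np.maximum((w * intron_total).astype(int), 100)
    else:
        introns = np.array([], dtype=int)
    exons = []
    cursor = start
    for i in range(k):
        e = cursor + int(exon_sizes[i])
        exons.append((cursor, min(e, end)))
        cursor = e
        if i < k - 1:
            cursor += int(introns[i])
    # pin last exon end to tx_end (standard annotation convention)
    s_last, _ = exons[-1]
    if s_last >= end:
        raise ConfigError("exon layout overflow")
    exons[-1] = (s_last, end)
    return tuple(exons)


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

@dataclass
class _Aberration:
    sample: str
    event_class: str
    chrom: str
    gene: str
    gene2: str
    start: int       # aberrant interval, 0-based half-open
    end: int
    break1: int      # intragenic cut coordinate(s); -1 when absent
    break2: int
    level: float


class _Placer:
    """Stateful deterministic placement of aberration intervals."""

    MARGIN = 30_000

    def __init__(self, cfg: SimConfig, genes: list[GeneModel],
                 chroms: np.ndarray, pos1: np.ndarray, rng):
        self.cfg = cfg
        self.rng = rng
        self.genes = {g.gene_id: g for g in genes}
        self.gene_list = genes
        self.chrom_len = dict(cfg.chrom_lengths)
        self.occupied: dict[str, list[tuple[str, int, int]]] = {}
        self.pos0_by_chrom = {}
        for chrom, _ in cfg.chrom_lengths:
            mask = chroms == chrom
            self.pos0_by_chrom[chrom] = np.sort(pos1[mask]) - 1

    def _in_gene_probes(self, gene: GeneModel) -> np.ndarray:
        p = self.pos0_by_chrom[gene.chrom]
        return p[(p >= gene.tx_start) & (p < gene.tx_end)]

    def _conflicts(self, sample: str, chrom: str, start: int, end: int) -> bool:
        for c, s, e in self.occupied.get(sample, ()):
            if c == chrom and start - self.MARGIN < e and s < end + self.MARGIN:
                return True
        return False

    def _reserve(self, sample: str, chrom: str, start: int, end: int):
        self.occupied.setdefault(sample, []).append((chrom, start, end))

    def _pick_cut(self, gene: GeneModel, side_margin: int = 2):
        """A cut coordinate strictly between two in-gene probes."""
        p = self._in_gene_probes(gene)
        if len(p) < 2 * side_margin + 1:
            raise ConfigError(
                f"gene {gene.gene_id} too short for a planted break at "
                f"{self.cfg.probe_spacing} bp probe spacing"
            )
        gi = int(self.rng.integers(side_margin, len(p) - side_margin))
        return int(self.rng.integers(p[gi - 1] + 1, p[gi] + 1))

    def _outward_extent(self, gene: GeneModel, cut: int, direction: str) -> tuple[int, int]:
        """Aberrant interval from ``cut`` running out of the gene."""
        for ext in (int(self.rng.integers(50_000, 200_000)) for _ in range(25)):
            if direction == "right":
                start, end = cut, min(gene.tx_end + ext, self.chrom_len[gene.chrom])
                far = end
            else:
                start, end = max(gene.tx_start - ext, 0), cut
                far = start
            if not self._point_in_other_gene(gene, far):
                return start, end
        # fall back to the minimal extent even if the far edge grazes a gene
        if direction == "right":
            return cut, min(gene.tx_end + 50_000, self.chrom_len[gene.chrom])
        return max(gene.tx_start - 50_000, 0), cut

    def _point_in_other_gene(self, gene: GeneModel, point: int) -> bool:
        for g in self.gene_list:
            if g.chrom == gene.chrom and g.gene_id != gene.gene_id and g.contains(point):
                return True
        return False

    # -- per-class realizers ---------------------------------------------

    def place_3prime_loss(self, sample, gene: GeneModel, level) -> _Aberration:
        for _ in range(12):
            cut = self._pick_cut(gene)
            # the 3' side in genomic terms depends on strand
            direction = "right" if gene.strand == "+" else "left"
            start, end = self._outward_extent(gene, cut, direction)
            if not self._conflicts(sample, gene.chrom, start, end):
                self._reserve(sample, gene.chrom, start, end)
                return _Aberration(sample, CLASS_3P_LOSS, gene.chrom, gene.gene_id, "",
                                   start, end, cut, -1, level)
        raise _PlacementConflict(f"3prime_loss in {gene.gene_id} for {sample}")

    def place_internal(self, sample, gene: GeneModel, level) -> _Aberration:
        p = self._in_gene_probes(gene)
        min_inside = 3
        if len(p) < min_inside + 4 + 1:
            raise ConfigError(
                f"gene {gene.gene_id} too short to contain an internal deletion "
                f"at {self.cfg.probe_spacing} bp probe spacing"
            )
        for _ in range(12):
            gi = int(self.rng.integers(2, len(p) - 2 - min_inside))
            gj = gi + min_inside + int(self.rng.integers(0, min(4, len(p) - 2 - gi - min_inside)))
            c1 = int(self.rng.integers(p[gi - 1] + 1, p[gi] + 1))
            c2 = int(self.rng.integers(p[gj] + 1, p[gj + 1] + 1))
            if not self._conflicts(sample, gene.chrom, c1, c2):
                self._reserve(sample, gene.chrom, c1, c2)
                return _Aberration(sample, CLASS_INTERNAL, gene.chrom, gene.gene_id, "",
                                   c1, c2, c1, c2, level)
        raise _PlacementConflict(f"internal deletion in {gene.gene_id} for {sample}")

    def place_flank(self, sample, gene: GeneModel, level, five_prime: bool) -> _Aberration:
        cls = CLASS_FLANK_5P if five_prime else CLASS_FLANK_3P
        for _ in range(12):
            cut = self._pick_cut(gene)
            # amplified portion covers the requested gene end
            end_is_left = (gene.strand == "+") == five_prime
            direction = "left" if end_is_left else "right"
            start, end = self._outward_extent(gene, cut, direction)
            if not self._conflicts(sample, gene.chrom, start, end):
                self._reserve(sample, gene.chrom, start, end)
                return _Aberration(sample, cls, gene.chrom, gene.gene_id, "",
                                   start, end, cut, -1, level)
        raise _PlacementConflict(f"{cls} in {gene.gene_id} for {sample}")

    def place_fusion(self, sample, gene_left: GeneModel, gene_right: GeneModel, level) -> _Aberration:
        # single amplicon from inside the left gene to inside the right gene;
        # with both genes plus-strand the left gene keeps its 3' portion and
        # the right gene its 5' portion
        for _ in range(12):
            c1 = self._pick_cut(gene_left)
            c2 = self._pick_cut(gene_right)
            if not self._conflicts(sample, gene_left.chrom, c1, c2):
                self._reserve(sample, gene_left.chrom, c1, c2)
                return _Aberration(sample, CLASS_FUSION, gene_left.chrom,
                                   gene_left.gene_id, gene_right.gene_id,
                                   c1, c2, c1, c2, level)
        raise _PlacementConflict(f"fusion {gene_left.gene_id}:{gene_right.gene_id}")

    def realize_germline_region(self, gene: GeneModel, level) -> tuple[int, int, int]:
        """Fixed region coordinates shared by all carriers of one CNV.

        The region must stay clear of every other gene body: it defines
        a catalogued polymorphism interval, and letting it brush a
        neighbouring gene would spuriously veto that gene's somatic
        events at the CNV-exclusion stage.
        """
        for _ in range(25):
            cut = self._pick_cut(gene)
            direction = "right" if gene.strand == "+" else "left"
            start, end = self._outward_extent(gene, cut, direction)
            if not self._overlaps_other_gene(gene, start - 15_000, end + 15_000):
                return start, end, cut
        # minimal extent fallback
        if direction == "right":
            return cut, min(gene.tx_end + 20_000, self.chrom_len[gene.chrom]), cut
        return max(gene.tx_start - 20_000, 0), cut, cut

    def _overlaps_other_gene(self, gene: GeneModel, start: int, end: int) -> bool:
        return any(
            g.chrom == gene.chrom and g.gene_id != gene.gene_id
            and g.tx_start < end and start < g.tx_end
            for g in self.gene_list
        )


# ---------------------------------------------------------------------------
# burden design
# ---------------------------------------------------------------------------

def _burden_targets(cfg: SimConfig, total_events: int, rng) -> dict[str, int]:
    n_t = cfg.n_tumours
    cs = cfg.clinical_spec
    samples = [f"T{i + 1:03d}" for i in range(n_t)]
    n_none = int(round(cs.prop_none * n_t))
    n_high = int(round(cs.prop_high * n_t))
    order = rng.permutation(n_t)
    none_ids = [samples[i] for i in order[:n_none]]
    high_ids = [samples[i] for i in order[n_none:n_none + n_high]]
    rest_ids = [samples[i] for i in order[n_none + n_high:]]
    targets = {s: 0 for s in none_ids}
    hi_lo, hi_hi = cs.high_burden_range
    for s in high_ids:
        targets[s] = int(rng.integers(hi_lo, hi_hi + 1))
    budget = total_events - sum(targets.values())
    if budget < 0:
        raise ConfigError("planted_event_spec too small for the burden design")
    # every rest sample carries >=1 event when the budget allows it
    floor = 1 if budget >= len(rest_ids) else 0
    mean_rest = budget / max(len(rest_ids), 1)
    rest = np.clip(rng.poisson(mean_rest, len(rest_ids)), floor, cs.rest_burden_max)
    diff = budget - int(rest.sum())
    i = 0
    while diff != 0:
        j = i % len(rest)
        if diff > 0 and rest[j] < cs.rest_burden_max:
            rest[j] += 1
            diff -= 1
        elif diff < 0 and rest[j] > floor:
            rest[j] -= 1
            diff += 1
        i += 1
        if i > 100_000:
            raise ConfigError("cannot satisfy burden design")
    for s, b in zip(rest_ids, rest):
        targets[s] = int(b)
    return {s: targets[s] for s in samples}


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig):
    """Generate (ProbeGrid, genes, germline-CNV IntervalSet, TruthTable).

    The signal is piecewise-constant log2 (0 baseline) plus iid
    N(0, noise_sd) per probe; the genomic layout and planted events are
    drawn from substreams independent of the noise stream, so cohorts at
    different noise levels share identical truth.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.rng_seed)
    genome_rng, events_rng, noise_rng, _clin = [np.random.default_rng(c) for c in ss.spawn(4)]

    chroms, pos1 = _make_probes(cfg, genome_rng)
    genes = _make_genes(cfg, genome_rng)

    tumours = [f"T{i + 1:03d}" for i in range(cfg.n_tumours)]
    normals = [f"N{i + 1:03d}" for i in range(cfg.n_normals)]
    pairing = {tumours[i]: normals[i] for i in range(cfg.n_normals)}
    sample_ids = tumours + normals
    roles = {s: TUMOUR for s in tumours} | {s: NORMAL for s in normals}

    pools, fusion_pairs = _assign_gene_pools(cfg, genes, events_rng)
    placer = _Placer(cfg, genes, chroms, pos1, events_rng)
    aberrations: list[_Aberration] = []

    # germline CNV regions first: fixed coordinates, matched-pair carriers
    gcs = cfg.germline_cnv_spec
    cnv_intervals = []
    gene_by_id = {g.gene_id: g for g in genes}
    paired_tumours = tumours[: cfg.n_normals]
    n_germ = (gcs.n_regions + gcs.n_uncatalogued) if pools.get(CLASS_GERMLINE) else 0
    for r in range(n_germ):
        gene = gene_by_id[pools[CLASS_GERMLINE][r % len(pools[CLASS_GERMLINE])]]
        level = gcs.dup_level if r % 2 == 0 else gcs.del_level
        start, end, cut = placer.realize_germline_region(gene, level)
        if r < gcs.n_regions:  # uncatalogued regions stay out of the interval set
            cnv_intervals.append((gene.chrom, start, end, f"cnv_region_{r + 1}"))
        carriers = list(events_rng.choice(paired_tumours, size=gcs.n_pairs_per_region, replace=False))
        for t in carriers:
            if placer._conflicts(t, gene.chrom, start, end):
                continue  # keep region coords canonical; skip colliding carrier
            placer._reserve(t, gene.chrom, start, end)
            placer._reserve(pairing[t], gene.chrom, start, end)
            aberrations.append(
                _Aberration(t, CLASS_GERMLINE, gene.chrom, gene.gene_id, "",
                            start, end, cut, -1, level)
            )

    # somatic slots dealt across samples per the burden design
    slots = _make_slots(cfg, pools, fusion_pairs, events_rng)
    if slots:
        targets = _burden_targets(cfg, len(slots), events_rng)
        dealt = _deal_slots(slots, targets, gene_by_id, events_rng)
    else:
        dealt = []
    def _place(sample, slot):
        cls, gene_id, gene2_id, level = slot
        if cls == CLASS_3P_LOSS:
            return placer.place_3prime_loss(sample, gene_by_id[gene_id], level)
        if cls == CLASS_INTERNAL:
            return placer.place_internal(sample, gene_by_id[gene_id], level)
        if cls == CLASS_FLANK_5P:
            return placer.place_flank(sample, gene_by_id[gene_id], level, True)
        if cls == CLASS_FLANK_3P:
            return placer.place_flank(sample, gene_by_id[gene_id], level, False)
        return placer.place_fusion(sample, gene_by_id[gene_id], gene_by_id[gene2_id], level)

    placed_count: dict[str, int] = {t: 0 for t in tumours}
    deferred = []
    for sample, slot in dealt:
        try:
            aberrations.append(_place(sample, slot))
            placed_count[sample] += 1
        except _PlacementConflict:
            deferred.append(slot)
    for slot in deferred:
        done = False
        for sample in sorted(placed_count, key=lambda s: (placed_count[s] == 0, placed_count[s], s)):
            try:
                aberrations.append(_place(sample, slot))
                placed_count[sample] += 1
                done = True
                break
            except _PlacementConflict:
                continue
        if not done:
            raise ConfigError(f"cannot place planted event {slot[0]} in any sample")

    # decoy polymorphism regions, disjoint from genes and events
    for d in range(gcs.n_decoy_regions):
        iv = _decoy_interval(cfg, genes, events_rng)
        if iv is not None:
            cnv_intervals.append((*iv, f"cnv_decoy_{d + 1}"))

    # synthesize signal
    values = np.zeros((len(pos1), len(sample_ids)))
    col = {s: j for j, s in enumerate(sample_ids)}
    pos0 = pos1 - 1
    chrom_masks = {c: chroms == c for c, _ in cfg.chrom_lengths}
    for ab in aberrations:
        mask = chrom_masks[ab.chrom] & (pos0 >= ab.start) & (pos0 < ab.end)
        values[mask, col[ab.sample]] += ab.level
        if ab.event_class == CLASS_GERMLINE:
            values[mask, col[pairing[ab.sample]]] += ab.level
    if cfg.noise_sd > 0:
        values += noise_rng.normal(0.0, cfg.noise_sd, values.shape)

    probe_ids = np.array([f"P{i + 1:06d}" for i in range(len(pos1))], dtype=object)
    grid = ProbeGrid(probe_ids, chroms, pos1, values, sample_ids, roles, pairing)
    truth = TruthTable(
        pd.DataFrame(
            [
                {
                    "sample": ab.sample, "event_class": ab.event_class, "chrom": ab.chrom,
                    "gene": ab.gene, "gene2": ab.gene2, "break1_bp": ab.break1,
                    "break2_bp": ab.break2, "interval_start": ab.start,
                    "interval_end": ab.end, "level": ab.level,
                }
                for ab in aberrations
            ]
        )
    )
    cnv_set = IntervalSet("germline_cnv", cnv_intervals)
    return grid, genes, cnv_set, truth


def _assign_gene_pools(cfg: SimConfig, genes: list[GeneModel], rng):
    """Partition genes into per-class driver pools, fusion pairs and CNV hosts."""
    by_len = sorted(genes, key=lambda g: g.size, reverse=True)
    taken: set[str] = set()

    internal_spec = next((s for s in cfg.planted_event_spec if s.event_class == CLASS_INTERNAL), None)
    pools: dict[str, list[str]] = {}
    if internal_spec:
        # prefer the longest genes: an internal deletion needs interior probes
        longest = by_len[: internal_spec.n_target_genes]
        pools[CLASS_INTERNAL] = [g.gene_id for g in longest]
        taken |= set(pools[CLASS_INTERNAL])

    # fusion pairs: consecutive same-chromosome gene pairs, both forced '+'
    fusion_spec = next((s for s in cfg.planted_event_spec if s.event_class == CLASS_FUSION), None)
    fusion_pairs: list[tuple[str, str]] = []
    if fusion_spec:
        n_pairs = fusion_spec.n_target_genes // 2
        by_pos = sorted(genes, key=lambda g: (g.chrom, g.tx_start))
        i = 0
        while len(fusion_pairs) < n_pairs and i < len(by_pos) - 1:
            a, b = by_pos[i], by_pos[i + 1]
            if a.chrom == b.chrom and a.gene_id not in taken and b.gene_id not in taken:
                fusion_pairs.append((a.gene_id, b.gene_id))
                taken |= {a.gene_id, b.gene_id}
                i += 2
            else:
                i += 1
        if len(fusion_pairs) < n_pairs:
            raise ConfigError("not enough adjacent gene pairs for fusions")
        # force plus strand so the left gene donates 3' and the right gene 5'
        for k, g in enumerate(genes):
            if g.gene_id in {x for p in fusion_pairs for x in p} and g.strand == "-":
                genes[k] = replace(g, strand="+")

    remaining = [g.gene_id for g in genes if g.gene_id not in taken]
    rng.shuffle(remaining)
    cursor = 0
    for spec in cfg.planted_event_spec:
        if spec.event_class in (CLASS_INTERNAL, CLASS_FUSION):
            continue
        pools[spec.event_class] = remaining[cursor: cursor + spec.n_target_genes]
        cursor += spec.n_target_genes
    gcs = cfg.germline_cnv_spec
    if gcs.n_regions + gcs.n_uncatalogued > 0:
        n_cnv_genes = min(gcs.n_regions + gcs.n_uncatalogued, len(remaining) - cursor)
        if n_cnv_genes <= 0:
            raise ConfigError("not enough genes left for germline CNV hosts")
        pools[CLASS_GERMLINE] = remaining[cursor: cursor + n_cnv_genes]
    return pools, fusion_pairs


def _make_slots(cfg: SimConfig, pools, fusion_pairs, rng):
    slots = []
    for spec in cfg.planted_event_spec:
        for i in range(spec.n_events):
            level = float(rng.uniform(spec.level_low, spec.level_high))
            if spec.event_class == CLASS_FUSION:
                a, b = fusion_pairs[i % len(fusion_pairs)]
                slots.append((CLASS_FUSION, a, b, level))
            else:
                pool = pools[spec.event_class]
                slots.append((spec.event_class, pool[i % len(pool)], "", level))
    rng.shuffle(slots)
    return slots


def _deal_slots(slots, targets: dict[str, int], gene_by_id, rng):
    """Assign slots to samples, avoiding same-sample gene proximity clashes."""
    dealt: list[tuple[str, tuple]] = []
    remaining = list(slots)
    order = sorted(targets, key=lambda s: -targets[s])
    for sample in order:
        need = targets[sample]
        chosen_spans: list[tuple[str, int, int]] = []
        picked_idx = []
        for idx, slot in enumerate(remaining):
            if len(picked_idx) >= need:
                break
            cls, g1, g2, _ = slot
            gene = gene_by_id[g1]
            span = (gene.chrom, gene.tx_start - 450_000, gene.tx_end + 450_000)
            clash = any(
                c == span[0] and span[1] < e and s < span[2]
                for c, s, e in chosen_spans
            )
            if g2:
                gene2 = gene_by_id[g2]
                clash = clash or any(
                    c == gene2.chrom and gene2.tx_start - 450_000 < e and s < gene2.tx_end + 450_000
                    for c, s, e in chosen_spans
                )
            if clash:
                continue
            picked_idx.append(idx)
            chosen_spans.append(span)
            if g2:
                gene2 = gene_by_id[g2]
                chosen_spans.append((gene2.chrom, gene2.tx_start - 450_000, gene2.tx_end + 450_000))
        # fall back: take whatever is left even if close together
        j = 0
        while len(picked_idx) < need and j < len(remaining):
            if j not in picked_idx:
                picked_idx.append(j)
            j += 1
        for idx in sorted(picked_idx, reverse=True):
            dealt.append((sample, remaining.pop(idx)))
    return dealt


def _decoy_interval(cfg: SimConfig, genes, rng):
    chrom_len = dict(cfg.chrom_lengths)
    for _ in range(50):
        chrom = list(chrom_len)[int(rng.integers(0, len(chrom_len)))]
        start = int(rng.integers(0, chrom_len[chrom] - 120_000))
        end = start + int(rng.integers(40_000, 120_000))
        clear = all(
            not (g.chrom == chrom and start - 50_000 < g.tx_end and g.tx_start < end + 50_000)
            for g in genes
        )
        if clear:
            return chrom, start, end
    return None


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------

def draw_survival(groups: dict[str, str], survival_spec: SurvivalSpec, rng):
    """Exponential survival with independent exponential censoring.

    The censoring hazard is ``h * c / (1 - c)`` so the realized censor
    fraction equals ``censor_rate`` in expectation within every group.
    Returns (os_months, os_event) dicts.
    """
    mult = dict(survival_spec.multipliers)
    c = survival_spec.censor_rate
    if not 0 <= c < 1:
        raise ConfigError("censor_rate must be in [0, 1)")
    months, events = {}, {}
    for sample in groups:
        h = survival_spec.baseline_hazard * mult[groups[sample]]
        if h <= 0:
            raise ConfigError(f"non-positive hazard for group {groups[sample]!r}")
        t = rng.exponential(1.0 / h)
        if c > 0:
            cens = rng.exponential((1.0 - c) / (h * c))
            months[sample] = float(min(t, cens))
            events[sample] = bool(t <= cens)
        else:
            months[sample] = float(t)
            events[sample] = True
    return months, events


def simulate_survival(truth: TruthTable, clinical_spec: ClinicalSpec,
                      survival_spec: SurvivalSpec, seed, n_tumours: int | None = None,
                      high_cutoff: int = 10) -> ClinicalTable:
    """Clinical covariates plus survival driven by planted somatic burden."""
    rng = np.random.default_rng(seed)
    if n_tumours is None:
        samples = sorted(set(truth.data["sample"]))
    else:
        samples = [f"T{i + 1:03d}" for i in range(n_tumours)]
    burden = truth.burden_per_sample(samples)
    groups = {
        s: ("none" if burden[s] == 0 else ("high" if burden[s] > high_cutoff else "rest"))
        for s in samples
    }
    months, events = draw_survival(groups, survival_spec, rng)
    grades, g_p = zip(*clinical_spec.grade_probs)
    h3, h_p = zip(*clinical_spec.h3f3a_probs)
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s,
                "who_grade": rng.choice(grades, p=g_p),
                "age_group": "infant" if rng.random() < clinical_spec.infant_prob else "older",
                "prior_rt": bool(rng.random() < clinical_spec.prior_rt_prob),
                "h3f3a": rng.choice(h3, p=h_p),
                "os_months": months[s],
                "os_event": events[s],
                "location": "supratentorial" if rng.random() < 0.9 else "DIPG",
            }
        )
    return ClinicalTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# truth evaluation helpers
# ---------------------------------------------------------------------------

def truth_breaks(truth: TruthTable) -> pd.DataFrame:
    """One row per planted *intragenic* breakpoint (sample, gene, cut)."""
    rows = []
    for _, r in truth.data.iterrows():
        if r["event_class"] == CLASS_FUSION:
            rows.append((r["sample"], r["gene"], r["chrom"], r["break1_bp"], r["event_class"], r["level"]))
            rows.append((r["sample"], r["gene2"], r["chrom"], r["break2_bp"], r["event_class"], r["level"]))
        elif r["event_class"] == CLASS_INTERNAL:
            rows.append((r["sample"], r["gene"], r["chrom"], r["break1_bp"], r["event_class"], r["level"]))
            rows.append((r["sample"], r["gene"], r["chrom"], r["break2_bp"], r["event_class"], r["level"]))
        else:
            rows.append((r["sample"], r["gene"], r["chrom"], r["break1_bp"], r["event_class"], r["level"]))
    return pd.DataFrame(rows, columns=["sample", "gene", "chrom", "cut_bp", "event_class", "level"])


def evaluate_recovery(truth: TruthTable, calls, events) -> pd.DataFrame:
    """Match planted intragenic breaks against pipeline calls and events.

    A break is recovered exactly when some same-sample call's
    flanking-probe gap contains the planted cut (the finest attainable
    localization) and an event links that sample to the right gene; the
    CI covers truth when ``ci_low <= cut <= ci_high``.
    """
    calls_by = {}
    for c in calls:
        calls_by.setdefault((c.sample_id, c.chrom), []).append(c)
    event_keys = {(ev.sample_id, ev.gene_id) for ev in events}
    out = []
    tb = truth_breaks(truth)
    for _, r in tb.iterrows():
        cut = r["cut_bp"]
        exact = covered = False
        nearby = calls_by.get((r["sample"], r["chrom"]), ())
        best = min(nearby, key=lambda c: abs(c.boundary_bp - cut), default=None)
        if best is not None:
            exact = best.left_probe0 < cut <= best.right_probe0
            covered = best.ci_low_bp <= cut <= best.ci_high_bp
        mapped = (r["sample"], r["gene"]) in event_keys
        out.append(
            {
                "sample": r["sample"], "gene": r["gene"], "cut_bp": cut,
                "event_class": r["event_class"], "level": r["level"],
                "called_exact": exact, "ci_covers": covered, "mapped_to_gene": mapped,
                "recovered": exact and mapped,
            }
        )
    return pd.DataFrame(out)


def verify_truth_against_signal(grid: ProbeGrid, truth: TruthTable) -> bool:
    """Noiseless conservation oracle: every planted event is visible in
    the raw signal (probes inside the interval sit at the planted level).

    Only meaningful for ``noise_sd == 0`` cohorts.
    """
    pos0 = grid.pos0()
    for _, r in truth.data.iterrows():
        sl = grid.chrom_slice(r["chrom"])
        j = grid.sample_index(r["sample"])
        mask = (pos0[sl] >= r["interval_start"]) & (pos0[sl] < r["interval_end"])
        vals = grid.values[sl, j][mask]
        if len(vals) == 0 or not np.allclose(vals, r["level"], atol=1e-9):
            return False
        if r["event_class"] == CLASS_GERMLINE:
            jn = grid.sample_index(grid.normal_pairing[r["sample"]])
            valsn = grid.values[sl, jn][mask]
            if not np.allclose(valsn, r["level"], atol=1e-9):
                return False
    return True
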