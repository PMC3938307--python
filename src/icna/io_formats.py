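"""Readers, writers and core containers for the iCNA pipeline.

All genomic intervals are handled internally as 0-based half-open
``[start, end)``.  Probe positions are ingested as 1-based point
coordinates (the convention of SNP-array annotation tables) and exposed
both ways: :attr:`ProbeGrid.pos` keeps the 1-based coordinate as read,
:meth:`ProbeGrid.pos0` converts at the module boundary.  The conversion
is total and invertible (``pos0 = pos - 1``), which confines the classic
off-by-one breakpoint error to a single line of code.

Formats covered: probe-level log2 matrix (TSV), SEG, BED12, refFlat,
DGV-style interval tables, clinical covariate tables, and the pipeline's
own events / candidates / funnel TSVs.  Every writer emits a ``#`` comment
header with the tool version and the parameters used; every reader skips
``#`` lines, so read -> write -> read is a fixed point at the declared
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__version__ = "0.1.0"

logger = logging.getLogger("icna")

SEG_MEAN_DECIMALS = 4

TUMOUR = "tumour"
NORMAL = "normal"

WHO_GRADES = ("III", "IV", "unknown")
AGE_GROUPS = ("infant", "older", "unknown")
H3F3A_STATES = ("K27M", "G34RV", "WT", "unknown")


class FormatError(ValueError):
    """A file violates the declared format or an invariant of its type."""


class ConfigError(ValueError):
    """A parameter combination is invalid."""


def _chrom_key(chrom: str):
    """Natural sort key so chr2 < chr10 (falls back to lexicographic)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


def tool_header(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# icna v{__version__}" + (f" {kv}" if kv else "")


# ---------------------------------------------------------------------------
# ProbeGrid
# ---------------------------------------------------------------------------

@dataclass
class ProbeGrid:
    """Sorted genomic probes with per-sample log2 ratios.

    Parameters
    ----------
    probe_id, chrom, pos :
        Parallel arrays describing the probes; ``pos`` is 1-based.
    values :
        ``(n_probes, n_samples)`` float matrix of log2 ratios.  Missing
        values are NaN — never silently zero.
    sample_ids :
        Column order of ``values``.
    sample_role :
        ``tumour`` / ``normal`` per sample.
    normal_pairing :
        Optional map tumour id -> matched normal id.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    sample_role: dict[str, str]
    normal_pairing: dict[str, str] | None = None

    def __post_init__(self):
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.pos), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pos)} probes x {len(self.sample_ids)} samples"
            )
        order = self._sort_order()
        if not np.array_equal(order, np.arange(len(order))):
            logger.info("probe grid re-sorted into genomic order")
            self.probe_id = self.probe_id[order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.values = self.values[order]
        self._validate()
        self._chrom_slices = self._build_slices()

    def _sort_order(self) -> np.ndarray:
        keys = [_chrom_key(c) for c in self.chrom]
        return np.array(
            sorted(
                range(len(self.pos)),
                key=lambda i: (keys[i], self.pos[i], str(self.probe_id[i])),
            )
        )

    def _validate(self):
        seen = set()
        for c, p, pid in zip(self.chrom, self.pos, self.probe_id):
            if (c, p) in seen:
                raise FormatError(f"duplicate probe coordinate {c}:{p} (probe {pid})")
            seen.add((c, p))
        roles = set(self.sample_role.get(s) for s in self.sample_ids)
        if not roles <= {TUMOUR, NORMAL}:
            raise FormatError(f"sample roles must be tumour/normal, got {roles}")
        if self.normal_pairing:
            for t, n in self.normal_pairing.items():
                if t not in self.sample_ids or n not in self.sample_ids:
                    raise FormatError(f"pairing {t}->{n} references unknown sample")
                if self.sample_role[n] != NORMAL:
                    raise FormatError(f"paired sample {n} is not a normal")

    def _build_slices(self) -> dict[str, slice]:
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                slices[str(self.chrom[start])] = slice(start, i)
                start = i
        return slices

    # -- accessors ---------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.pos)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    def pos0(self) -> np.ndarray:
        """Probe positions as 0-based point coordinates."""
        return self.pos - 1

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_role[s] == role]

    def sample_chrom(self, sample_id: str, chrom: str):
        """(positions, values) for one sample on one chromosome, NaN dropped.

        Returns 1-based positions; the count of dropped probes is logged.
        """
        sl = self.chrom_slice(chrom)
        v = self.values[sl, self.sample_index(sample_id)]
        p = self.pos[sl]
        ok = np.isfinite(v)
        dropped = int((~ok).sum())
        if dropped:
            logger.info("%s/%s: dropped %d probes with missing log2", sample_id, chrom, dropped)
        return p[ok], v[ok]

    def covered_genome_length(self) -> int:
        """Sum over chromosomes of the probe-covered span (bp)."""
        total = 0
        for c in self.chroms:
            sl = self.chrom_slice(c)
            total += int(self.pos[sl].max() - self.pos[sl].min())
        return total


def read_probe_matrix(path, role_map: Mapping[str, str]) -> ProbeGrid:
    """Read a tab-separated probe x sample log2 matrix.

    The file must have columns ``probe_id``, ``chrom``, ``pos`` followed by
    one column per sample.  ``role_map`` assigns tumour/normal to each
    sample column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "pos"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in required]
    values = np.empty((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
            & (~raw.astype(str).str.upper().isin(["NA", "NAN"]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric log2 value {raw.iloc[row]!r} at row {row + 1}, column {col!r}"
            )
        values[:, j] = num.to_numpy(dtype=float)
    return ProbeGrid(
        probe_id=df["probe_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        values=values,
        sample_ids=sample_cols,
        sample_role=dict(role_map),
    )


def write_probe_matrix(grid: ProbeGrid, path) -> None:
    meta = pd.DataFrame({"probe_id": grid.probe_id, "chrom": grid.chrom, "pos": grid.pos})
    vals = pd.DataFrame(grid.values, columns=grid.sample_ids)
    df = pd.concat([meta, vals], axis=1)
    with open(path, "w") as fh:
        fh.write(tool_header(format="probe_matrix") + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene locus with strand-aware exon numbering (0-based half-open).

    ``exons`` are stored in genomic order; exon 1 is the 5'-most exon in
    transcription order, i.e. the genomically *last* block of a
    minus-strand gene.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise FormatError(f"{self.gene_id}: tx_end must exceed tx_start")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise FormatError(f"{self.gene_id}: exon ({s},{e}) outside tx bounds")
            if s <= prev_end:
                raise FormatError(f"{self.gene_id}: exons overlap or unsorted at ({s},{e})")
            prev_end = e

    @property
    def size(self) -> int:
        """Genomic footprint used for break-rate statistics."""
        return self.tx_end - self.tx_start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_by_rank(self) -> list[tuple[int, int, int]]:
        """(rank, start, end) with rank 1 = 5'-most exon in transcription order."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        return [(i + 1, s, e) for i, (s, e) in enumerate(order)]

    def contains(self, point0: int) -> bool:
        return self.tx_start <= point0 < self.tx_end


def _parse_bed12_line(fields: Sequence[str]) -> GeneModel:
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise FormatError(f"{name}: blockCount does not match block lists")
    exons = tuple((start + s, start + s + z) for s, z in zip(starts, sizes))
    return GeneModel(name, chrom, strand, start, end, exons)


def _parse_refflat_line(fields: Sequence[str]) -> GeneModel:
    # geneName txName chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds
    name, chrom, strand = fields[0], fields[2], fields[3]
    start, end = int(fields[4]), int(fields[5])
    starts = [int(x) for x in fields[9].rstrip(",").split(",")]
    ends = [int(x) for x in fields[10].rstrip(",").split(",")]
    exons = tuple(zip(starts, ends))
    return GeneModel(name, chrom, strand, start, end, exons)


def read_gene_models(path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or refFlat tables (both 0-based half-open)."""
    if dialect not in ("bed12", "refflat"):
        raise ConfigError(f"unknown gene-model dialect {dialect!r}")
    parse = _parse_bed12_line if dialect == "bed12" else _parse_refflat_line
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            genes.append(parse(line.split("\t")))
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="bed12") + "\n")
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.tx_start), str(g.tx_end), g.gene_id, "0",
                        g.strand, str(g.tx_start), str(g.tx_end), "0",
                        str(g.n_exons), sizes, starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------

class IntervalSet:
    """Named collection of genomic intervals with sub-linear point/range query."""

    def __init__(self, name: str, intervals: Iterable[tuple] = ()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            label = iv[3] if len(iv) > 3 else None
            self.add(chrom, start, end, label)

    def add(self, chrom: str, start: int, end: int, label=None):
        if start >= end:
            raise FormatError(f"{self.name}: interval start {start} >= end {end} on {chrom}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def containing(self, chrom: str, point0: int) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.at(point0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._trees, key=_chrom_key):
            for iv in sorted(self._trees[chrom]):
                rows.append((chrom, iv.begin, iv.end, iv.data))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def read_interval_regions(path, name: str = "regions", one_based_inclusive: bool = False) -> IntervalSet:
    """Read a DGV-style interval table (chrom, start, end[, id]).

    The declared convention is 0-based half-open; pass
    ``one_based_inclusive=True`` to convert 1-based fully-closed input
    (start -> start-1, end unchanged).
    """
    ivs = IntervalSet(name)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if one_based_inclusive:
                start -= 1
            label = f[3] if len(f) > 3 else None
            ivs.add(chrom, start, end, label)
    return ivs


def write_interval_regions(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="intervals", name=ivs.name) + "\n")
        for _, row in ivs.to_frame().iterrows():
            label = "" if row["label"] is None else f"\t{row['label']}"
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}{label}\n")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample clinical covariates (grades, age group, H3F3A, survival)."""

    data: pd.DataFrame

    COLUMNS = (
        "sample_id", "who_grade", "age_group", "prior_rt", "h3f3a",
        "os_months", "os_event", "location",
    )

    def __post_init__(self):
        df = self.data
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        for col, allowed in [("who_grade", WHO_GRADES), ("age_group", AGE_GROUPS), ("h3f3a", H3F3A_STATES)]:
            bad = set(df[col].astype(str)) - set(allowed)
            if bad:
                raise FormatError(
                    f"invalid {col} value(s) {sorted(bad)}; allowed: {list(allowed)}"
                )
        has_event = df["os_event"].notna()
        if (has_event & df["os_months"].isna()).any():
            s = df.loc[has_event & df["os_months"].isna(), "sample_id"].iloc[0]
            raise FormatError(f"sample {s!r} has os_event without os_months")
        if (df["os_months"].dropna() < 0).any():
            raise FormatError("negative os_months")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "who_grade": str, "age_group": str, "h3f3a": str, "location": str},
    )
    for col in ("prior_rt", "os_event"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda x: x if pd.isna(x) else str(x).strip().lower() in ("1", "true", "yes")
            )
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="clinical") + "\n")
        table.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG / events / candidates / funnel writers
# ---------------------------------------------------------------------------

def write_seg(segments, path, **params) -> None:
    """Write segments in the standard 6-column SEG layout.

    ``segments`` is any iterable of objects with sample_id, chrom,
    start_bp, end_bp, n_probes and mean_log2 attributes (start/end are
    written as the ingested 1-based probe coordinates spanning the
    segment).  seg_mean is printed at 4 decimals; rows are ordered by
    (sample, chrom, start).
    """
    rows = sorted(
        segments,
        key=lambda s: (s.sample_id, _chrom_key(s.chrom), s.start_bp),
    )
    with open(path, "w") as fh:
        fh.write(tool_header(format="seg", **params) + "\n")
        fh.write("sample\tchrom\tstart\tend\tnum_probes\tseg_mean\n")
        for s in rows:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.n_probes}\t{s.mean_log2:.{SEG_MEAN_DECIMALS}f}\n"
            )


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "chrom": str})
    return df


def format_filter_status(status: list[tuple[str, str, str]]) -> str:
    return ";".join(
        f"{stage}:{verdict}" + (f"({reason})" if reason else "")
        for stage, verdict, reason in status
    )


def parse_filter_status(text: str) -> list[tuple[str, str, str]]:
    out = []
    if not text or (isinstance(text, float) and np.isnan(text)):
        return out
    for item in str(text).split(";"):
        stage, rest = item.split(":", 1)
        if "(" in rest:
            verdict, reason = rest.split("(", 1)
            reason = reason.rstrip(")")
        else:
            verdict, reason = rest, ""
        out.append((stage, verdict, reason))
    return out


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        for bp in ev.breakpoints:
            rows.append(
                {
                    "sample": ev.sample_id,
                    "gene": ev.gene_id,
                    "chrom": bp.chrom,
                    "boundary_bp": bp.boundary_bp,
                    "ci_low_bp": bp.ci_low_bp,
                    "ci_high_bp": bp.ci_high_bp,
                    "delta_log2": bp.delta_log2,
                    "probes_gap_bp": bp.probes_gap_bp,
                    "high_confidence": bp.high_confidence,
                    "direction": ev.direction,
                    "truncation_class": ev.truncation_class,
                    "level": ev.level,
                    "event_high_confidence": ev.high_confidence,
                    "filter_status": format_filter_status(ev.filter_status),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "gene", "chrom", "boundary_bp", "ci_low_bp", "ci_high_bp",
            "delta_log2", "probes_gap_bp", "high_confidence", "direction",
            "truncation_class", "level", "event_high_confidence", "filter_status",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["sample", "chrom", "boundary_bp", "gene"],
            key=lambda col: col.map(_chrom_key) if col.name == "chrom" else col,
        ).reset_index(drop=True)
    return df


def write_events_tsv(events, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="events", **params) + "\n")
        events_to_frame(events).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "gene": str, "chrom": str})
    df["filter_status_parsed"] = df["filter_status"].map(parse_filter_status)
    return df


def funnel_counts_from_events_frame(df: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Recompute (events_in, events_out) per stage from a re-read events table.

    Events are counted at the (sample, gene, direction, boundary set)
    grain used by the funnel, i.e. one row group per event.
    """
    counts: dict[str, list[int]] = {}
    groups = df.groupby(["sample", "gene", "direction", "truncation_class", "filter_status"], sort=False)
    for (_, _, _, _, status_text), _grp in groups:
        for stage, verdict, _reason in parse_filter_status(status_text):
            pair = counts.setdefault(stage, [0, 0])
            pair[0] += 1
            if verdict == "pass":
                pair[1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def write_funnel_tsv(report, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="funnel", **params) + "\n")
        fh.write("stage\tevents_in\tevents_out\tn_excluded\n")
        for st in report.stages:
            fh.write(f"{st.name}\t{st.events_in}\t{st.events_out}\t{len(st.excluded)}\n")


def read_funnel_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_candidates_tsv(candidates, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="fusion_candidates", **params) + "\n")
        fh.write(
            "sample\tgene_5p\tgene_3p\tlevel_5p\tlevel_3p\tlevel_difference\t"
            "genomic_span_bp\tretained_exons_5p\tretained_exons_3p\tcomplexity\n"
        )
        rows = sorted(candidates, key=lambda c: (c.sample_id, c.gene_5p, c.gene_3p))
        for c in rows:
            fh.write(
                f"{c.sample_id}\t{c.gene_5p}\t{c.gene_3p}\t{c.level_5p:.4f}\t"
                f"{c.level_3p:.4f}\t{c.level_difference:.4f}\t{c.genomic_span_bp}\t"
                f"{c.retained_exons_5p}\t{c.retained_exons_3p}\t{c.complexity_flag}\n"
            )


def write_burden_tsv(burden_frame: pd.DataFrame, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(tool_header(format="burden", **params) + "\n")
        burden_frame.to_csv(fh, sep="\t", index=False)
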