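"""One-command orchestration: simulate -> segment -> call -> filter ->
classify -> fusions -> cohort stats, with a provenance manifest.

A run is a pure function of its :class:`PipelineConfig` and inputs: a
single master seed fans out into per-stage, per-sample substreams, the
manifest records parameters and SHA-256 checksums of every input and
output, and rerunning with identical config and inputs reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats as iof
from .cohort_analysis import count_events_per_sample, survival_stratification
from .event_classification import nominate_fusions, predict_fusion_structure
from .filter_cascade import FunnelParams, run_funnel
from .icna_detection import (
    adjust_pvalues, attach_confidence_intervals, call_breakpoints,
    gene_break_statistic, map_breaks_to_genes,
)
from .io_formats import ConfigError, IntervalSet
from .segmentation import segment_cohort
from .synthetic_cohort import SimConfig, sim_config_from_dict, simulate_cohort, simulate_survival

logger = logging.getLogger("icna")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulate stage (None -> load from paths instead)
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    probe_matrix_path: str | None = None
    role_map: dict = field(default_factory=dict)
    gene_models_path: str | None = None
    gene_models_dialect: str = "bed12"
    cnv_regions_path: str | None = None
    clinical_path: str | None = None
    # segmentation
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    # breakpoint calling
    delta: float = 0.4
    window_probes: int = 20
    n_boot: int = 200
    # statistics
    correction: str = "bh"
    recurrence: bool = True
    # funnel
    sig_threshold: float = 0.05
    cnv_mode: str = "ci"
    direction_agnostic_normals: bool = False
    max_gap_bp: int = 100_000
    min_flank_probes: int = 3
    flank_bp: int = 50_000
    # fusion nomination
    amp_threshold: float = 0.8
    level_tol: float = 0.3
    max_span_bp: int = 10_000_000
    require_contiguous: bool = True
    # cohort analysis
    high_cutoff: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)


@dataclass
class PipelineResult:
    grid: object
    genes: list
    cnv: IntervalSet
    truth: object | None
    clinical: object | None
    segments: object
    calls: list
    normal_calls: list
    events: list
    normal_events: list
    intergenic_calls: list
    stats: list
    final_events: list
    funnel: object
    candidates: list
    burden: object
    survival: object | None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(config: PipelineConfig) -> SimConfig:
    base = SimConfig(rng_seed=config.seed)
    if config.sim_overrides:
        base = sim_config_from_dict(config.sim_overrides, base=base)
    return base


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run every stage in order and write all outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "icna", "version": iof.__version__,
                      "parameters": config.to_dict(), "stages": {}, "inputs": {}, "outputs": {}}

    # ---- inputs ----------------------------------------------------------
    truth = clinical = None
    try:
        if config.simulate:
            sim = _sim_config(config)
            grid, genes, cnv, truth = simulate_cohort(sim)
            clinical = simulate_survival(
                truth, sim.clinical_spec, sim.survival_spec,
                seed=np.random.SeedSequence(config.seed, spawn_key=(901,)),
                n_tumours=sim.n_tumours, high_cutoff=config.high_cutoff,
            )
            iof.write_probe_matrix(grid, outdir / "probes.tsv")
            iof.write_gene_models_bed12(genes, outdir / "genes.bed")
            iof.write_interval_regions(cnv, outdir / "cnv_regions.tsv")
            iof.write_clinical_table(clinical, outdir / "clinical.tsv")
            truth.data.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        else:
            if not config.probe_matrix_path:
                raise StageError("inputs", "probe_matrix_path required when simulate=False")
            grid = iof.read_probe_matrix(config.probe_matrix_path, config.role_map)
            manifest["inputs"]["probe_matrix"] = _sha256(Path(config.probe_matrix_path))
            if not config.gene_models_path:
                raise StageError("call-breaks", "gene_models_path is required")
            genes = iof.read_gene_models(config.gene_models_path, config.gene_models_dialect)
            manifest["inputs"]["gene_models"] = _sha256(Path(config.gene_models_path))
            if config.cnv_regions_path:
                cnv = iof.read_interval_regions(config.cnv_regions_path, "germline_cnv")
                manifest["inputs"]["cnv_regions"] = _sha256(Path(config.cnv_regions_path))
            else:
                cnv = IntervalSet("germline_cnv")
            if config.clinical_path:
                clinical = iof.read_clinical_table(config.clinical_path)
                manifest["inputs"]["clinical"] = _sha256(Path(config.clinical_path))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("inputs", str(exc)) from exc

    tumours = grid.samples_with_role(iof.TUMOUR)
    normals = grid.samples_with_role(iof.NORMAL)
    manifest["stages"]["inputs"] = {"n_tumours": len(tumours), "n_normals": len(normals),
                                    "n_probes": grid.n_probes, "n_genes": len(genes)}

    # ---- segmentation ----------------------------------------------------
    try:
        segments = segment_cohort(grid, alpha=config.alpha, n_perm=config.n_perm,
                                  min_width=config.min_width, seed=config.seed)
        iof.write_seg(segments.segments, outdir / "segments.seg",
                      alpha=config.alpha, n_perm=config.n_perm,
                      min_width=config.min_width, seed=config.seed)
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment", str(exc)) from exc
    manifest["stages"]["segment"] = {"n_segments": len(segments.segments)}

    # ---- breakpoint calling + mapping -----------------------------------
    try:
        all_calls = call_breakpoints(segments, delta=config.delta)
        attach_confidence_intervals(grid, all_calls, window_probes=config.window_probes,
                                    n_boot=config.n_boot, seed=config.seed)
        baselines = {s: segments.sample_baseline(s) for s in grid.sample_ids}
        calls = [c for c in all_calls if c.sample_id in set(tumours)]
        normal_calls = [c for c in all_calls if c.sample_id in set(normals)]
        events, intergenic = map_breaks_to_genes(calls, genes, baselines=baselines)
        normal_events, _ = map_breaks_to_genes(normal_calls, genes, baselines=baselines)
    except Exception as exc:  # noqa: BLE001
        raise StageError("call-breaks", str(exc)) from exc
    manifest["stages"]["call-breaks"] = {
        "n_tumour_calls": len(calls), "n_normal_calls": len(normal_calls),
        "n_events": len(events), "n_intergenic": len(intergenic),
    }

    # ---- statistics ------------------------------------------------------
    try:
        stats = gene_break_statistic(events, intergenic, genes, n_samples=len(tumours),
                                     genome_length=grid.covered_genome_length(),
                                     recurrence=config.recurrence)
        stats = adjust_pvalues(stats, method=config.correction)
    except Exception as exc:  # noqa: BLE001
        raise StageError("statistics", str(exc)) from exc
    manifest["stages"]["statistics"] = {
        "n_significant_genes": sum(1 for s in stats if s.q is not None and s.q < config.sig_threshold)
    }

    # ---- funnel ----------------------------------------------------------
    try:
        params = FunnelParams(
            sig_threshold=config.sig_threshold, cnv_mode=config.cnv_mode,
            direction_agnostic_normals=config.direction_agnostic_normals,
            max_gap_bp=config.max_gap_bp, min_flank_probes=config.min_flank_probes,
            flank_bp=config.flank_bp,
        )
        final_events, funnel = run_funnel(events, cnv, normal_events, stats,
                                          params=params, grid=grid, genes=genes)
        # written post-funnel so every event row carries its full filter trail
        iof.write_events_tsv(events, outdir / "events_raw.tsv", delta=config.delta)
        iof.write_events_tsv(final_events, outdir / "events_final.tsv")
        iof.write_funnel_tsv(funnel, outdir / "funnel.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", str(exc)) from exc
    manifest["stages"]["filter"] = {"counts": funnel.counts()}

    # ---- fusion nomination ----------------------------------------------
    try:
        candidates = nominate_fusions(final_events, segments,
                                      amp_threshold=config.amp_threshold,
                                      level_tol=config.level_tol,
                                      max_span_bp=config.max_span_bp,
                                      require_contiguous=config.require_contiguous)
        gene_models = {g.gene_id: g for g in genes}
        for cand in candidates:
            predict_fusion_structure(cand, gene_models)
        iof.write_candidates_tsv(candidates, outdir / "candidates.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("nominate-fusions", str(exc)) from exc
    manifest["stages"]["nominate-fusions"] = {"n_candidates": len(candidates)}

    # ---- cohort analysis -------------------------------------------------
    survival = None
    try:
        burden = count_events_per_sample(final_events, tumours, high_cutoff=config.high_cutoff)
        iof.write_burden_tsv(burden.data, outdir / "burden.tsv", high_cutoff=config.high_cutoff)
        if clinical is not None:
            survival = survival_stratification(burden, clinical)
            km = survival.km_curves
            with open(outdir / "km_curves.tsv", "w") as fh:
                fh.write(iof.tool_header(format="km_curves") + "\n")
                km.to_csv(fh, sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cohort-stats", str(exc)) from exc
    manifest["stages"]["cohort-stats"] = {
        "median_burden": float(burden.data["n_icna"].median()),
        "max_burden": int(burden.data["n_icna"].max()),
        "logrank_p": None if survival is None else survival.p,
    }

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        grid=grid, genes=genes, cnv=cnv, truth=truth, clinical=clinical,
        segments=segments, calls=calls, normal_calls=normal_calls, events=events,
        normal_events=normal_events, intergenic_calls=intergenic, stats=stats,
        final_events=final_events, funnel=funnel, candidates=candidates,
        burden=burden, survival=survival,
    )
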