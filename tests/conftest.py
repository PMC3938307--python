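import dataclasses

import numpy as np
import pytest

from icna.io_formats import ProbeGrid
from icna.pipeline import PipelineConfig, run_pipeline
from icna.synthetic_cohort import (
    ClinicalSpec, EventSpec, GermlineCNVSpec, SimConfig, simulate_cohort,
)


def small_sim_overrides(noise_sd: float = 0.15, seed: int = 7) -> dict:
    """A scaled-down cohort exercising every planted event class."""
    return dict(
        n_tumours=12,
        n_normals=4,
        chrom_lengths=tuple((f"chr{i}", 1_200_000) for i in range(1, 4)),
        n_genes=12,
        noise_sd=noise_sd,
        planted_event_spec=(
            EventSpec("3prime_loss", 8, -2.0, -0.8, 3),
            EventSpec("internal_deletion", 4, -2.0, -0.8, 2),
            EventSpec("amplicon_flank_5p", 3, 0.9, 2.5, 1),
            EventSpec("amplicon_flank_3p", 3, 0.9, 2.5, 1),
            EventSpec("fusion_pair", 2, 0.9, 2.5, 2),
        ),
        germline_cnv_spec=GermlineCNVSpec(
            n_regions=1, n_uncatalogued=1, n_pairs_per_region=2, n_decoy_regions=1
        ),
        clinical_spec=ClinicalSpec(prop_none=0.09, prop_high=0.09, high_burden_range=(4, 5)),
        rng_seed=seed,
    )


def small_sim_config(noise_sd: float = 0.15, seed: int = 7) -> SimConfig:
    return SimConfig(**small_sim_overrides(noise_sd=noise_sd, seed=seed))


@pytest.fixture(scope="session")
def small_cohort():
    """(grid, genes, cnv, truth) for the scaled-down noisy cohort."""
    return simulate_cohort(small_sim_config())


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(small_sim_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline result on the scaled-down cohort (shared across tests)."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(seed=7, sim_overrides=small_sim_overrides(), n_perm=400, n_boot=100)
    return run_pipeline(cfg, out), out, cfg


def single_sample_grid(values, spacing: int = 5_000, chrom: str = "chr1",
                       sample: str = "S1") -> ProbeGrid:
    """A one-sample ProbeGrid on a regular grid, for segmentation tests."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    pos = (np.arange(n) * spacing + spacing // 2 + 1).astype(np.int64)
    return ProbeGrid(
        np.array([f"p{i}" for i in range(n)], dtype=object),
        np.array([chrom] * n, dtype=object),
        pos,
        values[:, None],
        [sample],
        {sample: "tumour"},
    )
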