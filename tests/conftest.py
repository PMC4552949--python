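"""Shared fixtures: small planted worlds and one full pipeline run."""
from __future__ import annotations

import pytest

from lsgscan import SyntheticWorldConfig, generate_world, run_pipeline


@pytest.fixture(scope="session")
def zero_world_cfg() -> SyntheticWorldConfig:
    """Zero-divergence study world: homologs are exact copies, so every
    downstream label is exactly recoverable."""
    return SyntheticWorldConfig(
        seed=101,
        n_genes_per_class=(8, 8, 8),
        n_species_per_clade=(2, 2, 2, 2),
        genome_size=60_000,
        n_retrogenes=3,
        n_chimeras=2,
        mutation_rates=(0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def zero_world(zero_world_cfg, tmp_path_factory):
    return generate_world(zero_world_cfg, tmp_path_factory.mktemp("zero_world"))


@pytest.fixture(scope="session")
def zero_run(zero_world_cfg, tmp_path_factory):
    """Full pipeline results on the zero-divergence world."""
    return run_pipeline(
        tmp_path_factory.mktemp("zero_run"),
        synthetic_seed=zero_world_cfg.seed,
        world_config=zero_world_cfg,
    )


@pytest.fixture(scope="session")
def tiny_world_cfg() -> SyntheticWorldConfig:
    """Smallest world that still exercises every construct; for determinism
    and file-format tests."""
    return SyntheticWorldConfig(
        seed=7,
        n_genes_per_class=(4, 3, 3),
        n_species_per_clade=(1, 1, 1, 1),
        genome_size=25_000,
        n_retrogenes=1,
        n_chimeras=1,
        n_te_origin=1,
        n_dup_origin=1,
        n_both_origin=1,
        mutation_rates=(0.02, 0.1, 0.2, 0.3),
    )
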