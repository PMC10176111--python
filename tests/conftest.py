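"""Shared fixtures: small simulated studies and handcrafted SAM files."""

from __future__ import annotations

import pytest

from tepi import SimConfig, simulate_annotation, simulate_counts

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrA\tLN:100000\n@SQ\tSN:chrB\tLN:50000\n"


def make_sam(path, records: list[str], header: str = SAM_HEADER) -> str:
    """Write a SAM file from raw record lines (tab-joined strings)."""
    with open(path, "w") as fh:
        fh.write(header)
        for rec in records:
            fh.write(rec + "\n")
    return str(path)


def small_sim_config(**overrides) -> SimConfig:
    """A reduced study: same structure, fewer features, faster draws."""
    defaults = dict(
        seed=42,
        chromosomes={"chrA": 250_000, "chrB": 200_000},
        repeat_counts={"LTR/Gypsy": 40, "LTR/Pao": 15, "LINE/Jockey": 25, "Simple_repeat": 120},
        n_genes=20,
        te_in_expressed_gene=3,
        te_in_unexpressed_gene_activated=3,
        te_in_unexpressed_gene_silent=4,
        precursors_per_cluster=15,
        n_precursors_outside=60,
        replicates={"WT_b1": 4, "WT_b2": 4, "H3K36K": 3,
                    "H3K36R": 4, "Set2KO": 4, "NSDKO": 4, "ash1KO": 4},
        n_batch_inconsistent=10,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_bundle):
    counts, truth = simulate_counts(small_config, small_bundle)
    return small_bundle, counts, truth
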