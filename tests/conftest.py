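"""Shared fixtures: scaled-down synthetic datasets with planted ground truth.

Everything is generated programmatically and seeded; module-scoped fixtures
keep the suite fast by reusing one simulation across related tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sctotal import feature_counting as fc
from sctotal.synthetic_data import (
    SyntheticConfig,
    make_annotation,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Scaled-down, error-free study conditions for exact truth accounting."""
    return SyntheticConfig(
        seed=11,
        n_real_cells=60,
        n_ambient_barcodes=40,
        cell_log10_reads_mean=2.9,
        cell_log10_reads_sd=0.12,
        ambient_log10_reads_mean=1.0,
        ambient_log10_reads_sd=0.2,
        error_rate=0.0,
        doublet_fraction=0.0,
    )


@pytest.fixture(scope="session")
def annotation(small_config):
    return make_annotation(small_config)


@pytest.fixture(scope="session")
def reads_and_truth(annotation, small_config):
    return simulate_reads(annotation, small_config)


@pytest.fixture(scope="session")
def assigned_reads(reads_and_truth, annotation):
    reads, truth = reads_and_truth
    cell_reads = reads[reads["barcode"].isin(truth.barcode_to_cell)]
    survivors, _ = fc.deplete_rrna(cell_reads, annotation.rrna_intervals())
    return fc.assign_reads(survivors, annotation), truth


@pytest.fixture(scope="session")
def count_matrix(assigned_reads, annotation):
    assigned, truth = assigned_reads
    propagated = fc.propagate_unspliced(assigned)
    propagated = propagated.assign(
        barcode=propagated["barcode"].map(truth.barcode_to_cell)
    )
    cells = sorted(set(truth.barcode_to_cell.values()))
    return fc.count_molecules(propagated, annotation, cells=cells), truth


def toy_gene(gene_id="G1", biotype="protein_coding", strand="+",
             exons=((100, 200), (300, 400)), **kw) -> fc.Gene:
    return fc.Gene(gene_id, gene_id.lower(), biotype, "chr1", strand, tuple(exons), **kw)
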