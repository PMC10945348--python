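import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from immunosig.io_formats import BulkCohort, ExpressionMatrix, GeneSignature
from immunosig.synthetic_data import CnvSegment, SynthConfig, gen_single_cell


@pytest.fixture(scope="session")
def small_sc_config() -> SynthConfig:
    return SynthConfig(
        seed=11,
        n_patients_per_group={"PD-pre": 2, "NPD-pre": 2, "NPD-post": 1},
        cells_per_patient=120,
        n_genes=400,
        n_mito_genes=5,
        n_chromosomes=4,
        cnv_segments=[CnvSegment("1", 10, 50, 2.0)],
    )


@pytest.fixture(scope="session")
def small_sc_data(small_sc_config):
    """(ExpressionMatrix, cell annotation, gene annotation) at fixture scale."""
    return gen_single_cell(small_sc_config)


@pytest.fixture(scope="session")
def small_lognorm(small_sc_data, small_sc_config):
    from immunosig.sc_core import normalize_lognorm, qc_filter

    matrix, cell_ann, gene_ann = small_sc_data
    filtered, _, _ = qc_filter(matrix, gene_ann, min_genes=10, max_genes=6000)
    lognorm = normalize_lognorm(filtered)
    labels = cell_ann.set_index("cell_id").reindex(lognorm.cell_ids)
    return lognorm, labels, gene_ann


def random_expression_matrix(seed: int, n_genes: int = 20, n_cells: int = 15):
    rng = np.random.default_rng(seed)
    dense = rng.poisson(1.0, size=(n_genes, n_cells))
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        counts=sp.csr_matrix(dense),
    )


def make_bulk_cohort(
    seed: int,
    n_samples: int = 60,
    n_genes: int = 50,
    effect_genes=(),
    delta: float = 0.0,
    batches=("b1",),
) -> BulkCohort:
    """Hand-rolled bulk cohort independent of the synthetic_data module."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    response = np.where(np.arange(n_samples) % 2 == 0, "NPD", "PD")
    expr = rng.normal(size=(n_samples, n_genes))
    idx = [genes.index(g) for g in effect_genes]
    expr[np.ix_(response == "NPD", idx)] += delta
    batch = np.array([batches[i % len(batches)] for i in range(n_samples)])
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "response": response,
            "batch": batch,
            "os_time": rng.exponential(20, n_samples),
            "os_event": rng.integers(0, 2, n_samples),
        },
        index=samples,
    )
    return BulkCohort(
        expression=pd.DataFrame(expr, index=samples, columns=genes),
        clinical=clinical,
    )


@pytest.fixture
def four_marker_sets():
    return {
        "MM.sig": GeneSignature("G_MM", tuple(f"g{i}" for i in range(0, 10))),
        "B.sig": GeneSignature("G_B", tuple(f"g{i}" for i in range(10, 20))),
        "DC.sig": GeneSignature("G_DC", tuple(f"g{i}" for i in range(20, 30))),
        "CAF.sig": GeneSignature("G_CAF", tuple(f"g{i}" for i in range(30, 40))),
    }
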