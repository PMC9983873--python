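import pandas as pd
import pytest

from metscreen import (
    SimulationConfig,
    assemble_trios,
    call_all,
    cpm_normalize,
    simulate_trios,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact matched-trio simulation shared across tests."""
    cfg = SimulationConfig(
        n_cases=8, n_genes=1000, n_up_spiked=30, n_down_spiked=30, seed=11
    )
    return simulate_trios(cfg)


@pytest.fixture(scope="session")
def small_calls(small_sim):
    matrix, annot, truth = small_sim
    trios = assemble_trios(matrix, annot)
    norm = cpm_normalize(matrix)
    return call_all(norm, trios), norm, trios, truth


def make_matrix(values, gene_ids=None, sample_ids=None):
    """Small helper: build an ExpressionMatrix from a nested list."""
    from metscreen import ExpressionMatrix

    n_genes = len(values)
    n_samples = len(values[0]) if n_genes else 0
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids, dtype=float)
    )
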