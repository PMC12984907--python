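import numpy as np
import pandas as pd
import pytest

from redrug import simulate


@pytest.fixture(scope="session")
def demo_data():
    """Standard demo cohort, unstratified (one 100-sample stratum)."""
    cfg = simulate.demo_config(seed=1, hpv_positive_fraction=0.0)
    return simulate.simulate_all(cfg)


@pytest.fixture(scope="session")
def null_cnv():
    """Pure-null copy-number cohort: no planted alterations."""
    cfg = simulate.SimulationConfig(seed=7, n_genes=300, n_samples=100,
                                    hpv_positive_fraction=0.0)
    df, truth = simulate.simulate_cnv_cohort(cfg)
    assert truth["amplified"] == [] and truth["deleted"] == []
    return df


def long_cnv(copy_numbers, gene="G1"):
    """One-gene long-format table from a list of per-sample copy numbers."""
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(copy_numbers))],
            "gene": gene,
            "copy_number": copy_numbers,
        }
    )


def multi_gene_cnv(matrix, genes=None):
    """Long-format table from an (n_samples, n_genes) integer matrix."""
    matrix = np.asarray(matrix)
    n_samples, n_genes = matrix.shape
    genes = genes or [f"G{j}" for j in range(n_genes)]
    return pd.DataFrame(
        {
            "sample_id": np.repeat([f"S{i}" for i in range(n_samples)], n_genes),
            "gene": np.tile(genes, n_samples),
            "copy_number": matrix.ravel(),
        }
    )
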