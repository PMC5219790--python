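import numpy as np
import pytest

from scgxe.qc import ExpressionMatrix, tpm_normalize
from scgxe.simulate import simulate_experiment, study_config


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured experiment shared by read-only tests."""
    return simulate_experiment(
        study_config(seed=42, n_chips=4, cells_per_chip=24, n_genes=300,
                     single_time=True)
    )


@pytest.fixture(scope="session")
def small_tpm(small_sim):
    return tpm_normalize(small_sim.expression, small_sim.gene_lengths)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_expression(values, unit="counts"):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, unit=unit)
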