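import numpy as np
import pandas as pd
import pytest

from ador import AgeSeries, simulate_expression_study


@pytest.fixture(scope="session")
def decade_ages():
    return np.arange(20.0, 81.0, 10.0)


@pytest.fixture(scope="session")
def linear_series(decade_ages):
    """Values exactly 2*age + 1 at the decade ages."""
    return AgeSeries(decade_ages, 2 * decade_ages + 1, label="linear")


@pytest.fixture(scope="session")
def planted_study():
    """Two planted 40-gene clusters, 10 noise genes, a coupled and an
    uncoupled receptor, tumor upshift on both receptors; 200 samples."""
    study, truth = simulate_expression_study(
        cluster_sizes=(40, 40),
        n_noise_genes=10,
        n_samples=200,
        receptor_couplings={"RCPA": ("C1", 1.0, 0.5), "RCPB": ("C2", 0.0, 1.0)},
        condition_log2fc={"RCPA": 1.2, "RCPB": 1.2},
        seed=11,
    )
    return study, truth


@pytest.fixture(scope="session")
def annotations():
    return pd.DataFrame({
        "ligand": ["LIG_A", "LIG_B"],
        "receptor": ["RCPA", "RCPB"],
        "bloodborne": [True, True],
    })
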