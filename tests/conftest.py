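import numpy as np
import pandas as pd
import pytest

from ripenet.synthetic import GeneGroupSpec, SimulationSpec


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """Compact three-cluster population used across module tests."""
    return SimulationSpec(
        n_lines=48,
        n_traits=12,
        n_genes=300,
        gene_groups=(
            GeneGroupSpec("G1", 30, "I", +1),
            GeneGroupSpec("G2", 30, "II", +1),
            GeneGroupSpec("G3", 30, "III", -1),
        ),
        annotation_depth=3,
        n_top_bins=4,
        bin_branching=2,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def noise_free_spec(small_spec) -> SimulationSpec:
    """Deterministic-structure variant: perfect associations, no residual noise."""
    from dataclasses import replace

    return replace(small_spec, association_strength=1.0, sigma2_E=0.0)


@pytest.fixture()
def worked_anova_table() -> pd.DataFrame:
    """Two lines x two replicates with MSB=16, MSW=2 by hand."""
    return pd.DataFrame(
        {
            "line": ["A", "A", "B", "B"],
            "trait": ["t"] * 4,
            "replicate": [1, 2, 1, 2],
            "value": [1.0, 3.0, 5.0, 7.0],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
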