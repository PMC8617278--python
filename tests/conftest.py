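import numpy as np
import pytest

from scsimeval import (
    CountMatrix,
    FixtureSpec,
    PlantedSignals,
    generate_reference,
    normalize_log2cpm,
)


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(7)
    counts = rng.poisson(3.0, size=(30, 12))
    counts[:, 0] += 1  # guarantee positive library sizes
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(30)],
        cell_ids=[f"c{j}" for j in range(12)],
        groups=np.array(["a"] * 6 + ["b"] * 6, dtype=object),
    )


@pytest.fixture
def planted_spec() -> FixtureSpec:
    return FixtureSpec(
        n_genes=600,
        n_cells=200,
        seed=11,
        planted=PlantedSignals(
            de_prop=0.1, dv_prop=0.1, dp_prop=0.1, bd_prop=0.1
        ),
    )


@pytest.fixture
def planted_matrix(planted_spec):
    return generate_reference(planted_spec)


@pytest.fixture
def planted_norm(planted_matrix):
    return normalize_log2cpm(planted_matrix)
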