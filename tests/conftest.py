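import dataclasses

import numpy as np
import pytest

from tmesig import (
    ExpressionMatrix,
    SampleAnnotation,
    compute_entity_z,
    select_high_expressers,
    simulate_cohort,
)
from tmesig.simulate import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Tiny cohort: fast enough for RF-based unit tests."""
    return SimConfig(
        n_entities=2,
        samples_per_entity=150,
        n_genes=300,
        module_size=20,
        loading=0.8,
        noise_sd=0.5,
        entity_shift_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_labels(small_config, small_cohort):
    expr, ann, _truth = small_cohort
    z = compute_entity_z(expr, ann, small_config.target_gene_id)
    return select_high_expressers(z)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)],
        [f"s{j}" for j in range(8)],
        rng.lognormal(1.0, 1.0, size=(6, 8)),
    )


@pytest.fixture
def tiny_annotation() -> SampleAnnotation:
    return SampleAnnotation({f"s{j}": ("A" if j < 4 else "B") for j in range(8)})
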