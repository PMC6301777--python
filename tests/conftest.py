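import numpy as np
import pandas as pd
import pytest

from csme import (
    DEFAULT_SCHEME,
    BetaMatrix,
    CellTypeScheme,
    ProportionTable,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def scheme() -> CellTypeScheme:
    return DEFAULT_SCHEME


@pytest.fixture
def tiny_beta_matrix() -> BetaMatrix:
    values = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8], [0.0, 1.0, 0.25, 0.75]],
        index=pd.Index(["a1", "a2", "a3"], name="sample_id"),
        columns=["cg1", "cg2", "cg3", "cg4"],
    )
    samples = pd.DataFrame(
        {"subject_id": ["s1", "s2", "s3"], "cell_label": ["mixed", "mixed", "mixed"]},
        index=values.index,
    )
    return BetaMatrix(values, samples)


def make_proportions(rows: np.ndarray, scheme: CellTypeScheme, **kwargs) -> ProportionTable:
    index = pd.Index([f"mixed_s{i:03d}" for i in range(len(rows))], name="sample_id")
    return ProportionTable(
        pd.DataFrame(rows, index=index, columns=list(scheme.base_types)), **kwargs
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Fixed-remainder equal-weight zero-noise bundle: the exact-recovery oracle."""
    config = SimulationConfig(
        n_cpgs=2000, n_subjects=6, diff_fraction=0.05, effect_size=0.4,
        noise_sd=0.0, within_subject_sd=0.0, seed=11, target="CD8T",
    )
    return config, generate_dataset(config)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Small noisy bundle with planted signal, for power/clustering tests."""
    config = SimulationConfig(
        n_cpgs=2000, n_subjects=6, diff_fraction=0.05, effect_size=0.4,
        noise_sd=0.02, within_subject_sd=0.02, seed=7, target="CD4T",
    )
    return config, generate_dataset(config)
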