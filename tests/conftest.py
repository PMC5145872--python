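import numpy as np
import pandas as pd
import pytest

from coexkit import ExpressionStudy, SimConfig, generate_annotations, generate_expression


@pytest.fixture(scope="session")
def small_config():
    """Two tight modules, low noise: everything recoverable at small n."""
    return SimConfig(
        n_genes=120,
        n_samples_per_group=(20, 20),
        n_modules=2,
        module_size=40,
        loading_range=(0.8, 1.0),
        noise_sd=0.5,
        de_effect=1.5,
        de_fraction=0.1,
        de_module=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_expression(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, small_study):
    _, truth = small_study
    return generate_annotations(truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_study(values: np.ndarray, n_case: int, prefix: str = "G") -> ExpressionStudy:
    """Wrap a plain matrix as an ExpressionStudy (first n_case columns = case)."""
    n_genes, n_samples = values.shape
    genes = [f"{prefix}{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    return ExpressionStudy(pd.DataFrame(values, index=genes, columns=samples), groups)
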