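import numpy as np
import pandas as pd
import pytest

from isamod import preprocess, synthetic_data


@pytest.fixture(scope="session")
def tiny_config() -> synthetic_data.SimulationConfig:
    """Small study used across tests: fast but with clear planted signal."""
    return synthetic_data.SimulationConfig(
        n_genes=300,
        n_datasets=2,
        samples_per_dataset=(10, 10),
        n_planted_modules=3,
        module_gene_sizes=(15, 20, 25),
        module_sample_fraction=0.3,
        module_amplitude=4.0,
        noise_sd=0.3,
        batch_shift_sd=0.2,
        batch_scale_sd=0.05,
        n_cases=5,
        n_controls=5,
        case_effect_modules=(0,),
        case_effect_size=1.5,
        hemizygous_set_size=5,
        detection_dropout_rate=0.0,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return synthetic_data.generate_study(tiny_config)


def make_matrix(values: np.ndarray, prefix: str = "g", groups=None) -> preprocess.ExpressionMatrix:
    """Helper: wrap a raw array into an ExpressionMatrix with generated ids."""
    n_genes, n_samples = values.shape
    genes = [f"{prefix}{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = None
    if groups is not None:
        meta = pd.DataFrame({"group": list(groups)}, index=samples)
    return preprocess.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), sample_meta=meta
    )
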