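import warnings

import numpy as np
import pytest

from icer.pipeline import PipelineConfig, run_on_data
from icer.synthetic_data import SyntheticConfig, detected_features, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """4 samples x 60 species with drift, mass error, dropout and noise."""
    cfg = SyntheticConfig(
        n_samples=4, n_species=60, id_dropout_rate=0.3,
        noise_ion_density=0.2, rt_drift_amplitude=0.3, mz_error_ppm=3.0,
        seed=2,
    )
    ion_maps, tables, truth = generate_dataset(cfg)
    return cfg, ion_maps, tables, truth


@pytest.fixture(scope="session")
def small_result(small_dataset):
    """Full pipeline run on the small dataset (shared, read-only)."""
    _, ion_maps, tables, truth = small_dataset
    features = detected_features(tables)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_on_data(ion_maps, features,
                             PipelineConfig(seed=3, fdr_n_mask=50))
    return result, truth


def run_quiet(ion_maps, features, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_on_data(ion_maps, features, config)
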