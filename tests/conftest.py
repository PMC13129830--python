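import numpy as np
import pytest

from porenoise import (
    DatasetConfig,
    generate_dataset,
    prepare_psd,
    sample_coefficients,
    synthesize_psd,
)
from porenoise.pipeline import features_from_dataset
from porenoise.simulate import DEFAULT_ARCHETYPES

SEED = 20240917


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def grid():
    """Positive one-sided 5 Hz Welch grid of a 200 kHz recording."""
    return DatasetConfig().frequency_grid()


@pytest.fixture(scope="session")
def archetype_psds(grid, session_rng):
    """One noisy wetted and one noisy unwetted PSD at 100 mV (raw scale)."""
    out = {}
    for label, arch in DEFAULT_ARCHETYPES.items():
        coeffs, current = sample_coefficients(arch, 100.0, session_rng)
        psd = synthesize_psd(
            coeffs, grid, n_averages=39, rng=session_rng,
            mean_current=current, voltage=100.0, label=label,
        )
        out[label] = (coeffs, psd)
    return out


@pytest.fixture(scope="session")
def prepared_psds(archetype_psds):
    return {label: (c, prepare_psd(p)) for label, (c, p) in archetype_psds.items()}


@pytest.fixture(scope="session")
def small_dataset():
    """Small labelled synthetic dataset: 18 pore-experiment groups, 108 segments."""
    cfg = DatasetConfig(
        n_wetted_pores=6,
        n_unwetted_pores=3,
        experiments_per_pore=2,
        segments_per_cell=1,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Feature table of the small dataset (PSD-level route)."""
    feats = features_from_dataset(small_dataset)
    feats["label"] = small_dataset.manifest["label"].to_numpy()
    feats["group_id"] = small_dataset.manifest["group_id"].to_numpy()
    return feats
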