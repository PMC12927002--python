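import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from corticomap import synth


@pytest.fixture(scope="session")
def small_section():
    """A compact synthetic section + truth for cheap per-module tests."""
    cfg = synth.scaled_section_config(scale=0.5, seed=11)
    dataset, truth = synth.generate_section(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noiseless_section():
    """Noise-free, drift-free, jitter-free section: pipeline must be exact."""
    cfg = synth.scaled_section_config(
        scale=0.5, seed=3, noise_cv=0.0, drift_amplitude=0.0, mz_jitter_ppm=0.0
    )
    dataset, truth = synth.generate_section(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Six-section control cohort at the default study conditions."""
    cfg = synth.SectionConfig()
    return synth.generate_cohort(cfg, n_sections=6, seed=1, animal_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
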