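import numpy as np
import pytest

from ramanmap.io_formats import AnalysisConfig, TissueLabel
from ramanmap.synthetic import DEFAULT_AXIS, SceneSpec, default_profiles


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def axis():
    return DEFAULT_AXIS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def clean_scene():
    """Noise-free, background-free scene with a deterministic two-region
    label grid (left half tumor, right half connective)."""
    labels = np.full((10, 10), int(TissueLabel.CONNECTIVE), dtype=np.int8)
    labels[:, :5] = int(TissueLabel.TUMOR)
    return SceneSpec(
        grid_shape=(10, 10),
        label_grid=labels,
        snr=None,
        cosmic_rate=0.0,
        fluor_scale=0.0,
    )
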