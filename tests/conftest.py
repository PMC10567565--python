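import numpy as np
import pytest

from camii import fixtures as fx
from camii.imaging import MORPHOLOGY_FEATURES


@pytest.fixture(scope="session")
def separable_profiles():
    """Two genera with unit-variance features and means 10 SD apart."""
    return [
        fx.GenusProfile("Dorea", np.zeros(14), 1.0),
        fx.GenusProfile("Bacteroides", np.full(14, 10.0), 1.0),
    ]


@pytest.fixture(scope="session")
def separable_table(separable_profiles):
    return fx.generate_morphology_dataset(separable_profiles, 200, seed=11)


@pytest.fixture(scope="session")
def plate_with_truth():
    """A 20-colony plate pair plus its generator ground truth."""
    spec = fx.random_plate_spec(20, seed=7)
    trans, epi, truth = fx.generate_plate(spec)
    return trans, epi, truth


def disk_contour(cx: float, cy: float, r: float, n: int = 720) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cy + r * np.sin(theta), cx + r * np.cos(theta)])


@pytest.fixture(scope="session")
def feature_names():
    return MORPHOLOGY_FEATURES
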