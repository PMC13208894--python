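import numpy as np
import pytest

from spatimet import MSIDataset, ROIMask, StudyConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """4-pixel, 3-channel section with easily checkable numbers."""
    return MSIDataset(
        section_id="toy",
        pixels=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        mz_index=np.array([100.0, 200.0, 300.0]),
        intensities=np.array([
            [1.0, 3.0, 0.0],
            [2.0, 4.0, 6.0],
            [0.0, 0.0, 0.0],
            [5.0, 5.0, 10.0],
        ]),
    )


@pytest.fixture
def toy_mask():
    return ROIMask("toy", {
        (0, 0): "N", (0, 1): "N", (1, 0): "PT", (1, 1): "PT",
    })


@pytest.fixture(scope="session")
def small_study():
    """Small but complete synthetic study shared across test modules."""
    return generate_study(StudyConfig(
        n_metabolites=50, pixels_per_region=12, n_decoys=15, seed=42,
    ))
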