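import numpy as np
import pytest

from colloidquant.synthetic import SceneParams, generate_micrograph

PH_GRID = np.arange(3.0, 10.01, 0.5)


@pytest.fixture(scope="session")
def small_scene():
    """One small micrograph with ground truth, shared across tests."""
    params = SceneParams(n_nuclei=20, n_foci=10, n_puncta=40, n_vesicles=5)
    channels, truth = generate_micrograph(params, image_shape=(256, 256),
                                          seed=11)
    return params, channels, truth


@pytest.fixture(scope="session")
def study_scene():
    """A full-scale scene (~100 nuclei, 250 puncta, 40 foci)."""
    params = SceneParams()
    channels, truth = generate_micrograph(params, seed=21)
    return params, channels, truth
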