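import numpy as np
import pytest

from glandstab import ProjectConfig
from glandstab.synthetic import roi_spec_for_class, simulate_roi


@pytest.fixture(scope="session")
def base_roi():
    """One benign ROI with ground-truth glands, reused across tests."""
    spec = roi_spec_for_class("noncancer", seed=1)
    return simulate_roi(spec)


@pytest.fixture(scope="session")
def small_roi():
    """A reduced ROI for image-level tests that do not need 40 glands."""
    spec = roi_spec_for_class(
        "noncancer", seed=2, n_glands=20, image_size_px=(384, 384)
    )
    return simulate_roi(spec)


@pytest.fixture(scope="session")
def config():
    return ProjectConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
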