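import numpy as np
import pytest

from petmrqual import (
    ProjectionGeometry,
    derive_true_mu,
    forward_project,
    generate_head_phantom,
)
from petmrqual.config import RunConfig
from petmrqual.phantom import PhantomConfig


@pytest.fixture(scope="session")
def phantom2d():
    """Default-scale single-slice phantom: (labels, ct, activity)."""
    cfg = PhantomConfig(shape=(128, 128), spacing_mm=(2.0, 2.0))
    return generate_head_phantom(cfg, seed=1)


@pytest.fixture(scope="session")
def mu2d(phantom2d):
    labels, _, _ = phantom2d
    return derive_true_mu(labels)


@pytest.fixture(scope="session")
def sino2d(phantom2d, mu2d):
    """Noiseless attenuated sinogram of the 2-D phantom."""
    _, _, act = phantom2d
    return forward_project(act, mu2d, ProjectionGeometry())


@pytest.fixture()
def run_config_2d():
    """Fast single-slice qualification config (aligned phantom, no PSF kernel)."""
    return RunConfig.model_validate(
        {
            "phantom": {"shape": [128, 128], "spacing_mm": [2.0, 2.0]},
            "attenuation": {"fwhm_mm": 0.0},
            "registration": {"enabled": False},
        }
    )
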