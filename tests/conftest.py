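import numpy as np
import pytest

from volsmlm.localizer import calibrate_astigmatism
from volsmlm.pipeline import make_bead_zstack
from volsmlm.sim_core import CameraModel, OpticalConfig
from volsmlm.zernike import ZernikeCoeffs


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def camera_noiseless() -> CameraModel:
    return CameraModel(read_noise_e=0.0)


@pytest.fixture(scope="session")
def astig60() -> ZernikeCoeffs:
    """The induced 60 nm RMS vertical astigmatism used for 3D localization."""
    return ZernikeCoeffs({"astig_vertical": 60.0})


@pytest.fixture(scope="session")
def calibration(cfg, camera, astig60):
    """Noiseless astigmatism calibration on the simulated bead z-stack."""
    stack, z_step = make_bead_zstack(astig60, cfg, camera)
    return calibrate_astigmatism(stack, z_step, cfg.pixel_size_camera_nm)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
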