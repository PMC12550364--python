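import numpy as np
import pytest

from coloct import phantom as ph
from coloct import reconstruction as rc
from coloct import segmentation as sg


@pytest.fixture(scope="session")
def geom():
    """Scaled-down phantom geometry shared across the suite."""
    return ph.default_phantom_geometry(n_bscans=20)


@pytest.fixture(scope="session")
def phantom_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def volume_truth(geom, phantom_spec):
    """One rendered default phantom volume with ground truth."""
    return ph.simulate_volume(phantom_spec, geom)


@pytest.fixture(scope="session")
def seg_params(geom, phantom_spec):
    return ph.default_segmentation_params(phantom_spec, geom)


@pytest.fixture(scope="session")
def segmented_wall(volume_truth, geom, seg_params):
    vol, _ = volume_truth
    vol_db = rc.log_compress(vol, floor=1e-4)
    return sg.segment_volume(vol_db, seg_params)


@pytest.fixture(scope="session")
def quiet_geom():
    """Tiny geometry for noise-free construction-level tests."""
    return ph.default_phantom_geometry(n_bscans=4, a_lines_per_bscan=90, n_depth_samples=256)


@pytest.fixture(scope="session")
def quiet_spec():
    """Phantom with every stochastic/structured perturbation disabled."""
    return ph.PhantomSpec(
        speckle_model="none",
        noise_floor=0.0,
        detachment=ph.DetachmentSpec(0, 0.0, 0.0),
        motion_jitter=ph.MotionJitterSpec(0.0, 0.0),
        crypt_modulation=ph.CryptModulationSpec(0.0, 12.0),
        surface_waviness_um=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
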