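import numpy as np
import pytest

import sarcoreg as sr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def invivo_phantom():
    """Small in vivo phantom shared across tests (volume, roi, landmarks)."""
    return sr.make_invivo_phantom(seed=3)


@pytest.fixture(scope="session")
def mri_slice(invivo_phantom):
    """Central axial slice of the phantom plus its in-plane pixel size."""
    volume, _, _ = invivo_phantom
    return volume.data[:, :, volume.shape[2] // 2], float(volume.spacing[0])


def make_pairs_3d(points_src, points_tgt, space_a="moving", space_b="fixed"):
    labels = [f"L{i}" for i in range(len(points_src))]
    return sr.PairedLandmarks(
        sr.LandmarkSet(space_a, labels, points_src),
        sr.LandmarkSet(space_b, labels, points_tgt),
    )
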