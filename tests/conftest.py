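import numpy as np
import pytest

from wristt1 import (AcquisitionProtocol, PhantomStudy, default_t1_prior,
                     render_phantom, sample_subject_truth)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Small rendering grid so image-level tests stay fast."""
    return AcquisitionProtocol(image_shape=(48, 40))


@pytest.fixture(scope="session")
def prior():
    return default_t1_prior()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def noiseless_study(small_protocol, prior):
    """One noiseless rendered patient: estimates must equal truth exactly."""
    rng = np.random.default_rng(7)
    truth = sample_subject_truth("P001", "patient", True, prior, rng)
    return render_phantom(truth, small_protocol, rng)


@pytest.fixture(scope="session")
def noisy_study(small_protocol, prior):
    rng = np.random.default_rng(11)
    truth = sample_subject_truth("P002", "patient", False, prior, rng,
                                 noise_sigma=0.5)
    return render_phantom(truth, small_protocol, rng)


def toy_study(images, masks, flip_angles=(5.0, 10.0), tr_ms=5.81):
    """Hand-built study for ROI arithmetic tests (no wrist geometry)."""
    images = np.asarray(images, dtype=float)
    masks = np.asarray(masks)
    nl, na = images.shape[:2]
    proto = AcquisitionProtocol(flip_angles_deg=flip_angles, tr_ms=tr_ms,
                                n_levels=nl, image_shape=images.shape[2:])
    from wristt1.phantom import SubjectTruth
    from wristt1.tissues import TissueClass
    truth = SubjectTruth("toy", "control", False, 40.0, "female",
                         {t.name: 1000.0 for t in TissueClass},
                         {t.name: 1.0 for t in TissueClass})
    return PhantomStudy("toy", images, masks, truth, proto)
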