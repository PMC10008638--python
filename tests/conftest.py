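import numpy as np
import pytest

from toothmove.crownprep import build_tooth_frame, crop_occlusal_third
from toothmove.geometry import EulerAngles, RigidTransform, rotation_from_euler
from toothmove.synthetic import CohortSpec, make_case, make_crown


def random_rigid(rng: np.random.Generator, max_angle: float = 170.0,
                 max_trans: float = 10.0) -> RigidTransform:
    """Random proper rigid transform; angles bounded away from gimbal lock."""
    e = EulerAngles(
        float(rng.uniform(-max_angle, max_angle)),
        float(rng.uniform(-min(max_angle, 84.0), min(max_angle, 84.0))),
        float(rng.uniform(-max_angle, max_angle)),
    )
    return RigidTransform(rotation_from_euler(e), rng.uniform(-max_trans, max_trans, 3))


@pytest.fixture(scope="session")
def molar_cropped():
    """A cropped synthetic molar crown with its anatomical frame."""
    crown, (occ, buc) = make_crown("molar", seed=11)
    frame0 = build_tooth_frame(crown, occ, buc)
    cropped = crop_occlusal_third(crown, frame0)
    frame = build_tooth_frame(cropped, occ, buc)
    return cropped, frame


@pytest.fixture(scope="session")
def null_case(tmp_path_factory):
    """One noiseless synthetic patient with zero-mean, zero-spread
    displacements: the pipeline should measure ~0 everywhere."""
    out = tmp_path_factory.mktemp("nullcase")
    spec = CohortSpec(
        n_patients=1, noise_sd=0.0, seed=5,
        sigma={t: np.zeros(6) for t in ("incisor", "canine", "premolar", "molar")},
    )
    return make_case(spec, 0, out)


@pytest.fixture(scope="session")
def displaced_case(tmp_path_factory):
    """One noiseless patient with the default per-tooth displacement spread
    (1.5 deg / 0.25 mm) and known ground truth."""
    out = tmp_path_factory.mktemp("dispcase")
    spec = CohortSpec(n_patients=1, noise_sd=0.0, seed=42)
    return make_case(spec, 0, out)
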