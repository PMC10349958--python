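import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from abag_eval.synthetic_data import DecoyConfig, build_toy_complex, make_decoys


@pytest.fixture(scope="session")
def toy_complex():
    """Nanobody-antigen reference complex with numbering table."""
    return build_toy_complex(seed=11)


@pytest.fixture(scope="session")
def toy_complex_ab():
    """Heavy-light antibody-antigen reference complex."""
    return build_toy_complex(seed=12, include_light=True)


@pytest.fixture(scope="session")
def translation_decoys(toy_complex):
    """Noise-free pure-translation decoy sweep with exact planted L-RMSD."""
    config = DecoyConfig(seed=5, translation_magnitudes=(0.0, 2.0, 6.0, 15.0, 40.0),
                         plddt_noise_sd=0.0)
    return make_decoys(toy_complex, config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from abag_eval.geometry import RigidTransform
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return RigidTransform(rot.as_matrix(), rng.uniform(-20, 20, 3))
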