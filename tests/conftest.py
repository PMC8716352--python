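import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cbctnav as cn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tool():
    return cn.make_tool_model()


@pytest.fixture(scope="session")
def clean_scene(tool):
    """Noise-free default phantom at identity pose, with ground truth."""
    vol, truth = cn.render_phantom_volume(tool, cn.RigidTransform.identity())
    return vol, truth


def random_rigid(seed, max_rot=30.0, max_trans=40.0):
    return cn.RigidTransform.random(np.random.default_rng(seed), max_rot, max_trans)
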