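import numpy as np
import pytest

from exobench import exo as xo
from exobench.markers import MarkerFrameSeries
from exobench.synthetic import SubjectAnthropometry, Task, TaskSpec, \
    generate_lift_kinematics


@pytest.fixture(scope="session")
def anthro():
    return SubjectAnthropometry()


@pytest.fixture(scope="session")
def laevo_model():
    return xo.builtin_device("laevo_like")


@pytest.fixture(scope="session")
def darwing_model():
    return xo.builtin_device("darwing_like")


@pytest.fixture(scope="session")
def stoop_trial(anthro):
    """Noise-free Stoop trial (2 cycles) without a device."""
    spec = TaskSpec(task=Task.STOOP)
    return generate_lift_kinematics(anthro, spec, marker_noise_std=0.0)


@pytest.fixture(scope="session")
def rigid_stoop_trial(anthro, laevo_model):
    """Noise-free Stoop trial wearing the rigid device."""
    spec = TaskSpec(task=Task.STOOP)
    return generate_lift_kinematics(anthro, spec, exo=laevo_model,
                                    marker_noise_std=0.0)


def make_series(positions_by_label, rate=128.0):
    """Build a MarkerFrameSeries from a {label: (n, 3) array} dict."""
    labels = list(positions_by_label)
    arrays = [np.atleast_2d(np.asarray(positions_by_label[lab], dtype=float))
              for lab in labels]
    n = max(2, max(a.shape[0] for a in arrays))
    stacked = np.stack([np.broadcast_to(a, (n, 3)) for a in arrays], axis=1)
    return MarkerFrameSeries(labels=labels, positions=stacked, rate=rate)
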