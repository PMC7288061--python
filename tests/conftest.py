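import numpy as np
import pytest

from physikin import cekf, synth, tuning
from physikin.skeleton import N_STATE, S_LEN, S_ROOT, S_THETA, build_default_skeleton


@pytest.fixture(scope="session")
def model():
    return build_default_skeleton()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def squat_truth(model):
    return synth.generate_task("squat_lateral_arms", dt=1 / 30, reps=4)


@pytest.fixture(scope="session")
def squat_clean(model, squat_truth):
    return synth.render_joint_centers(model, squat_truth)


def exact_init(truth, p0_scale=1.0):
    """Filter state at the ground-truth first frame."""
    x = np.zeros(N_STATE)
    x[S_THETA] = truth.theta[0]
    x[S_LEN] = truth.lengths
    x[S_ROOT] = truth.root[0]
    return cekf.FilterState(x=x, P=p0_scale * np.eye(N_STATE))


def truth_constraints(model, truth):
    return cekf.ConstraintSet.from_model(
        model, 0.8 * truth.lengths, 1.2 * truth.lengths)


def uniform_config(sigma2=10.0, r_var=0.0052):
    return tuning.TuningConfig(sigma2=np.full(11, sigma2), r_var=r_var)


# A task-appropriate squat configuration (moving groups dynamic, axial
# rotations and unused groups quiet), used where a test needs a sensible
# filter without re-running the tuning optimizer.
SQUAT_SIGMA2 = np.array(
    [88.8, 88.2, 0.106, 100.0, 96.5, 90.1, 10.45, 0.01, 0.001, 0.097, 1.0])


def squat_config(r_var=0.0052):
    return tuning.TuningConfig(sigma2=SQUAT_SIGMA2, r_var=r_var)
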