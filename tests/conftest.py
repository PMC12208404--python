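"""Shared fixtures: one subject, both variant models, one processed trial.

Session scope keeps the suite fast: the walking trial, kinematic fit,
inverse dynamics and both recruitment solutions are computed once and
reused by every test that needs them.
"""

import warnings

import numpy as np
import pytest

from paleogait.core import AUSTRALOPITH_LIKE, HUMAN_LIKE
from paleogait.dynamics import extract_stride, fit_kinematics, net_joint_loads
from paleogait.model import build_subject_model
from paleogait.redundancy import solve_stride
from paleogait.synthetic import generate_cohort, generate_gait_trial

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def subject():
    return generate_cohort(1, 7)[0]


@pytest.fixture(scope="session")
def human_model(subject):
    return build_subject_model(HUMAN_LIKE, subject)


@pytest.fixture(scope="session")
def austral_model(subject):
    return build_subject_model(AUSTRALOPITH_LIKE, subject)


@pytest.fixture(scope="session")
def trial(subject, human_model):
    return generate_gait_trial(subject, 1.3, 42, model=human_model)


@pytest.fixture(scope="session")
def kinematics(trial, human_model):
    return fit_kinematics(trial, human_model)


@pytest.fixture(scope="session")
def loads(trial, human_model, kinematics):
    return net_joint_loads(human_model, kinematics, trial)


@pytest.fixture(scope="session")
def stride_window(trial):
    return extract_stride(trial)


@pytest.fixture(scope="session")
def solutions(human_model, austral_model, kinematics, loads, stride_window):
    window, _ = stride_window
    return {
        "human_like": solve_stride(human_model, kinematics, loads, frames=window),
        "australopith_like": solve_stride(austral_model, kinematics, loads, frames=window),
    }


def stance_mean_group_activation(model, solution, group, side):
    """Strength-weighted mean group activation over the stance phase."""
    cols = [j for j, m in enumerate(model.muscles)
            if m.anatomical_group == group and m.side == side]
    w = np.array([model.muscles[j].max_strength for j in cols])
    stance = slice(0, int(0.6 * solution.activations.shape[0]))
    return float((solution.activations[stance][:, cols] @ w / w.sum()).mean())
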