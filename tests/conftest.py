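import pytest

from reachlearn.learner import LearnerParams
from reachlearn.paradigm import Condition, build_schedule
from reachlearn.simulate import run_condition

N_SEEDS = 20
SEEDS = list(range(N_SEEDS))


@pytest.fixture(scope="session")
def exp1():
    return build_schedule("EXP1")


def _batch(label, schedule, **overrides):
    cond = Condition.from_label(label)
    params = LearnerParams.for_condition(cond, **overrides)
    return [run_condition(params, schedule, cond, seed=s) for s in SEEDS]


@pytest.fixture(scope="session")
def err_runs(exp1):
    """20 ERR simulations on the EXP1 schedule with default parameters."""
    return _batch("ERR", exp1)


@pytest.fixture(scope="session")
def rwd_runs(exp1):
    """20 reward-only simulations on the EXP1 schedule with default parameters."""
    return _batch("RWD", exp1)


@pytest.fixture(scope="session")
def epe_runs(exp1):
    """20 endpoint-feedback simulations on the EXP1 schedule."""
    return _batch("EPE", exp1)
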