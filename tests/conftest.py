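import numpy as np
import pytest

from attnrl.attribute_space import AttributeMatrix, normalize_attributes
from attnrl.rl_core import ModelParams
from attnrl.task_library import CONDITION_PARAMS, builtin_condition, generate_subject


@pytest.fixture(scope="session")
def condition1_subject():
    """One full synthetic subject in the four-foods condition."""
    return generate_subject(1, seed=11)


@pytest.fixture(scope="session")
def condition1_spec():
    return builtin_condition(1).with_assignments(seed=5)


@pytest.fixture
def two_option_spec():
    """Minimal one-attribute, two-option context for hand-unrolled oracles."""
    from attnrl.task_library import ConditionSpec

    return ConditionSpec(
        condition_id=1,
        options=("A", "B"),
        attributes=("value",),
        intrinsic={"value": (1.0, 0.5)},
        location_attr=None,
        session_length=10,
        n_sessions=1,
    )


@pytest.fixture
def calorie_matrix():
    return AttributeMatrix(
        options=("PN", "FG", "PL", "KR"),
        attributes=("calorie", "proximity"),
        raw_values=np.array(
            [[2.06, 0.78, 0.15, 0.08], [1 / 18, 1 / 15, 1 / 15, 1 / 18]]
        ),
    )


@pytest.fixture
def normalized_calorie_matrix(calorie_matrix):
    return normalize_attributes(calorie_matrix)


@pytest.fixture
def table1_condition1() -> ModelParams:
    return CONDITION_PARAMS[1]
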