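import numpy as np
import pytest

from t2dmcea.config import EventReward, ModelSpec, MortalitySchedule, Strategy
from t2dmcea.study import build_reference_model


@pytest.fixture(scope="session")
def reference_inputs():
    return build_reference_model()


@pytest.fixture(scope="session")
def reference_fit(reference_inputs):
    from t2dmcea.model import MarkovCEA

    return MarkovCEA(reference_inputs).fit()


@pytest.fixture
def flat_mortality():
    """Zero mortality over ages 40-90, for hand-computable traces."""
    ages = tuple(range(40, 91))
    zeros = (0.0,) * len(ages)
    return MortalitySchedule(ages, zeros, zeros)


def make_strategy(
    name="toy",
    annual_treatment_cost=75.0,
    uncontrolled_treatment_cost=208.0,
    p_complication_controlled=0.0,
    p_complication_uncontrolled=0.0,
    p_failure=0.0,
    event_cost=228.0,
    event_disutility=0.13,
    **kwargs,
):
    return Strategy(
        name=name,
        annual_treatment_cost=annual_treatment_cost,
        uncontrolled_treatment_cost=uncontrolled_treatment_cost,
        p_complication_controlled=p_complication_controlled,
        p_complication_uncontrolled=p_complication_uncontrolled,
        p_failure=p_failure,
        event=EventReward(event_cost, event_disutility),
        **kwargs,
    )


@pytest.fixture
def toy_strategy():
    return make_strategy()
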