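import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from steptrain import CohortParams, ThoughtStimulus, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_inventory() -> list[ThoughtStimulus]:
    """Balanced 9-item inventory: 3 approach/positive, 3 avoidance/negative,
    3 neutral/neutral."""
    items = []
    for k in range(3):
        items.append(ThoughtStimulus(f"pos{k}", f"positive thought {k}", "positive", "approach"))
        items.append(ThoughtStimulus(f"neg{k}", f"negative thought {k}", "negative", "avoidance"))
        items.append(ThoughtStimulus(f"neu{k}", f"neutral thought {k}", "neutral", "neutral"))
    return items


@pytest.fixture(scope="session")
def default_cohort():
    """One reproducible 12-participant cohort with assessment trial logs."""
    return generate_cohort(CohortParams(seed=20210128))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
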