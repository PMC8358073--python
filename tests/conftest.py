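import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avspeech import (
    AuditoryParams,
    GroupHyperParams,
    LapseSet,
    ParticipantParams,
    VisualParams,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: published CI group-level means; focused auditory lapse from the 84%
#: saturation (0.9 * (1 - lam) + 0.1 = 0.84), divided = focused + 0.22
CI_LAM_A_FOC = 1.0 - 0.74 / 0.9


@pytest.fixture(scope="session")
def ci_group_params() -> ParticipantParams:
    return ParticipantParams(
        auditory=AuditoryParams(threshold_db=-3.1, width_db=10.4),
        visual=VisualParams(threshold_px=17.7),
        lapses=LapseSet.vis_shared(CI_LAM_A_FOC, CI_LAM_A_FOC + 0.22, 0.46),
    )


@pytest.fixture(scope="session")
def nh_group_params() -> ParticipantParams:
    return GroupHyperParams.nh_defaults().group_means()
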