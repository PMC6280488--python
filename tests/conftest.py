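import numpy as np
import pytest

from bloodloss import LognormalParams

# the published per-arm threshold-lognormal fits (location, scale, threshold)
TRIAL_PARAMS = {
    "misoprostol_misoprostol": LognormalParams(5.58, 0.71, -8.60),
    "misoprostol_oxytocin": LognormalParams(5.46, 0.69, -12.01),
    "am_simplified": LognormalParams(5.63, 0.63, -47.38),
    "am_full": LognormalParams(5.57, 0.65, -43.53),
    "champion": LognormalParams(5.19, 0.83, -22.25),
    "althabe_hands_off": LognormalParams(5.57, 0.72, 55.14),
    "althabe_cct": LognormalParams(5.37, 0.80, 62.88),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
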