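import numpy as np
import pytest

from facemimic import AUSeries, AU_CHANNELS, CohortConfig, ResponseParams
from facemimic.records import ARTIFICIAL_EMBODIMENTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """No mimicry, no flicker, no occlusion, no participant heterogeneity."""
    return ResponseParams(
        p_mimic_rfr=0.0, p_mimic_cfr=0.0, baseline_flicker_rate=0.0,
        p_occlusion=0.0, participant_effect_sd=0.0)


@pytest.fixture
def perfect_copy_params(quiet_params):
    """Instructed responses are exact copies of the stimulus."""
    quiet_params.instructed_lag_frames = (0, 0)
    quiet_params.instructed_gain_sd = 0.0
    quiet_params.instructed_noise_sd = 0.0
    return quiet_params


@pytest.fixture
def small_config():
    """Scaled-down design: 6 participants, artificial embodiments only."""
    return CohortConfig(n_participants=6, group_sizes=(2, 2, 2),
                        embodiments=ARTIFICIAL_EMBODIMENTS)


def series_from_channel(channel: str, values, fps: float = 30.0) -> AUSeries:
    """A series that is zero everywhere except one named channel."""
    values = np.asarray(values)
    mat = np.zeros((values.size, len(AU_CHANNELS)), dtype=np.int64)
    mat[:, AU_CHANNELS.index(channel)] = values
    return AUSeries(mat, AU_CHANNELS, fps)
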