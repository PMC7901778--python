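import numpy as np
import pytest

from pavarb import build_task_config, make_params, simulate_cohort
from pavarb.recovery import default_param_sampler


@pytest.fixture(scope="session")
def eeg_config():
    return build_task_config("eeg")


@pytest.fixture(scope="session")
def fmri_config():
    return build_task_config("fmri")


@pytest.fixture(scope="session")
def adaptive_params():
    return make_params("adaptive", beta=5.0, v0_pav=0.5,
                       eta0_pav=3.0, eta0_inst=3.0)


@pytest.fixture(scope="session")
def small_cohort(eeg_config):
    """Four adaptive-model subjects on the EEG design, with traces."""
    rng = np.random.default_rng(42)
    params = [make_params("adaptive", **default_param_sampler(rng))
              for _ in range(4)]
    data, traces = simulate_cohort(eeg_config, "adaptive", params, seed=42,
                                   return_traces=True)
    return data, traces
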