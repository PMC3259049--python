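import numpy as np
import pytest

from csrdesign import DesignHypotheses, StoppingRules, TrialConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_trial_hyps():
    """The canonical small-trial scenario: weak response, 3 vs 6 month TTP."""
    return DesignHypotheses(r_nul=0.05, r_alt=0.20, ttp_nul=3.0, ttp_alt=6.0)


@pytest.fixture
def small_trial_config():
    return TrialConfig(n1=15, n2=15, n_sim=20_000, seed=7)


@pytest.fixture
def small_trial_rules():
    """Published thresholds for the canonical small trial."""
    return StoppingRules(r1_stop=0, epd_stop=5, r2_reject=5, ttp2_reject=5.25)
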