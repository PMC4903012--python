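import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import edchest as e


@pytest.fixture(scope="session")
def sim_cohort():
    """A study-sized synthetic cohort (n=763, ~33 % events)."""
    return e.simulate_cohort(e.CohortSimSpec(n=763, seed=11))


@pytest.fixture(scope="session")
def clean_ecg():
    """Noise-free 6-min ECG at 72 beats/min with its ground-truth series."""
    rr = e.simulate_rr(e.RRSimSpec(mean_rr=60 / 72, amp_lf=0.02,
                                   amp_hf=0.02, jitter_sd=0.003,
                                   duration=360, seed=1))
    ecg = e.simulate_ecg(rr, e.ECGSimSpec(seed=1))
    return rr, ecg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
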