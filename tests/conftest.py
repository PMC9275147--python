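import numpy as np
import pytest

from ofr_brf import (BRFTruth, default_truth, make_condition_grid,
                     simulate_session)
from ofr_brf.models import DoGParams, dog_summation_response
from ofr_brf.traces import SummationCurve
from ofr_brf import defaults as d


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def noiseless_truth(truth):
    return BRFTruth(dog=truth.dog, decay=truth.decay, noise_sd=0.0, drift_sd=0.0)


@pytest.fixture(scope="session")
def exp1_noiseless_session(noiseless_truth):
    grid = make_condition_grid(1)
    return simulate_session(grid, noiseless_truth, n_trials_per_condition=2,
                            catch_fraction=0.1, seed=11)


def noiseless_disk_curve(sf: float, diameters=d.DISK_DIAMETERS,
                         direction="rightward") -> SummationCurve:
    """Disk summation curve evaluated exactly from the per-SF DoG truth."""
    s_e, s_i, g_e, g_i = d.DOG_TABLE[sf]
    p = DoGParams(sigma_e=s_e, sigma_i=s_i, g_e=g_e, g_i=g_i)
    diams = np.asarray(diameters, float)
    amp = dog_summation_response(diams, p)
    return SummationCurve(shape="disk", diameters=diams, amp=amp,
                          se=np.full(diams.size, 1e-4), n=np.full(diams.size, 150),
                          window=d.REFERENCE_WINDOW, sf=sf, speed=30.0,
                          direction=direction)
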