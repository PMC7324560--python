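import numpy as np
import pytest

from aptrans import apmodel as ap
from aptrans.biomarkers import compute_biomarkers


@pytest.fixture(scope="session")
def human():
    return ap.species_defaults("human")


@pytest.fixture(scope="session")
def zebrafish():
    return ap.species_defaults("zebrafish")


@pytest.fixture(scope="session")
def human_steady_trace(human):
    """Human control model paced to periodic steady state at 1 Hz."""
    return ap.simulate_paced(human, protocol=ap.StimulusProtocol(n_beats=100))


@pytest.fixture(scope="session")
def human_steady_biomarkers(human_steady_trace):
    return compute_biomarkers(human_steady_trace, include_dvdt=True)


@pytest.fixture()
def triangle_trace():
    """Piecewise-linear AP: -85 -> 35 mV over 2 ms, then back over 300 ms.

    Closed forms: amplitude 120 mV, APDp = (2 + 300) * p/100 - 2 * p/100
    = 3.0 * p - 0.02 * p, e.g. APD50 = 151 ms, APD90 = 271.8 ms.
    """
    t = np.array([0.0, 2.0, 302.0])
    v = np.array([-85.0, 35.0, -85.0])
    # refine so each segment has several samples (linear interpolation is
    # exact on the segments, so biomarkers stay in closed form)
    tt = np.unique(np.concatenate([t, np.linspace(0, 302, 605)]))
    vv = np.interp(tt, t, v)
    return ap.PacedTrace(tt, vv, {})
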