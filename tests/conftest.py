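import warnings

import numpy as np
import pytest

from capop import synthgen
from capop.signals import DFFTraces


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Tests assert on returned values, not on warning chatter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def disk_cells():
    return synthgen.make_cells(15, "disk", (96, 96), pixel_size=1.0,
                               radius=4.0, min_gap=3.0, seed=11)


@pytest.fixture(scope="session")
def gcamp6f_traces():
    """20 traces, 60 Hz, tau 250 ms, 4sigma transient peaks on sigma=0.05 noise."""
    gt = synthgen.make_activity(n_cells=20, duration=100.0, frame_rate=60.0,
                                tau_decay=0.25, amplitude=0.2, noise_sigma=0.05,
                                background_rate=0.08, seed=13)
    return gt


@pytest.fixture(scope="session")
def gcamp6f_dff(gcamp6f_traces):
    return DFFTraces(dff=gcamp6f_traces.observed,
                     F0=np.ones(gcamp6f_traces.n_cells), f0_method="window")
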