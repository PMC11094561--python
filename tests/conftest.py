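import numpy as np
import pytest

from gazedx.cohort import SimulationSpec, simulate_biomarker_table
from gazedx.events import GazeStream


@pytest.fixture(scope="session")
def cohort_table():
    """Default-condition cohort (102 autism / 44 nonautism), fixed seed."""
    return simulate_biomarker_table(SimulationSpec(seed=11))


def make_stream(x, y, rate=100.0, pupil=None, valid=None, t0=0.0):
    """Build a GazeStream from position arrays at a fixed rate."""
    x = np.asarray(x, float)
    n = len(x)
    t = t0 + np.arange(n) * (1000.0 / rate)
    y = np.asarray(y, float) if y is not None else np.zeros(n)
    pupil = np.asarray(pupil, float) if pupil is not None else np.full(n, 4.0)
    valid = np.asarray(valid, bool) if valid is not None else np.ones(n, bool)
    return GazeStream(t, x, y, pupil, valid, rate)
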