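import numpy as np
import pytest

from purkinje import channels as ch
from purkinje import solver as slv
from purkinje.morphology import PassiveParams


@pytest.fixture(scope="session")
def channelome():
    return ch.build_default_channelome()


@pytest.fixture(scope="session")
def desk_model():
    """The canonical desk-scale cell (deterministic, seed 1)."""
    return slv.Model.canonical(n_dend=48, seed=1)


@pytest.fixture(scope="session")
def passive_defaults():
    return PassiveParams()


def detect_rate(trace, t, threshold=-20.0, tmin=None):
    """Crossing-count firing rate in Hz over t > tmin."""
    sel = t > (tmin if tmin is not None else t[0])
    v = trace[sel]
    n = int(np.sum((v[1:] > threshold) & (v[:-1] <= threshold)))
    span = (t[sel][-1] - t[sel][0]) / 1000.0
    return n / span if span > 0 else 0.0
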