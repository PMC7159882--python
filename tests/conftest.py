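import numpy as np
import pytest

from cardiopufa import ap, synth


@pytest.fixture(scope="session")
def epi_model():
    return ap.build_model("epi")


@pytest.fixture(scope="session")
def ctrl_1hz(epi_model):
    """Epicardial model paced to steady state at 1 Hz (shared; do not mutate
    the returned model)."""
    m = epi_model.copy()
    res = ap.pace_to_steady_state(m, ap.PacingProtocol(cl_ms=1000.0, n_beats=400))
    return m, res


@pytest.fixture
def iks_params():
    return synth.default_params("IKs")


@pytest.fixture
def nav_params():
    return synth.default_params("INa")


@pytest.fixture
def cav_params():
    return synth.default_params("ICaL")


def triangular_ap(v_peak=40.0, v_rest=-85.0, fall_ms=300.0, dt=0.1,
                  total_ms=400.0):
    """Idealized AP: instant rise at t=1 ms, linear fall over fall_ms."""
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, v_rest)
    rise_at = 1.0
    falling = (t >= rise_at) & (t < rise_at + fall_ms)
    v[falling] = v_peak - (v_peak - v_rest) * (t[falling] - rise_at) / fall_ms
    return t, v
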