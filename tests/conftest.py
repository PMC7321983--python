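import numpy as np
import pytest

from fusmap.cortex import make_cortex
from fusmap.events import (
    TimingConfig,
    eccentricity_stimuli,
    make_event_log,
    od_stimuli,
)
from fusmap.hemodynamics import HemodynamicModel
from fusmap.preprocess import preprocess
from fusmap.simulate import simulate_cbv_series


@pytest.fixture(scope="session")
def hemo():
    return HemodynamicModel()


@pytest.fixture(scope="session")
def od_cortex():
    """Straight ribbon with 520-um OD columns, layer-graded modulation."""
    return make_cortex(
        shape=(30, 128),
        thickness_mm=1.5,
        od_column_width=520.0,
        od_layer_gain={"I": 0.1, "II/III": 0.6, "IV": 1.0, "V": 0.6, "VI": 0.1},
    )


@pytest.fixture(scope="session")
def od_tensor(od_cortex, hemo):
    """Preprocessed OD session: 8 trials/eye, pixel SNR ~5 (16% / 3%)."""
    events = make_event_log(
        od_stimuli(), 8, timing=TimingConfig(extra_gap_s=4.0), seed=11
    )
    series = simulate_cbv_series(od_cortex, events, hemo, noise_sd=3.0, seed=12)
    return preprocess(series, events, protocol="od")


@pytest.fixture(scope="session")
def ecc_setup(hemo):
    """Eccentricity session on a small plane: scene, stimuli, trial tensor."""
    cortex = make_cortex(shape=(24, 64), thickness_mm=1.2, od_column_width=520.0)
    stimuli = eccentricity_stimuli()
    events = make_event_log(
        stimuli, 8, timing=TimingConfig(extra_gap_s=4.0), seed=21
    )
    series = simulate_cbv_series(cortex, events, hemo, noise_sd=3.0, seed=22)
    tensor = preprocess(series, events, protocol="retinotopy")
    return cortex, stimuli, tensor


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
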