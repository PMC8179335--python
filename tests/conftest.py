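import numpy as np
import pytest

import fieldunfold as fu


@pytest.fixture(scope="session")
def topology():
    return fu.default_topology()


@pytest.fixture(scope="session")
def native(topology):
    return fu.build_native_model(topology, seed=0)


@pytest.fixture(scope="session")
def cdeb_schedule():
    """Noise-free scripted CDEB schedule with breaks at 5/10/15/20 ps."""
    return fu.UnfoldingSchedule(
        break_order="CDEB",
        mean_break_times={"C": 5.0, "D": 10.0, "E": 15.0, "B": 20.0},
    )


@pytest.fixture(scope="session")
def cdeb_run(native, topology, cdeb_schedule):
    """One deterministic 50 ps CDEB run on the 0.05 ps grid."""
    return fu.simulate_unfolding_run(
        native, topology, cdeb_schedule, n_frames=1001, dt=0.05, seed=1
    )


@pytest.fixture(scope="session")
def small_detector():
    """Coarse detector covering the same solid angle as the reference one."""
    return fu.DetectorConfig().binned(16)  # 64 x 64 pixels of 3.2 mm


@pytest.fixture(scope="session")
def small_qmap(small_detector):
    return fu.build_q_map(small_detector)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
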