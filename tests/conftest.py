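import numpy as np
import pytest

from modnet import synth
from modnet.io_core import ModuleMap, RecordingSession, SpikeTrain


def make_train(times, t_stop, eid="ch1", t_start=0.0):
    return SpikeTrain(eid, np.asarray(times, dtype=float), t_start, t_stop)


def make_session(spikes_by_electrode, t_stop, t_start=0.0):
    trains = {
        eid: make_train(times, t_stop, eid, t_start)
        for eid, times in spikes_by_electrode.items()
    }
    return RecordingSession(trains)


@pytest.fixture
def two_module_map():
    return ModuleMap(
        {"ch1": "N1", "ch2": "N1", "ch3": "N2", "ch4": "N2", "ch5": "CTRL"}
    )


@pytest.fixture(scope="session")
def asymmetric_bundle():
    """One coupled two-module session reused by read-only tests."""
    cfg = synth.asymmetric_pair_config(seed=11, duration=600.0)
    return synth.generate_session(cfg)
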