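import datetime as dt

import pytest

from pitmove.io import raceway_geometry, stream_geometry
from pitmove.model import DetectionEvent, DetectionRecord
from pitmove.simulate import SimulationConfig

TZ = dt.timezone(dt.timedelta(hours=-5))
BASE = dt.datetime(2014, 11, 10, 0, 0, tzinfo=TZ)


def at(seconds: float) -> dt.datetime:
    """Timestamp ``seconds`` after the fixture epoch (site local midnight)."""
    return BASE + dt.timedelta(seconds=seconds)


def rec(tag, antenna, t_s, dur_s=0.0):
    return DetectionRecord(tag, antenna, at(t_s), at(t_s + dur_s))


def ev(tag, antenna, t0_s, t1_s, n=1):
    return DetectionEvent(tag, antenna, at(t0_s), at(t1_s), n)


@pytest.fixture(scope="session")
def raceway():
    return raceway_geometry()


@pytest.fixture(scope="session")
def stream():
    return stream_geometry()


def noise_free_config(**overrides) -> SimulationConfig:
    """Raceway scenario with every noise channel switched off."""
    base = dict(
        topology="raceway",
        seed=0,
        n_fish=10,
        study_days=10,
        mover_fraction=1.0,
        detection_prob=1.0,
        crosstalk_per_1000=0.0,
        rest_prob=0.0,
        teleport_per_1000=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
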