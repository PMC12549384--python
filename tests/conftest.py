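import pytest

from diefill import (
    AirProperties,
    DieGeometry,
    FillCam,
    MachineConfig,
    fixture_materials,
)


@pytest.fixture(scope="session")
def materials():
    """The three characterized excipients keyed by name."""
    return {m.name: m for m in fixture_materials()}


@pytest.fixture(scope="session")
def die():
    return DieGeometry()


@pytest.fixture(scope="session")
def air():
    return AirProperties()


@pytest.fixture
def conventional_cam():
    return FillCam("conventional")


@pytest.fixture
def stearate_cam():
    return FillCam("stearate")


@pytest.fixture
def rotary(die):
    return MachineConfig(machine="rotary_press", turret_speed=20.0, die=die)


@pytest.fixture
def simulator(die):
    return MachineConfig(machine="compaction_simulator", turret_speed=20.0, die=die)
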