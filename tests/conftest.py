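import pytest

from sdmcell import CellGeometry, Conditions, FeedState, Membrane, fixtures
from sdmcell.units import bar_to_pa, rpm_to_rad_s


@pytest.fixture(scope="session")
def solutes():
    return fixtures.load_solutes()


@pytest.fixture(scope="session")
def nacl(solutes):
    return solutes["NaCl"]


@pytest.fixture
def geometry():
    return CellGeometry(
        membrane_area=14.6e-4, initial_feed_volume=300e-6, stirring_radius=0.02
    )


@pytest.fixture
def conditions_300rpm():
    return Conditions(delta_p=bar_to_pa(10.0), stirring_speed=rpm_to_rad_s(300.0))


@pytest.fixture
def nf_membrane():
    return fixtures.reference_membrane("NF")


@pytest.fixture
def salt_feed():
    """300 mL of 500 mg/L NaCl, no trace compounds."""
    return FeedState(300e-6, {"NaCl": 0.5})


@pytest.fixture
def study_feed():
    return fixtures.study_feed()


@pytest.fixture
def salt_membrane():
    return Membrane("salt-only", "NF", 1.45e-11, {"NaCl": 3.492e-6})
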