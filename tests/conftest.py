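import numpy as np
import pytest

from paleoflight import AeroConfig, Specimen, builtin_fixtures
from paleoflight.wings import WingPlanform


@pytest.fixture(scope="session")
def cfg():
    return AeroConfig()


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def yi(fixtures):
    return fixtures.get("STM 31-2")


@pytest.fixture(scope="session")
def ambopteryx(fixtures):
    return fixtures.get("STM 0-144")


@pytest.fixture
def simple_planform():
    return WingPlanform(model="MFW", span_b_m=1.0, area_S_m2=0.1)


def random_planform(rng: np.random.Generator) -> WingPlanform:
    span = rng.uniform(0.3, 1.5)
    aspect = rng.uniform(3.0, 12.0)
    return WingPlanform(model="MFW", span_b_m=span, area_S_m2=span ** 2 / aspect)


@pytest.fixture
def make_specimen():
    def _make(**kwargs):
        base = dict(taxon="test", specimen_id="T-1", mass_hypotheses_kg=(0.3,),
                    segments_m={"femur": 0.05, "tibia": 0.06, "metatarsus": 0.025,
                                "hindlimb_total": 0.135, "humerus": 0.06,
                                "ulna": 0.065, "styliform": 0.09,
                                "metacarpal_IV": 0.035, "phalanges_IV": 0.15,
                                "metacarpal_III": 0.028, "phalanges_III": 0.05},
                    wing_geometry={"MFW": {"span_m": 0.7, "area_m2": 0.05}})
        base.update(kwargs)
        return Specimen(**base)
    return _make
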