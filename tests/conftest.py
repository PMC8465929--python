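import pytest

from sfosim.calibration import FoodParameters
from sfosim.defaults import default_calibration
from sfosim.domain import FoodGroup, FoodSpec, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def default_cal():
    """The shipped default synthetic calibration (catalog, params)."""
    return default_calibration()


@pytest.fixture
def small_catalog():
    """A four-food catalog spanning perishable and shelf-stable items."""
    return [
        FoodSpec("tomato", "Tomatoes", FoodGroup.VEGETABLES, 1, 0.45, 3, 1.00),
        FoodSpec("milk", "Milk", FoodGroup.DAIRY, 2, 1.25, 4, 2.80),
        FoodSpec("eggs", "Eggs", FoodGroup.PROTEIN, 4, 1.15, 4, 2.60),
        FoodSpec("rice", "Rice", FoodGroup.GRAINS, 52, 1.00, 5, 2.20),
    ]


def make_params(
    food_id="tomato",
    *,
    p1=0.5,
    p2=0.0,
    p3=0.0,
    p4=0.7,
    p5=0.7,
    p6=0.7,
    p7=6.0,
    p10=0.05,
    p11=0.0,
    p12=0.10,
    p13=0.0,
    d_max=13.0,
    c_max=2.0,
    c_store=0.5,
):
    return FoodParameters(
        food_id=food_id,
        p1=p1, p2=p2, p3=p3, p4=p4, p5=p5, p6=p6, p7=p7,
        p10=p10, p11=p11, p12=p12, p13=p13,
        d_max=d_max, c_max=c_max, c_store=c_store,
    )


@pytest.fixture
def params_factory():
    return make_params
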