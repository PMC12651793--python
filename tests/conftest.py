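import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from egikit import FoodRecord, HydrolysisCurve
from egikit.datasets import load_reference_egi, load_reference_foods
from egikit.io import INTESTINAL_GRID

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_foods():
    """The packaged 14-food composition table."""
    return load_reference_foods()


@pytest.fixture(scope="session")
def reference_egi():
    """Published eGI columns for the 14-food panel."""
    return load_reference_egi()


@pytest.fixture
def grid():
    return np.asarray(INTESTINAL_GRID)


@pytest.fixture
def linear_curve():
    """Hydrolysis rising linearly 0 -> 100 over the 0-120 min grid."""
    times = INTESTINAL_GRID
    return HydrolysisCurve(
        food_id="lin", digestion_model="dynamic", replicate=1,
        times=times, values=tuple(t / 120 * 100 for t in times),
    )


@pytest.fixture
def constant_curve():
    times = INTESTINAL_GRID
    return HydrolysisCurve(
        food_id="const", digestion_model="dynamic", replicate=1,
        times=times, values=(100.0,) * len(times),
    )


def make_curve(values, times=INTESTINAL_GRID, food_id="f", model="dynamic", replicate=1):
    return HydrolysisCurve(
        food_id=food_id, digestion_model=model, replicate=replicate,
        times=tuple(times), values=tuple(values),
    )


def make_food(food_id="f", carbohydrate=60.0, protein=0.0, fat=0.0, fiber=0.0, human_gi=None):
    return FoodRecord(
        food_id=food_id, name=food_id, carbohydrate=carbohydrate,
        protein=protein, fat=fat, fiber=fiber, human_gi=human_gi,
    )
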