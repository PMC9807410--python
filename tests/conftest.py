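import io

import pytest
from hypothesis import HealthCheck, settings

import nutristock as ns

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_demo() -> ns.DemographicTable:
    """Two-sex × one-age municipality, 40 residents split 10/30."""
    a = ns.Stratum(sex="male", age_group="adult")
    b = ns.Stratum(sex="female", age_group="adult")
    return ns.DemographicTable("Toyville", {a: 10, b: 30}, strata=(a, b))


@pytest.fixture
def toy_dri() -> ns.DRITable:
    """One-nutrient grid: energy 2000 (male) / 1600 (female) kcal/day."""
    a = ns.Stratum(sex="male", age_group="adult")
    b = ns.Stratum(sex="female", age_group="adult")
    return ns.DRITable(
        nutrients=(ns.NutrientSpec("energy", "Energy", "kcal"),),
        values={("energy", a): 2000.0, ("energy", b): 1600.0},
        strata=(a, b),
    )


@pytest.fixture
def toy_catalog() -> ns.FoodCatalog:
    return ns.FoodCatalog(
        items=(
            ns.FoodItem(
                id="biscuit",
                name="Ration biscuit",
                category="staple",
                per100g={"energy": 350.0},
                pack_grams=100.0,
                cost_per_pack=200.0,
            ),
            ns.FoodItem(
                id="chilled_meal",
                name="Chilled prepared meal",
                category="side",
                per100g={"energy": 150.0},
                shelf_stable=False,
            ),
        ),
        categories=("staple", "side"),
    )


@pytest.fixture
def fixture_set():
    """Default seeded synthetic municipality + catalog + stockpile."""
    spec = ns.FixtureSpec(seed=11)
    demo = ns.gen_demographics(spec)
    dri = ns.gen_dri(spec)
    catalog = ns.gen_catalog(spec)
    inventory = ns.gen_inventory(spec, catalog)
    return spec, demo, dri, catalog, inventory


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
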