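"""Seeded synthetic inputs for every pipeline stage.

The generators emulate the structure of the real inputs — a municipal
sex × age population pyramid, a per-stratum reference-intake grid, a
catalog split into energy-rich staples and protein/vitamin-carrying side
dishes, and a stockpile whose mass is skewed toward carbohydrates (the
default 85 % staple share mirrors the documented state of municipal
stockpiles).  Magnitudes loosely follow real-world scales (energy
~10² kcal/100 g, vitamins ~10⁻¹–10⁰ mg/100 g); exact values are
arbitrary and synthetic.

Every generator is a pure function of its FixtureSpec: one integer seed
drives one documented substream per generator (seed, k) with k = 0
demographics, 1 DRI, 2 catalog, 3 inventory, so the same seed yields
bit-identical outputs.

``exact_cover_inventory`` solves a non-negative linear system so the
assessed excess/deficiency ratio is exactly 100 % for every profile
nutrient — the package's core parameter-recovery fixture.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import ConfigError, ConstructionError
from .reference_data import (
    SEXES,
    DemographicTable,
    DRITable,
    FoodCatalog,
    FoodItem,
    Inventory,
    InventoryEntry,
    NutrientSpec,
    Stratum,
)
from .requirements import ScenarioConfig, nutrient_profile, total_required

#: The synthetic nutrient set: the five shelter-reference nutrients plus
#: fat and calcium, so the "full" profile is a strict superset of shelter5.
FIXTURE_NUTRIENTS = (
    NutrientSpec("energy", "Energy", "kcal"),
    NutrientSpec("protein", "Protein", "g"),
    NutrientSpec("fat", "Fat", "g"),
    NutrientSpec("vitamin_b1", "Vitamin B1", "mg"),
    NutrientSpec("vitamin_b2", "Vitamin B2", "mg"),
    NutrientSpec("vitamin_c", "Vitamin C", "mg"),
    NutrientSpec("calcium", "Calcium", "mg"),
)

#: Per-person per-day base reference values for the synthetic DRI grid.
_DRI_BASE = {
    "energy": 2000.0,
    "protein": 50.0,
    "fat": 60.0,
    "vitamin_b1": 1.1,
    "vitamin_b2": 1.3,
    "vitamin_c": 100.0,
    "calcium": 650.0,
}

_STREAM = {"demographics": 0, "dri": 1, "catalog": 2, "inventory": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic municipality and its stockpile."""

    seed: int = 0
    n_age_groups: int = 3
    total_population: int = 9000
    n_staples: int = 6
    n_sides: int = 9
    carb_skew: float = 0.85

    def __post_init__(self) -> None:
        if self.n_age_groups < 1 or self.n_staples < 1 or self.n_sides < 1:
            raise ConfigError("counts must be >= 1")
        if not 0.0 <= self.carb_skew <= 1.0:
            raise ConfigError(f"carb_skew must be in [0, 1], got {self.carb_skew}")
        if self.total_population < 2 * self.n_age_groups:
            raise ConfigError("population too small to fill every stratum")


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAM[stream]])


def _age_labels(n: int) -> list[str]:
    edges = np.linspace(0, 90, n + 1).astype(int)
    labels = [f"{edges[i]}-{edges[i + 1] - 1}" for i in range(n - 1)]
    labels.append(f"{edges[n - 1]}+")
    return labels


def gen_demographics(spec: FixtureSpec) -> DemographicTable:
    """A population pyramid with positive counts in every sex × age stratum
    summing exactly to ``total_population``."""
    rng = _rng(spec, "demographics")
    labels = _age_labels(spec.n_age_groups)
    strata = tuple(
        Stratum(sex=sex, age_group=ag) for ag in labels for sex in SEXES
    )
    w = rng.dirichlet(np.full(len(strata), 3.0))
    counts = np.floor(w * spec.total_population).astype(int)
    counts = np.maximum(counts, 1)
    # repair the rounding/clipping drift on the largest cells
    while counts.sum() > spec.total_population:
        i = int(np.argmax(counts))
        counts[i] -= 1
    while counts.sum() < spec.total_population:
        i = int(np.argmin(counts))
        counts[i] += 1
    return DemographicTable(
        municipality=f"Synthetic City {spec.seed}",
        counts={s: int(c) for s, c in zip(strata, counts)},
        strata=strata,
    )


def gen_dri(spec: FixtureSpec) -> DRITable:
    """A complete reference-intake grid over the synthetic nutrients with
    positive values varying by stratum (females scaled down, age groups
    jittered around the base values)."""
    rng = _rng(spec, "dri")
    labels = _age_labels(spec.n_age_groups)
    strata = tuple(
        Stratum(sex=sex, age_group=ag) for ag in labels for sex in SEXES
    )
    values: dict[tuple[str, Stratum], float] = {}
    for n in FIXTURE_NUTRIENTS:
        base = _DRI_BASE[n.id]
        for s in strata:
            sex_f = 0.85 if s.sex == "female" else 1.0
            jitter = rng.uniform(0.8, 1.2)
            values[(n.id, s)] = base * sex_f * jitter
    return DRITable(nutrients=FIXTURE_NUTRIENTS, values=values, strata=strata)


def gen_catalog(spec: FixtureSpec) -> FoodCatalog:
    """Staples are energy-dense and vitamin-poor; sides carry protein and
    the B1/B2/C vitamins.  Flags make some items perishable or
    cooking-required so the stockpilable filter has work to do."""
    rng = _rng(spec, "catalog")
    items: list[FoodItem] = []

    def flags(i: int) -> tuple[bool, bool]:
        # every 4th item perishable, every 4th (offset) needs cooking
        return (i % 4 != 3, i % 4 == 2)

    for i in range(spec.n_staples):
        shelf, cook = flags(i)
        # staple 0 is a germ-rice profile: the one staple that is B1-rich
        # (germ and bran carry thiamin) while staying low-protein
        b1 = rng.uniform(0.30, 0.50) if i == 0 else rng.uniform(0.0, 0.06)
        items.append(
            FoodItem(
                id=f"staple_{i:02d}",
                name="Synthetic germ rice" if i == 0 else f"Synthetic staple {i}",
                category="staple",
                per100g={
                    "energy": rng.uniform(330, 380),
                    "protein": rng.uniform(5, 8),
                    "fat": rng.uniform(0.5, 2.0),
                    "vitamin_b1": b1,
                    "vitamin_b2": rng.uniform(0.0, 0.04),
                    "vitamin_c": 0.0,
                    "calcium": rng.uniform(3, 10),
                },
                shelf_stable=shelf,
                requires_cooking=cook,
                contains_wheat=bool(i % 3 == 1),
                pack_grams=float(rng.choice([100, 150, 200])),
                cost_per_pack=float(np.round(rng.uniform(100, 400), 0)),
                volume_per_pack=float(np.round(rng.uniform(0.1, 0.4), 2)),
            )
        )
    # The first (up to) three sides are always-stockpilable specialist
    # profiles modeled on real shelter foods — a fortified
    # balanced-nutrition ration, small dried fish (protein/calcium), and
    # vitamin-rich dried vegetables.  They anchor the catalog's nutrient
    # span so an exact-cover stockpile is always constructible; the
    # remaining sides are random canned/pouched-style dishes.
    specialists = [
        (
            "Fortified balanced-nutrition ration",
            {
                "energy": rng.uniform(390, 430),
                "protein": rng.uniform(8, 10),
                "fat": rng.uniform(18, 24),
                "vitamin_b1": rng.uniform(0.8, 1.0),
                "vitamin_b2": rng.uniform(1.4, 1.8),
                "vitamin_c": rng.uniform(90, 120),
                "calcium": rng.uniform(180, 240),
            },
        ),
        (
            "Vegetable oil",
            {
                "energy": rng.uniform(880, 900),
                "protein": 0.0,
                "fat": rng.uniform(97, 100),
                "vitamin_b1": 0.0,
                "vitamin_b2": 0.0,
                "vitamin_c": 0.0,
                "calcium": 0.0,
            },
        ),
        (
            "Small dried fish",
            {
                "energy": rng.uniform(300, 340),
                "protein": rng.uniform(55, 68),
                "fat": rng.uniform(4, 8),
                "vitamin_b1": rng.uniform(0.1, 0.25),
                "vitamin_b2": rng.uniform(0.2, 0.4),
                "vitamin_c": 0.0,
                "calcium": rng.uniform(1800, 2400),
            },
        ),
        (
            "Pouched pork and beans",
            {
                "energy": rng.uniform(220, 280),
                "protein": rng.uniform(12, 16),
                "fat": rng.uniform(8, 14),
                "vitamin_b1": rng.uniform(0.5, 0.8),
                "vitamin_b2": rng.uniform(0.15, 0.25),
                "vitamin_c": 0.0,
                "calcium": rng.uniform(30, 60),
            },
        ),
        (
            "Canned fish in oil",
            {
                "energy": rng.uniform(290, 330),
                "protein": rng.uniform(16, 20),
                "fat": rng.uniform(22, 30),
                "vitamin_b1": rng.uniform(0.01, 0.05),
                "vitamin_b2": rng.uniform(0.15, 0.3),
                "vitamin_c": 0.0,
                "calcium": rng.uniform(200, 350),
            },
        ),
        (
            "Dried mixed vegetables",
            {
                "energy": rng.uniform(250, 300),
                "protein": rng.uniform(7, 10),
                "fat": rng.uniform(0.5, 1.5),
                "vitamin_b1": rng.uniform(0.3, 0.5),
                "vitamin_b2": rng.uniform(0.3, 0.6),
                "vitamin_c": rng.uniform(160, 220),
                "calcium": rng.uniform(400, 600),
            },
        ),
    ]
    for i in range(spec.n_sides):
        if i < len(specialists):
            name, comp = specialists[i]
            shelf, cook = True, False
        else:
            name, comp = f"Synthetic side dish {i}", {
                "energy": rng.uniform(80, 250),
                "protein": rng.uniform(8, 22),
                "fat": rng.uniform(2, 15),
                "vitamin_b1": rng.uniform(0.1, 0.6),
                "vitamin_b2": rng.uniform(0.1, 0.6),
                "vitamin_c": rng.uniform(5, 60),
                "calcium": rng.uniform(20, 300),
            }
            shelf, cook = flags(i)
        items.append(
            FoodItem(
                id=f"side_{i:02d}",
                name=name,
                category="side",
                per100g=comp,
                shelf_stable=shelf,
                requires_cooking=cook,
                contains_wheat=bool(i % 5 == 4),
                pack_grams=float(rng.choice([70, 100, 150])),
                cost_per_pack=float(np.round(rng.uniform(150, 500), 0)),
                volume_per_pack=float(np.round(rng.uniform(0.1, 0.5), 2)),
            )
        )
    return FoodCatalog(items=tuple(items), categories=("staple", "side"))


def gen_inventory(spec: FixtureSpec, catalog: FoodCatalog) -> Inventory:
    """A carbohydrate-skewed stockpile: total mass split carb_skew :
    (1 − carb_skew) between staples and sides.

    The total mass targets roughly 60 % energy coverage of the default
    scenario (20 % of the population for 3 days at ~2000 kcal/day,
    ~3.5 kcal per staple gram), so under the default 85 % skew the
    vitamin ratios come out well below the energy ratio — the pattern
    practitioners reported for real municipal stockpiles.
    """
    rng = _rng(spec, "inventory")
    victims = 0.2 * spec.total_population
    target_energy = victims * 3 * 2000.0 * 0.6
    total_grams = target_energy / 3.5

    # Municipal stockpiles hold commodity foods; the fortified/specialist
    # items (germ rice, fortified ration, dried fish, ...) are what the
    # planner should end up recommending, so only the plain "Synthetic"
    # items are stocked (falling back to the whole group if a tiny spec
    # leaves no plain item in it).
    staples = [it for it in catalog.items if it.category == "staple"]
    sides = [it for it in catalog.items if it.category != "staple"]
    plain_staples = [it for it in staples if it.name.startswith("Synthetic staple")]
    plain_sides = [it for it in sides if it.name.startswith("Synthetic side")]
    staples = plain_staples or staples
    sides = plain_sides or sides
    entries: list[InventoryEntry] = []
    for group, share in ((staples, spec.carb_skew), (sides, 1.0 - spec.carb_skew)):
        if not group or share == 0.0:
            continue
        w = rng.dirichlet(np.full(len(group), 2.0))
        for it, wi in zip(group, w):
            grams = float(np.round(share * total_grams * wi, 1))
            if grams > 0:
                entries.append(InventoryEntry(food_id=it.id, quantity_grams=grams))
    return Inventory(entries=tuple(entries))


def exact_cover_inventory(
    demo: DemographicTable,
    dri: DRITable,
    catalog: FoodCatalog,
    config: ScenarioConfig,
) -> Inventory:
    """An inventory whose assessment is exactly 100 % for every profile
    nutrient, found by non-negative least squares on the coverage system
    Σ_i q_i · content_i,n / 100 = required_n.

    Raises :class:`ConstructionError` when the catalog's nutrient span
    cannot reach the requirement vector (relative residual > 1e-9).
    """
    nutrients = nutrient_profile(config.profile, dri)
    if not nutrients:
        return Inventory(entries=())
    req = total_required(dri, demo, config)
    b = np.array([req.total_required[n] for n in nutrients])
    if np.any(b <= 0):
        zero = [n for n, v in zip(nutrients, b) if v <= 0]
        raise ConstructionError(
            f"exact cover needs positive requirements; zero for {zero}"
        )
    a = np.array(
        [[it.content(n) / 100.0 for it in catalog.items] for n in nutrients]
    )
    # row-normalize by the requirement so kcal and mg rows condition equally
    scale = b[:, None]
    x, _ = nnls(a / scale, b / b)
    resid = a @ x - b
    rel = np.abs(resid) / b
    if rel.max() > 1e-9:
        raise ConstructionError(
            f"catalog span cannot cover the profile exactly "
            f"(max relative residual {rel.max():.3e})"
        )
    # lift the solution so every row sits at/just above the requirement,
    # robust to summation-order noise when the assessment recomputes supply
    covered = a @ x
    factor = max(float(np.max(b / covered)), 1.0) * (1.0 + 1e-12)
    x = x * factor
    entries = tuple(
        InventoryEntry(food_id=it.id, quantity_grams=float(q))
        for it, q in zip(catalog.items, x)
        if q > 1e-9
    )
    return Inventory(entries=entries)
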