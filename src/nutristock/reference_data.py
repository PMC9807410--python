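"""Domain types and tabular I/O for stockpile assessment inputs.

Four tables drive an assessment run:

* a demographic table — residents per sex × age-group stratum of one
  municipality;
* a dietary-reference-intake (DRI) table — the per-person per-day
  reference value of each nutrient for each stratum;
* a food catalog — per-100 g nutrient composition plus category and
  stockpilability flags for every selectable food;
* a stockpile inventory — grams (or packs) held of each catalog food.

All readers accept a file path (delimiter inferred from the extension:
``.tsv`` → tab, otherwise comma) or an open text stream / DataFrame.
Writers emit the same column layout so read → write → read round-trips
are value-identical.  The column dictionary is documented in
``docs/input_formats.md``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._bundled_lists import (
    BUNDLED_ITEMS,
    CATEGORY_REQUIRES_COOKING,
    MAIN_SIDE_CATEGORIES,
    READY_TO_EAT,
    STAPLE_CATEGORIES,
    contains_wheat,
)
from .errors import CompletenessError, TableSchemaError, UnknownFoodError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Columns of a food-catalog table that are not nutrient compositions.
CATALOG_RESERVED_COLUMNS = (
    "id",
    "name",
    "category",
    "shelf_stable",
    "requires_cooking",
    "contains_wheat",
    "pack_grams",
    "cost_per_pack",
    "volume_per_pack",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientSpec:
    """Identity of one nutrient column: id token, display name, unit."""

    id: str
    name: str
    unit: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("nutrient id must be non-empty")
        if not self.unit:
            raise ValueError(f"nutrient {self.id!r}: unit must be non-empty")


@dataclass(frozen=True, order=True)
class Stratum:
    """One demographic cell: sex × age-group label."""

    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class DemographicTable:
    """Resident counts per stratum for a single municipality."""

    municipality: str
    counts: Mapping[Stratum, int]
    strata: tuple[Stratum, ...] = ()

    def __post_init__(self) -> None:
        strata = self.strata or tuple(self.counts)
        object.__setattr__(self, "strata", strata)
        if set(strata) != set(self.counts):
            raise TableSchemaError("strata order does not match counts keys")
        for s, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {s}: {c}")
        if self.total_population <= 0:
            raise ValueError("total population must be positive")

    @property
    def total_population(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class DRITable:
    """Per-person per-day reference values over nutrients × strata."""

    nutrients: tuple[NutrientSpec, ...]
    values: Mapping[tuple[str, Stratum], float]
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nutrients]
        if len(set(ids)) != len(ids):
            raise TableSchemaError("duplicate nutrient ids in DRI table")
        missing = [
            (nid, s)
            for nid in ids
            for s in self.strata
            if (nid, s) not in self.values
        ]
        if missing:
            raise CompletenessError(
                f"DRI grid missing {len(missing)} cell(s), first: {missing[0]}"
            )
        for key, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative DRI value for {key}: {v}")

    def nutrient(self, nutrient_id: str) -> NutrientSpec:
        for n in self.nutrients:
            if n.id == nutrient_id:
                return n
        raise KeyError(nutrient_id)

    def value(self, nutrient_id: str, stratum: Stratum) -> float:
        try:
            return self.values[(nutrient_id, stratum)]
        except KeyError:
            raise CompletenessError(
                f"no DRI value for nutrient {nutrient_id!r}, stratum {stratum}"
            ) from None


@dataclass(frozen=True)
class FoodItem:
    """One catalog food with per-100 g composition and planning metadata."""

    id: str
    name: str
    category: str
    per100g: Mapping[str, float] = field(default_factory=dict)
    shelf_stable: bool = True
    requires_cooking: bool = False
    contains_wheat: bool = False
    pack_grams: float = 100.0
    cost_per_pack: float | None = None
    volume_per_pack: float | None = None

    def __post_init__(self) -> None:
        if self.pack_grams <= 0:
            raise ValueError(f"{self.id}: pack_grams must be positive")
        for nid, v in self.per100g.items():
            if v < 0:
                raise ValueError(f"{self.id}: negative composition for {nid!r}: {v}")

    def content(self, nutrient_id: str) -> float:
        """Per-100 g content; absent nutrients read as 0 (the 'Tr/—'
        convention of food-composition tables)."""
        return float(self.per100g.get(nutrient_id, 0.0))


@dataclass(frozen=True)
class FoodCatalog:
    """An ordered food list partitioned into categories."""

    items: tuple[FoodItem, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise TableSchemaError(f"duplicate food ids: {sorted(dupes)}")
        bad = [it.id for it in self.items if it.category not in self.categories]
        if bad:
            raise TableSchemaError(
                f"items with category outside the catalog's category list: {bad}"
            )

    def __len__(self) -> int:
        return len(self.items)

    def get(self, food_id: str) -> FoodItem:
        for it in self.items:
            if it.id == food_id:
                return it
        raise UnknownFoodError(f"food id {food_id!r} not in catalog")

    def in_category(self, category: str) -> tuple[FoodItem, ...]:
        return tuple(it for it in self.items if it.category == category)

    def subset(self, food_ids: Iterable[str]) -> "FoodCatalog":
        wanted = set(food_ids)
        items = tuple(it for it in self.items if it.id in wanted)
        return FoodCatalog(items=items, categories=self.categories)


@dataclass(frozen=True)
class InventoryEntry:
    food_id: str
    quantity_grams: float

    def __post_init__(self) -> None:
        if self.quantity_grams < 0:
            raise ValueError(
                f"{self.food_id}: quantity_grams must be >= 0, got {self.quantity_grams}"
            )


@dataclass(frozen=True)
class Inventory:
    entries: tuple[InventoryEntry, ...] = ()

    def total_grams(self) -> float:
        return float(sum(e.quantity_grams for e in self.entries))

    def scaled(self, factor: float) -> "Inventory":
        return Inventory(
            tuple(replace(e, quantity_grams=e.quantity_grams * factor) for e in self.entries)
        )


# ---------------------------------------------------------------------------
# tabular I/O helpers
# ---------------------------------------------------------------------------

def _read_frame(source, required: Sequence[str]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = ","
        if isinstance(source, (str, Path)):
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(path)
            if path.suffix.lower() in {".tsv", ".tab"}:
                sep = "\t"
            df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        else:
            df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(f"missing required column(s): {missing}")
    return df


def _dest_sep(dest) -> str:
    if isinstance(dest, (str, Path)) and Path(dest).suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    return ","


_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _as_bool(value, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise TableSchemaError(f"column {column!r}: cannot parse boolean from {value!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_demographics(source) -> DemographicTable:
    """Read a demographic table (columns: municipality, sex, age_group, count).

    Strata are ordered canonically: age groups in file order, male before
    female within an age group.  Exactly one municipality per table.
    """
    df = _read_frame(source, ["municipality", "sex", "age_group", "count"])
    munis = df["municipality"].astype(str).unique()
    if len(munis) != 1:
        raise TableSchemaError(
            f"expected exactly one municipality per table, got {sorted(munis)}"
        )
    pairs = list(zip(df["sex"].astype(str), df["age_group"].astype(str)))
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        if p in seen:
            raise TableSchemaError(f"duplicate stratum {p} in demographic table")
        seen.add(p)

    age_order: list[str] = []
    for _, ag in pairs:
        if ag not in age_order:
            age_order.append(ag)
    rows = {
        Stratum(sex=str(r.sex), age_group=str(r.age_group)): int(r.count)
        for r in df.itertuples()
    }
    strata = tuple(
        Stratum(sex=sex, age_group=ag)
        for ag in age_order
        for sex in SEXES
        if Stratum(sex=sex, age_group=ag) in rows
    )
    counts = {s: rows[s] for s in strata}
    return DemographicTable(municipality=str(munis[0]), counts=counts, strata=strata)


def write_demographics(table: DemographicTable, dest) -> None:
    df = pd.DataFrame(
        {
            "municipality": table.municipality,
            "sex": [s.sex for s in table.strata],
            "age_group": [s.age_group for s in table.strata],
            "count": [table.counts[s] for s in table.strata],
        }
    )
    df.to_csv(dest, sep=_dest_sep(dest), index=False)


def read_dri_table(source) -> DRITable:
    """Read a long-format DRI table
    (columns: nutrient_id, unit, sex, age_group, value; optional nutrient_name).

    The grid must be complete over nutrients × strata.
    """
    df = _read_frame(source, ["nutrient_id", "unit", "sex", "age_group", "value"])
    if "nutrient_name" not in df.columns:
        df = df.assign(nutrient_name=df["nutrient_id"])

    nutrients: list[NutrientSpec] = []
    for nid, grp in df.groupby("nutrient_id", sort=False):
        units = grp["unit"].astype(str).unique()
        if len(units) != 1:
            raise TableSchemaError(f"nutrient {nid!r} has conflicting units: {list(units)}")
        nutrients.append(
            NutrientSpec(id=str(nid), name=str(grp["nutrient_name"].iloc[0]), unit=units[0])
        )

    age_order: list[str] = []
    for ag in df["age_group"].astype(str):
        if ag not in age_order:
            age_order.append(ag)
    present = {
        Stratum(sex=str(r.sex), age_group=str(r.age_group)) for r in df.itertuples()
    }
    strata = tuple(
        Stratum(sex=sex, age_group=ag)
        for ag in age_order
        for sex in SEXES
        if Stratum(sex=sex, age_group=ag) in present
    )

    values: dict[tuple[str, Stratum], float] = {}
    for r in df.itertuples():
        key = (str(r.nutrient_id), Stratum(sex=str(r.sex), age_group=str(r.age_group)))
        if key in values:
            raise TableSchemaError(f"duplicate DRI cell {key}")
        v = float(r.value)
        if v < 0:
            raise ValueError(f"negative DRI value for {key}: {v}")
        values[key] = v

    return DRITable(nutrients=tuple(nutrients), values=values, strata=strata)


def write_dri_table(table: DRITable, dest) -> None:
    recs = [
        {
            "nutrient_id": n.id,
            "nutrient_name": n.name,
            "unit": n.unit,
            "sex": s.sex,
            "age_group": s.age_group,
            "value": repr(table.values[(n.id, s)]),
        }
        for n in table.nutrients
        for s in table.strata
    ]
    pd.DataFrame(recs).to_csv(dest, sep=_dest_sep(dest), index=False)


def read_food_catalog(source, *, nutrients: Sequence[str] | None = None) -> FoodCatalog:
    """Read a food catalog (one row per food).

    Reserved columns are listed in :data:`CATALOG_RESERVED_COLUMNS`; every
    other column is a per-100 g nutrient composition.  If *nutrients* is
    given, composition columns outside that set are rejected.  Missing
    composition cells are treated as 0 with a logged warning.
    """
    df = _read_frame(source, ["id", "name", "category"])
    comp_cols = [c for c in df.columns if c not in CATALOG_RESERVED_COLUMNS]
    if nutrients is not None:
        unknown = [c for c in comp_cols if c not in set(nutrients)]
        if unknown:
            raise TableSchemaError(f"undeclared nutrient column(s): {unknown}")

    items: list[FoodItem] = []
    categories: list[str] = []
    for r in df.itertuples(index=False):
        row = r._asdict() if hasattr(r, "_asdict") else dict(zip(df.columns, r))
        per100g: dict[str, float] = {}
        for c in comp_cols:
            v = row[c]
            if pd.isna(v):
                logger.warning(
                    "food %s: missing composition for %s treated as 0", row["id"], c
                )
                v = 0.0
            per100g[c] = float(v)
        cat = str(row["category"])
        if cat not in categories:
            categories.append(cat)

        def _opt(colname: str) -> float | None:
            v = row.get(colname)
            return None if v is None or pd.isna(v) else float(v)

        pack = row.get("pack_grams")
        items.append(
            FoodItem(
                id=str(row["id"]),
                name=str(row["name"]),
                category=cat,
                per100g=per100g,
                shelf_stable=_as_bool(row.get("shelf_stable", True), "shelf_stable"),
                requires_cooking=_as_bool(
                    row.get("requires_cooking", False), "requires_cooking"
                ),
                contains_wheat=_as_bool(
                    row.get("contains_wheat", False), "contains_wheat"
                ),
                pack_grams=100.0 if pack is None or pd.isna(pack) else float(pack),
                cost_per_pack=_opt("cost_per_pack"),
                volume_per_pack=_opt("volume_per_pack"),
            )
        )
    return FoodCatalog(items=tuple(items), categories=tuple(categories))


def write_food_catalog(catalog: FoodCatalog, dest) -> None:
    nutrient_cols: list[str] = []
    for it in catalog.items:
        for nid in it.per100g:
            if nid not in nutrient_cols:
                nutrient_cols.append(nid)
    recs = []
    for it in catalog.items:
        rec: dict[str, object] = {
            "id": it.id,
            "name": it.name,
            "category": it.category,
            "shelf_stable": it.shelf_stable,
            "requires_cooking": it.requires_cooking,
            "contains_wheat": it.contains_wheat,
            "pack_grams": repr(it.pack_grams),
            "cost_per_pack": "" if it.cost_per_pack is None else repr(it.cost_per_pack),
            "volume_per_pack": ""
            if it.volume_per_pack is None
            else repr(it.volume_per_pack),
        }
        for c in nutrient_cols:
            rec[c] = repr(it.content(c))
        recs.append(rec)
    pd.DataFrame(recs).to_csv(dest, sep=_dest_sep(dest), index=False)


def read_inventory(source, *, catalog: FoodCatalog | None = None) -> Inventory:
    """Read a stockpile inventory (columns: food_id + quantity_grams | packs).

    Quantities normalize to grams at read time.  A ``packs`` column is
    converted through each food's ``pack_grams`` and therefore requires
    *catalog*.  An empty file is a valid, empty inventory.
    """
    try:
        df = _read_frame(source, ["food_id"])
    except pd.errors.EmptyDataError:
        return Inventory(entries=())
    if df.empty:
        return Inventory(entries=())
    has_grams = "quantity_grams" in df.columns
    has_packs = "packs" in df.columns
    if not has_grams and not has_packs:
        raise TableSchemaError("inventory needs a quantity_grams or packs column")
    entries: list[InventoryEntry] = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        fid = str(row["food_id"])
        if has_grams and not pd.isna(row.get("quantity_grams")):
            grams = float(row["quantity_grams"])
        elif has_packs and not pd.isna(row.get("packs")):
            if catalog is None:
                raise TableSchemaError(
                    "inventory uses packs; a catalog is required to convert to grams"
                )
            grams = float(row["packs"]) * catalog.get(fid).pack_grams
        else:
            raise TableSchemaError(f"inventory row for {fid!r} has no quantity")
        if grams < 0:
            raise ValueError(f"negative quantity for {fid!r}: {grams}")
        entries.append(InventoryEntry(food_id=fid, quantity_grams=grams))
    return Inventory(entries=tuple(entries))


def write_inventory(inv: Inventory, dest) -> None:
    df = pd.DataFrame(
        {
            "food_id": [e.food_id for e in inv.entries],
            "quantity_grams": [repr(e.quantity_grams) for e in inv.entries],
        },
        columns=["food_id", "quantity_grams"],
    )
    df.to_csv(dest, sep=_dest_sep(dest), index=False)


def read_workbook(path) -> dict[str, pd.DataFrame]:
    """Convenience spreadsheet import: one sheet per table, sheets named
    demographics / dri / catalog / inventory, honoring the CSV columns."""
    sheets = pd.read_excel(path, sheet_name=None)
    return {str(k).strip().lower(): v for k, v in sheets.items()}


# ---------------------------------------------------------------------------
# bundled catalog & alignment check
# ---------------------------------------------------------------------------

def _slug(name: str) -> str:
    out = []
    for ch in name.lower():
        if ch.isalnum():
            out.append(ch)
        elif out and out[-1] != "_":
            out.append("_")
    return "".join(out).strip("_")


def bundled_catalog() -> FoodCatalog:
    """The packaged transcription of the Simulator's printed food lists.

    Four staple groups and five main/side groups; names verbatim.  The
    source prints names and group membership only, so compositions are
    empty (read as 0) and the stockpilability flags are synthetic
    per-category defaults — see :mod:`nutristock._bundled_lists`.
    """
    categories = STAPLE_CATEGORIES + MAIN_SIDE_CATEGORIES
    items: list[FoodItem] = []
    used: set[str] = set()
    for cat in categories:
        for name in BUNDLED_ITEMS[cat]:
            base = _slug(name)
            fid, k = base, 2
            while fid in used:
                fid = f"{base}_{k}"
                k += 1
            used.add(fid)
            items.append(
                FoodItem(
                    id=fid,
                    name=name,
                    category=cat,
                    per100g={},
                    shelf_stable=True,
                    requires_cooking=(
                        CATEGORY_REQUIRES_COOKING[cat] and name not in READY_TO_EAT
                    ),
                    contains_wheat=contains_wheat(name),
                )
            )
    return FoodCatalog(items=tuple(items), categories=categories)


def validate_alignment(demo: DemographicTable, dri: DRITable) -> list[str]:
    """Report demographic strata that lack DRI values.

    Returns an empty list iff every demographic stratum has a DRI value
    for every nutrient; extra DRI-only strata are harmless.  Reports,
    never raises.
    """
    issues: list[str] = []
    for s in demo.strata:
        for n in dri.nutrients:
            if (n.id, s) not in dri.values:
                issues.append(
                    f"stratum ({s.sex}, {s.age_group}) has no DRI value for {n.id!r}"
                )
    return issues


def bind_inventory(inv: Inventory, catalog: FoodCatalog) -> Inventory:
    """Check that every inventory food id resolves against *catalog*."""
    for e in inv.entries:
        catalog.get(e.food_id)
    return inv
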