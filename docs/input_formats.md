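# Input formats — column dictionary

All tables are CSV (or TSV; the delimiter is inferred from the file
extension, `.tsv`/`.tab` → tab) with a header row, UTF-8 encoded.
An `.xlsx` workbook with one sheet per table (sheet names
`demographics`, `dri`, `catalog`, `inventory`) is accepted as a
convenience via `read_workbook`; sheets honor the same columns.

## demographics.csv

One row per sex × age-group stratum of a single municipality.

| column        | type   | notes                                        |
|---------------|--------|----------------------------------------------|
| municipality  | string | must be identical on every row               |
| sex           | enum   | `male` or `female`                           |
| age_group     | string | free label; must match the DRI table exactly |
| count         | int    | residents, ≥ 0; total must be > 0            |

Strata must be unique. Canonical ordering is age groups in file order,
male before female.

## dri.csv

Long format; the grid must be complete over nutrients × strata.

| column        | type   | notes                                   |
|---------------|--------|-----------------------------------------|
| nutrient_id   | string | e.g. `energy`, `protein`, `vitamin_b1`  |
| nutrient_name | string | optional display name (defaults to id)  |
| unit          | string | `kcal`, `g`, `mg`, `µg`, ...            |
| sex           | enum   | `male` / `female`                       |
| age_group     | string | must match demographics labels exactly  |
| value         | float  | per person per day, ≥ 0                 |

The `shelter5` profile requires the ids `energy`, `protein`,
`vitamin_b1`, `vitamin_b2`, `vitamin_c` to be present.

## catalog.csv

One row per food. Reserved columns below; **every other column is a
per-100 g nutrient composition** keyed by nutrient id. Empty
composition cells are read as 0 with a logged warning.

| column          | type   | notes                                    |
|-----------------|--------|------------------------------------------|
| id              | string | unique token                             |
| name            | string | display name                             |
| category        | string | free label                               |
| shelf_stable    | bool   | default true                             |
| requires_cooking| bool   | default false                            |
| contains_wheat  | bool   | default false                            |
| pack_grams      | float  | grams per pack, > 0, default 100         |
| cost_per_pack   | float  | optional, currency units                 |
| volume_per_pack | float  | optional, litres                         |

Booleans accept `true/false`, `yes/no`, `1/0`.

## inventory.csv

One row per stocked food; quantities normalize to grams at read time.

| column         | type   | notes                                        |
|----------------|--------|----------------------------------------------|
| food_id        | string | must resolve against the catalog             |
| quantity_grams | float  | ≥ 0; **or** supply `packs` instead           |
| packs          | float  | converted via the food's `pack_grams`        |

A header-only (or empty) file is a valid empty inventory.

## scenario config (YAML or JSON)

```yaml
affected_fraction: 0.20   # proportion of residents affected, [0, 1]
days: 3                   # days the stockpile must cover, >= 1
profile: full             # full | shelter5
victim_rounding: ceil     # ceil | round | floor
mark_boundary: inclusive  # inclusive (pass at 100%) | exclusive
```

Absent keys keep their defaults; unknown keys are rejected.
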