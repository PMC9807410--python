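# nutristock

Nutritional assessment and purchase planning for municipal emergency
food stockpiles.

Municipalities that run evacuation shelters must feed disaster victims
from their own food stockpiles until relief arrives — typically three to
five days. Whether a stockpile is *nutritionally* adequate, rather than
merely large, is the question this package answers, for public-health
dietitians and disaster-management staff: given a municipality's
population pyramid, a dietary-reference-intake (DRI) table, a food
catalog and the current inventory, it computes per-nutrient adequacy,
re-expresses it as the number of people actually covered, and recommends
what to buy to close the gaps.

## The model

For a municipality with resident counts `c_s` per sex × age-group
stratum `s`, the per-capita daily requirement of nutrient `n` is the
population-weighted mean of the reference values:

    r_n = Σ_s c_s · DRI[n, s] / Σ_s c_s

With affected fraction `f` (default 20 %) and `D` days covered
(default 3), the scenario requirement is

    R_n = r_n · V · D,     V = ⌈f · P⌉  victims out of population P.

Supply is summed from the inventory via per-100 g compositions,
`S_n = Σ_i q_i/100 · comp[i, n]`, and each nutrient is scored by the
excess/deficiency ratio `S_n / R_n × 100 %`, marked **Ο** (pass, ratio
≥ 100 %) or **×** (deficient). Two complementary views:

* **people covered** — `⌊S_n / (r_n · D)⌋`, the number of people whose
  full-period requirement the current stock meets;
* **shelter5 profile** — restrict the report to the five nutrients that
  matter most in shelter meal provision: energy, protein, vitamins B1,
  B2 and C.

The **planner** filters the catalog to genuinely stockpilable foods
(shelf-stable, no cooking required, optionally wheat-free) and closes
deficits either greedily in whole packs (best reduction in total
normalized deficit per unit cost) or as a least-cost diet LP in
continuous grams; every plan is re-verified through the independent
assessment path.

## Worked example

```sh
python examples/01_assess_stockpile.py
```

```
municipality: Synthetic City 1  victims: 1800
nutrient          required      supplied  ratio %  mark
energy             9928258       6229200     62.7  ×
protein             255707        148397     58.0  ×
fat                 285708         40985     14.3  ×
vitamin_b1            5549          1449     26.1  ×
vitamin_b2            6659          1282     19.3  ×
vitamin_c           498046        104773     21.0  ×
calcium            3260020        404447     12.4  ×
```

A 9000-resident synthetic municipality, 1800 estimated victims, 3 days.
The stockpile holds 85 % of its mass in staples, so energy reaches
62.7 % of the requirement while every vitamin sits far lower — the
carbohydrate-skew pattern that motivates stocking main/side dishes. The
other examples show the purchase planner (`02`), the people-covered
view (`03`) and the bundled transcription of the official food lists
(`04`).

The same pipeline is scriptable from the shell:

```sh
nutristock fixtures --seed 1 --out fx
nutristock assess   --demographics fx/demographics.csv --dri fx/dri.csv \
                    --catalog fx/catalog.csv --inventory fx/inventory.csv --out report
nutristock plan     ... --mode lp --budget 500000
nutristock coverage ...
```

Exit codes: 0 success, 2 I/O, 3 schema/validation, 4 configuration,
5 planning/infeasible. Input column layouts are documented in
`docs/input_formats.md`; the JSON report schema ships in
`src/nutristock/schemas/`.

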