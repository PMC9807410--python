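"""The packaged transcription of the official stockpile food lists.

The selectable food list is split into "staple foods" (four groups of
energy carriers) and "main and side dishes" (five groups carrying
protein and vitamins).  Compositions are not part of the printed lists,
so the items carry synthetic stockpilability flags only -- enough to
demonstrate wheat-allergy and no-cooking filtering.
"""
import nutristock as ns

catalog = ns.bundled_catalog()
print(f"{len(catalog)} items in {len(catalog.categories)} categories:")
for category in catalog.categories:
    print(f"  {category}: {len(catalog.in_category(category))} items")

wheat_free = ns.filter_stockpilable(
    catalog,
    ns.PlanningConstraints(
        require_shelf_stable=True, exclude_cooking=False, exclude_wheat=True
    ),
)
print(f"\nwheat-free items: {len(wheat_free)} of {len(catalog)}")
ready = ns.filter_stockpilable(catalog, ns.PlanningConstraints())
print(f"shelf-stable and ready-to-eat items: {len(ready)} of {len(catalog)}")

# Rice-group items stay available to people with wheat allergies, which
# is why the list guidance stresses stocking rice alongside dry bread,
# cookies and cup noodles.
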