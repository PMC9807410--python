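"""Tabular readers/writers, the bundled food lists, and alignment checks."""
import io
import warnings

import pandas as pd
import pytest

import nutristock as ns
from nutristock.errors import CompletenessError, TableSchemaError, UnknownFoodError

from conftest import csv_stream

DEMO_CSV = """
municipality,sex,age_group,count
Toyville,male,child,10
Toyville,female,child,20
Toyville,male,adult,30
Toyville,female,adult,40
Toyville,male,senior,50
Toyville,female,senior,60
"""

DRI_CSV = """
nutrient_id,unit,sex,age_group,value
energy,kcal,male,adult,2000
energy,kcal,female,adult,1700
"""


class TestReadDemographics:
    def test_sums_and_canonical_order(self):
        table = ns.read_demographics(csv_stream(DEMO_CSV))
        assert table.total_population == 210
        assert table.municipality == "Toyville"
        # age groups in file order, male before female
        assert [(s.sex, s.age_group) for s in table.strata[:2]] == [
            ("male", "child"),
            ("female", "child"),
        ]

    def test_minimal_two_row_table(self):
        text = "municipality,sex,age_group,count\nA,male,adult,50\nA,female,adult,50\n"
        assert ns.read_demographics(io.StringIO(text)).total_population == 100

    @pytest.mark.parametrize(
        "rows,err",
        [
            ("A,male,adult,50\nA,male,adult,60", TableSchemaError),  # duplicate stratum
            ("A,male,adult,-5\nA,female,adult,60", ValueError),  # negative count
            ("A,male,adult,0\nA,female,adult,0", ValueError),  # zero total
            ("A,male,adult,50\nB,female,adult,50", TableSchemaError),  # two municipalities
        ],
    )
    def test_rejects_bad_tables(self, rows, err):
        text = "municipality,sex,age_group,count\n" + rows + "\n"
        with pytest.raises(err):
            ns.read_demographics(io.StringIO(text))

    def test_missing_column_is_schema_error(self):
        with pytest.raises(TableSchemaError, match="count"):
            ns.read_demographics(io.StringIO("municipality,sex,age_group\nA,male,adult\n"))


class TestReadDRI:
    def test_small_grid(self):
        dri = ns.read_dri_table(csv_stream(DRI_CSV))
        assert [n.id for n in dri.nutrients] == ["energy"]
        assert dri.value("energy", ns.Stratum("female", "adult")) == 1700.0

    def test_missing_cell_is_completeness_error(self):
        text = (
            "nutrient_id,unit,sex,age_group,value\n"
            "energy,kcal,male,adult,2000\n"
            "energy,kcal,female,adult,1700\n"
            "protein,g,male,adult,60\n"  # protein × (female, adult) missing
        )
        with pytest.raises(CompletenessError):
            ns.read_dri_table(io.StringIO(text))

    def test_negative_value_rejected(self):
        text = "nutrient_id,unit,sex,age_group,value\nenergy,kcal,male,adult,-1\n"
        with pytest.raises(ValueError):
            ns.read_dri_table(io.StringIO(text))


class TestRoundTrips:
    """Read → write → read is value-identical for all four table types."""

    def test_demographics(self, tmp_path, fixture_set):
        _, demo, _, _, _ = fixture_set
        p = tmp_path / "demo.csv"
        ns.write_demographics(demo, p)
        assert ns.read_demographics(p) == demo

    def test_dri(self, tmp_path, fixture_set):
        _, _, dri, _, _ = fixture_set
        p = tmp_path / "dri.csv"
        ns.write_dri_table(dri, p)
        back = ns.read_dri_table(p)
        assert back.nutrients == dri.nutrients
        assert back.strata == dri.strata
        assert back.values == dri.values  # bit-exact

    def test_catalog(self, tmp_path, fixture_set):
        _, _, _, catalog, _ = fixture_set
        p = tmp_path / "catalog.csv"
        ns.write_food_catalog(catalog, p)
        assert ns.read_food_catalog(p) == catalog

    def test_inventory(self, tmp_path, fixture_set):
        _, _, _, _, inventory = fixture_set
        p = tmp_path / "inv.csv"
        ns.write_inventory(inventory, p)
        assert ns.read_inventory(p) == inventory

    def test_tsv_extension_switches_delimiter(self, tmp_path, fixture_set):
        _, demo, _, _, _ = fixture_set
        p = tmp_path / "demo.tsv"
        ns.write_demographics(demo, p)
        assert "\t" in p.read_text()
        assert ns.read_demographics(p) == demo


class TestReadCatalog:
    def test_two_item_toy(self):
        text = (
            "id,name,category,energy\n"
            "a,Food A,staple,350\n"
            "b,Food B,side,120\n"
        )
        cat = ns.read_food_catalog(io.StringIO(text))
        assert len(cat) == 2
        assert cat.get("a").content("energy") == 350.0

    def test_duplicate_id_rejected(self):
        text = "id,name,category,energy\na,A,c,1\na,A2,c,2\n"
        with pytest.raises(TableSchemaError):
            ns.read_food_catalog(io.StringIO(text))

    def test_negative_composition_rejected(self):
        text = "id,name,category,energy\na,A,c,-5\n"
        with pytest.raises(ValueError):
            ns.read_food_catalog(io.StringIO(text))

    def test_undeclared_nutrient_column_rejected(self):
        text = "id,name,category,energy,unobtainium\na,A,c,1,2\n"
        with pytest.raises(TableSchemaError, match="unobtainium"):
            ns.read_food_catalog(io.StringIO(text), nutrients=["energy"])

    def test_missing_composition_reads_as_zero(self, caplog):
        text = "id,name,category,energy,protein\na,A,c,350,\nb,B,c,100,5\n"
        with caplog.at_level("WARNING"):
            cat = ns.read_food_catalog(io.StringIO(text))
        assert cat.get("a").content("protein") == 0.0
        assert any("treated as 0" in r.message for r in caplog.records)


class TestReadInventory:
    def test_grams(self):
        inv = ns.read_inventory(io.StringIO("food_id,quantity_grams\nalpha_rice,5000\n"))
        assert inv.entries == (ns.InventoryEntry("alpha_rice", 5000.0),)

    def test_packs_convert_via_pack_grams(self):
        cat = ns.FoodCatalog(
            items=(ns.FoodItem(id="tuna_can", name="t", category="c", pack_grams=70.0),),
            categories=("c",),
        )
        inv = ns.read_inventory(io.StringIO("food_id,packs\ntuna_can,3\n"), catalog=cat)
        assert inv.entries[0].quantity_grams == 210.0

    def test_packs_without_catalog_rejected(self):
        with pytest.raises(TableSchemaError):
            ns.read_inventory(io.StringIO("food_id,packs\nx,3\n"))

    @pytest.mark.parametrize("text", ["", "food_id,quantity_grams\n"])
    def test_empty_is_valid(self, text):
        assert ns.read_inventory(io.StringIO(text)) == ns.Inventory(entries=())

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError):
            ns.read_inventory(io.StringIO("food_id,quantity_grams\nx,-1\n"))

    def test_binding_catches_unknown_id(self, toy_catalog):
        inv = ns.Inventory((ns.InventoryEntry("ghost", 10.0),))
        with pytest.raises(UnknownFoodError):
            ns.bind_inventory(inv, toy_catalog)


class TestBundledCatalog:
    @pytest.mark.parametrize(
        "category,count",
        [
            ("Rice and the like", 10),
            ("Wheat flour, rice flour, rice cakes", 10),
            ("Dried noodles, instant noodles, cup noodles", 13),
            ("Dried bread, cookies, and the like", 6),
            ("Pouched, sterilized food", 9),
            ("Canned food", 29),
            ("Dried food", 47),
        ],
    )
    def test_printed_category_counts(self, category, count):
        cat = ns.bundled_catalog()
        assert len(cat.in_category(category)) == count

    def test_nine_categories_and_unique_ids(self):
        cat = ns.bundled_catalog()
        assert len(cat.categories) == 9
        assert len({it.id for it in cat.items}) == len(cat.items) == 124

    def test_names_kept_verbatim(self):
        names = {it.name for it in ns.bundled_catalog().items}
        assert "Alpha rice" in names
        assert "Sweet red bean jelly (Youkan)" in names
        assert "Small, boiled–dried Katakuchi sardines" in names

    def test_duplicate_printed_name_gets_distinct_ids(self):
        cat = ns.bundled_catalog()
        rice_flours = [it for it in cat.items if it.name == "Rice flour"]
        assert len(rice_flours) == 2
        assert rice_flours[0].id != rice_flours[1].id

    def test_synthetic_flag_defaults(self):
        cat = ns.bundled_catalog()
        assert not cat.get("alpha_rice").requires_cooking  # ready to eat
        assert cat.get("dried_gourds").requires_cooking
        assert cat.get("wheat_flour").contains_wheat
        assert not cat.get("brown_rice").contains_wheat


class TestValidateAlignment:
    def test_identical_strata_clean(self, toy_demo, toy_dri):
        assert ns.validate_alignment(toy_demo, toy_dri) == []

    def test_missing_stratum_named(self, toy_demo, toy_dri):
        extra = ns.Stratum("male", "senior")
        demo = ns.DemographicTable(
            "Toyville",
            {**dict(toy_demo.counts), extra: 5},
            strata=toy_demo.strata + (extra,),
        )
        issues = ns.validate_alignment(demo, toy_dri)
        assert len(issues) == 1 and "senior" in issues[0]

    def test_extra_dri_strata_harmless(self, toy_demo, toy_dri):
        extra = ns.Stratum("male", "senior")
        dri = ns.DRITable(
            nutrients=toy_dri.nutrients,
            values={**dict(toy_dri.values), ("energy", extra): 2200.0},
            strata=toy_dri.strata + (extra,),
        )
        assert ns.validate_alignment(toy_demo, dri) == []

    def test_clean_alignment_implies_requirements_compute(self, fixture_set):
        _, demo, dri, _, _ = fixture_set
        assert ns.validate_alignment(demo, dri) == []
        ns.total_required(dri, demo, ns.ScenarioConfig())  # must not raise


class TestWorkbookImport:
    def test_one_sheet_per_table(self, tmp_path, fixture_set):
        _, demo, _, _, _ = fixture_set
        buf = io.StringIO()
        ns.write_demographics(demo, buf)
        buf.seek(0)
        df = pd.read_csv(buf)
        xlsx = tmp_path / "book.xlsx"
        with pd.ExcelWriter(xlsx) as w:
            df.to_excel(w, sheet_name="demographics", index=False)
        sheets = ns.read_workbook(xlsx)
        assert ns.read_demographics(sheets["demographics"]) == demo
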