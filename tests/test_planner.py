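"""Stockpilable filtering, deficit computation and both planning modes."""
import warnings

import pytest

import nutristock as ns
from nutristock.errors import ConfigError, ConsistencyError, PlanningError


def _report(rows: dict[str, tuple[float, float]], days: int = 1) -> ns.AssessmentReport:
    """Hand-built report: nutrient -> (required, supplied)."""
    cfg = ns.ScenarioConfig(days=days)
    return ns.AssessmentReport(
        scenario=cfg,
        municipality="T",
        victims=1,
        rows=tuple(
            ns.NutrientAssessment(
                nutrient=n,
                name=n,
                unit="u",
                required=req,
                supplied=sup,
                ratio_pct=ns.excess_deficiency_ratio(sup, req),
                mark=ns.mark(ns.excess_deficiency_ratio(sup, req)),
                people_covered=0,
            )
            for n, (req, sup) in rows.items()
        ),
    )


def _item(fid: str, energy: float, *, pack=100.0, cost=None, **flags) -> ns.FoodItem:
    return ns.FoodItem(
        id=fid,
        name=fid,
        category="c",
        per100g={"energy": energy},
        pack_grams=pack,
        cost_per_pack=cost,
        **flags,
    )


def _cat(*items: ns.FoodItem) -> ns.FoodCatalog:
    return ns.FoodCatalog(items=items, categories=("c",))


class TestFilterStockpilable:
    def test_default_filters_drop_perishable_and_cooking(self):
        cat = _cat(
            _item("ok", 100.0),
            _item("fresh", 100.0, shelf_stable=False),
            _item("raw", 100.0, requires_cooking=True),
        )
        kept = ns.filter_stockpilable(cat, ns.PlanningConstraints())
        assert [it.id for it in kept.items] == ["ok"]

    def test_wheat_exclusion_can_empty_catalog_with_warning(self):
        cat = _cat(_item("noodles", 100.0, contains_wheat=True))
        with pytest.warns(UserWarning):
            kept = ns.filter_stockpilable(
                cat, ns.PlanningConstraints(exclude_wheat=True)
            )
        assert len(kept) == 0

    def test_all_flags_off_is_identity(self):
        cat = _cat(
            _item("a", 1.0, shelf_stable=False),
            _item("b", 2.0, requires_cooking=True, contains_wheat=True),
        )
        off = ns.PlanningConstraints(
            require_shelf_stable=False, exclude_cooking=False, exclude_wheat=False
        )
        assert ns.filter_stockpilable(cat, off) == cat

    def test_whitelist(self):
        cat = _cat(_item("a", 1.0), _item("b", 2.0))
        kept = ns.filter_stockpilable(cat, ns.PlanningConstraints(candidate_ids=("b",)))
        assert [it.id for it in kept.items] == ["b"]


class TestDeficits:
    def test_subtraction_and_clipping(self):
        rep = _report({"energy": (1000.0, 400.0), "protein": (50.0, 80.0)})
        assert ns.deficits(rep) == {"energy": 600.0, "protein": 0.0}

    def test_zero_exactly_at_ratio_100(self):
        rep = _report({"energy": (1000.0, 1000.0)})
        assert ns.deficits(rep) == {"energy": 0.0}


class TestGreedyPlan:
    def test_single_candidate_closed_form(self):
        """600 kcal short, one 300 kcal pack → exactly 2 packs."""
        rep = _report({"energy": (1000.0, 400.0)})
        plan = ns.greedy_plan(rep, _cat(_item("bar", 300.0)))
        assert plan.feasible
        assert plan.suggestions == (
            ns.PurchaseSuggestion(food_id="bar", add_grams=200.0, packs=2, cost=None),
        )
        assert plan.objective == 200.0  # grams objective when unpriced

    def test_zero_deficits_empty_plan(self):
        rep = _report({"energy": (1000.0, 1200.0)})
        plan = ns.greedy_plan(rep, _cat(_item("bar", 300.0)))
        assert plan.feasible and plan.suggestions == () and plan.objective == 0.0

    def test_budget_below_one_pack_infeasible(self):
        rep = _report({"energy": (1000.0, 400.0)})
        cat = _cat(_item("bar", 300.0, cost=250.0))
        plan = ns.greedy_plan(rep, cat, ns.PlanningConstraints(budget=100.0))
        assert not plan.feasible and plan.suggestions == ()
        assert plan.violations

    def test_no_candidates_is_planning_error(self):
        rep = _report({"energy": (1000.0, 400.0)})
        cat = _cat(_item("fresh", 300.0, shelf_stable=False))
        with pytest.raises(PlanningError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ns.greedy_plan(rep, cat)

    def test_deterministic_suggestion_sequence(self, fixture_set):
        _, demo, dri, catalog, inventory = fixture_set
        rep = ns.assess(demo, dri, catalog, inventory, ns.ScenarioConfig())
        p1 = ns.greedy_plan(rep, catalog)
        p2 = ns.greedy_plan(rep, catalog)
        assert p1 == p2

    def test_tie_breaks_toward_cheaper_then_lexicographic(self):
        rep = _report({"energy": (1000.0, 400.0)})
        # identical nutrition; 'b' cheaper than 'a'
        cat = _cat(_item("a", 300.0, cost=250.0), _item("b", 300.0, cost=200.0))
        plan = ns.greedy_plan(rep, cat)
        assert {s.food_id for s in plan.suggestions} == {"b"}
        # equal cost → lexicographically first id
        cat2 = _cat(_item("zz", 300.0, cost=200.0), _item("aa", 300.0, cost=200.0))
        plan2 = ns.greedy_plan(rep, cat2)
        assert {s.food_id for s in plan2.suggestions} == {"aa"}

    def test_mixed_pricing_under_budget_cap_rejected(self):
        rep = _report({"energy": (1000.0, 400.0)})
        cat = _cat(_item("a", 300.0, cost=250.0), _item("b", 300.0))
        with pytest.raises(ConfigError):
            ns.greedy_plan(rep, cat, ns.PlanningConstraints(budget=1000.0))


class TestLpPlan:
    def test_single_candidate_closed_form(self):
        """600 kcal short at 350 kcal/100 g → 600/3.5 g."""
        rep = _report({"energy": (1000.0, 400.0)})
        plan = ns.lp_plan(rep, _cat(_item("bar", 350.0)))
        assert plan.feasible
        assert plan.suggestions[0].add_grams == pytest.approx(600.0 / 3.5, rel=1e-6)

    def test_infeasible_when_nutrient_unsupplied(self):
        rep = _report({"energy": (1000.0, 400.0), "vitamin_c": (100.0, 0.0)})
        plan = ns.lp_plan(rep, _cat(_item("bar", 350.0)))  # no vitamin C anywhere
        assert not plan.feasible
        assert any("vitamin_c" in v for v in plan.violations)

    def test_lp_never_beats_greedy_objective(self):
        for seed in range(8):
            spec = ns.FixtureSpec(seed=seed, total_population=200 + 31 * seed)
            demo = ns.gen_demographics(spec)
            dri = ns.gen_dri(spec)
            catalog = ns.gen_catalog(spec)
            inv = ns.gen_inventory(spec, catalog)
            rep = ns.assess(demo, dri, catalog, inv, ns.ScenarioConfig())
            g = ns.greedy_plan(rep, catalog)
            l = ns.lp_plan(rep, catalog)
            assert l.objective <= g.objective

    def test_enlarging_candidates_never_raises_objective(self):
        spec = ns.FixtureSpec(seed=5, total_population=300)
        demo = ns.gen_demographics(spec)
        dri = ns.gen_dri(spec)
        catalog = ns.gen_catalog(spec)
        inv = ns.gen_inventory(spec, catalog)
        rep = ns.assess(demo, dri, catalog, inv, ns.ScenarioConfig())
        full = ns.lp_plan(rep, catalog)
        stockpilable = ns.filter_stockpilable(catalog, ns.PlanningConstraints())
        sub_ids = tuple(it.id for it in stockpilable.items)[:6]
        sub = ns.lp_plan(rep, catalog, ns.PlanningConstraints(candidate_ids=sub_ids))
        if sub.feasible:
            assert full.objective <= sub.objective + 1e-9 * sub.objective


class TestVerifyPlan:
    def _instance(self):
        spec = ns.FixtureSpec(seed=3, total_population=240)
        demo = ns.gen_demographics(spec)
        dri = ns.gen_dri(spec)
        catalog = ns.gen_catalog(spec)
        inv = ns.gen_inventory(spec, catalog)
        rep = ns.assess(demo, dri, catalog, inv, ns.ScenarioConfig())
        return rep, catalog

    def test_both_modes_verify(self):
        rep, catalog = self._instance()
        for plan in (ns.greedy_plan(rep, catalog), ns.lp_plan(rep, catalog)):
            record = ns.verify_plan(plan, rep, catalog)
            assert record.ok
            assert record.max_rel_diff <= 1e-9
            assert all(v >= 100.0 for v in record.achieved_ratios.values())

    def test_tampered_plan_is_inconsistent(self):
        rep, catalog = self._instance()
        plan = ns.greedy_plan(rep, catalog)
        tampered = ns.PurchasePlan(
            mode=plan.mode,
            suggestions=plan.suggestions[1:],  # drop one purchase
            achieved_ratios=plan.achieved_ratios,
            objective=plan.objective,
            feasible=plan.feasible,
        )
        with pytest.raises(ConsistencyError):
            ns.verify_plan(tampered, rep, catalog)

    def test_empty_plan_on_zero_deficit_report(self):
        rep = _report({"energy": (1000.0, 1500.0)})
        cat = _cat(_item("bar", 300.0))
        plan = ns.greedy_plan(rep, cat)
        assert ns.verify_plan(plan, rep, cat).ok
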