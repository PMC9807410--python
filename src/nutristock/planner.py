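"""Stockpilable-food filtering and purchase-gap planning.

Given an assessment showing per-nutrient deficits, the planner answers
the practitioner's question "what and how much should be purchased?" in
two modes:

* ``greedy_plan`` — whole packs, actionable shopping list.  Deficits are
  normalized per nutrient (max(0, 1 − supplied/required)) so that kcal
  and µg nutrients are commensurable, and the candidate with the largest
  reduction in total normalized deficit per unit cost (per gram when the
  catalog is unpriced) is added one pack at a time.
* ``lp_plan`` — continuous grams, auditable least-cost bound, solved as
  a classic diet problem with HiGHS.  Its objective never exceeds the
  greedy objective on the same instance.

Both respect planning constraints: shelf stability, no-cooking,
wheat-free, an optional budget and storage-volume cap, and an optional
candidate whitelist.  ``verify_plan`` recomputes a plan's achieved
ratios through the assessment module — the independent path — and
raises if they disagree.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .assessment import AssessmentReport, excess_deficiency_ratio, total_supply
from .errors import ConfigError, ConsistencyError, PlanningError
from .reference_data import FoodCatalog, FoodItem, Inventory, InventoryEntry


@dataclass(frozen=True)
class PlanningConstraints:
    """Which foods count as stockpilable, and optional resource caps."""

    require_shelf_stable: bool = True
    exclude_cooking: bool = True
    exclude_wheat: bool = False
    budget: float | None = None
    volume_cap: float | None = None
    candidate_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.budget is not None and self.budget < 0:
            raise ConfigError(f"budget must be >= 0, got {self.budget}")
        if self.volume_cap is not None and self.volume_cap < 0:
            raise ConfigError(f"volume_cap must be >= 0, got {self.volume_cap}")
        if self.candidate_ids is not None:
            object.__setattr__(self, "candidate_ids", tuple(self.candidate_ids))


@dataclass(frozen=True)
class PurchaseSuggestion:
    food_id: str
    add_grams: float
    packs: int | None = None
    cost: float | None = None


@dataclass(frozen=True)
class PurchasePlan:
    mode: str
    suggestions: tuple[PurchaseSuggestion, ...]
    achieved_ratios: Mapping[str, float]
    objective: float
    feasible: bool
    violations: tuple[str, ...] = ()


@dataclass(frozen=True)
class VerificationRecord:
    ok: bool
    achieved_ratios: Mapping[str, float]
    max_rel_diff: float


def filter_stockpilable(
    catalog: FoodCatalog, constraints: PlanningConstraints
) -> FoodCatalog:
    """Keep only foods passing every active flag filter and the whitelist.

    An empty result warns (the caller may still want the empty catalog)
    rather than raising.
    """
    items = []
    for it in catalog.items:
        if constraints.require_shelf_stable and not it.shelf_stable:
            continue
        if constraints.exclude_cooking and it.requires_cooking:
            continue
        if constraints.exclude_wheat and it.contains_wheat:
            continue
        if constraints.candidate_ids is not None and it.id not in constraints.candidate_ids:
            continue
        items.append(it)
    if not items:
        warnings.warn(
            "no catalog item passes the stockpilable filters", stacklevel=2
        )
    return FoodCatalog(items=tuple(items), categories=catalog.categories)


def deficits(report: AssessmentReport) -> dict[str, float]:
    """Amount short per profile nutrient: max(0, required − supplied)."""
    return {r.nutrient: max(0.0, r.required - r.supplied) for r in report.rows}


def _candidate_arrays(
    candidates: Sequence[FoodItem], nutrients: Sequence[str]
) -> np.ndarray:
    """Per-gram nutrient content matrix, shape (n_items, n_nutrients)."""
    return np.array(
        [[it.content(n) / 100.0 for n in nutrients] for it in candidates], float
    )


def _cost_vectors(
    candidates: Sequence[FoodItem], constraints: PlanningConstraints
) -> tuple[np.ndarray, bool]:
    """Per-pack objective weights and whether the catalog is fully priced.

    With a budget cap every candidate must carry a price; with a volume
    cap, a volume.  Mixed priced/unpriced sets under a cap are an error
    rather than a silent guess.
    """
    priced = all(it.cost_per_pack is not None for it in candidates)
    if constraints.budget is not None and not priced:
        missing = [it.id for it in candidates if it.cost_per_pack is None]
        raise ConfigError(f"budget cap set but candidates lack prices: {missing}")
    if constraints.volume_cap is not None:
        no_vol = [it.id for it in candidates if it.volume_per_pack is None]
        if no_vol:
            raise ConfigError(f"volume cap set but candidates lack volumes: {no_vol}")
    if priced:
        weights = np.array([it.cost_per_pack for it in candidates], float)
    else:
        weights = np.array([it.pack_grams for it in candidates], float)
    return weights, priced


def greedy_plan(
    report: AssessmentReport,
    catalog: FoodCatalog,
    constraints: PlanningConstraints = PlanningConstraints(),
    max_packs: int = 1_000_000,
) -> PurchasePlan:
    """Integer-pack plan: repeatedly add one pack of the candidate with the
    best normalized-deficit reduction per unit cost.

    Ties break toward lower cost, then lexicographic food id, so the
    suggestion sequence is fully deterministic.  Stops feasible when all
    deficits reach zero; stops infeasible when no candidate reduces any
    deficit or a budget/volume cap binds.
    """
    filtered = filter_stockpilable(catalog, constraints)
    candidates = sorted(filtered.items, key=lambda it: it.id)
    if not candidates:
        raise PlanningError("no candidate foods after stockpilable filtering")

    nutrients = [r.nutrient for r in report.rows]
    required = np.array([r.required for r in report.rows], float)
    supplied = np.array([r.supplied for r in report.rows], float)
    per_gram = _candidate_arrays(candidates, nutrients)
    pack_grams = np.array([it.pack_grams for it in candidates], float)
    per_pack = per_gram * pack_grams[:, None]
    weights, priced = _cost_vectors(candidates, constraints)
    costs = (
        np.array([it.cost_per_pack for it in candidates], float)
        if priced
        else np.full(len(candidates), np.nan)
    )
    volumes = np.array(
        [
            np.nan if it.volume_per_pack is None else it.volume_per_pack
            for it in candidates
        ],
        float,
    )

    pos = required > 0
    packs = np.zeros(len(candidates), int)
    spent = 0.0
    used_volume = 0.0
    violations: list[str] = []

    def norm_deficit(sup: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            d = np.where(pos, np.maximum(0.0, 1.0 - sup / np.where(pos, required, 1.0)), 0.0)
        return float(d.sum())

    for _ in range(max_packs):
        if np.all(supplied >= required):
            break
        current = norm_deficit(supplied)
        # affordability mask under the caps
        ok = np.ones(len(candidates), bool)
        if constraints.budget is not None:
            ok &= spent + costs <= constraints.budget + 1e-9
        if constraints.volume_cap is not None:
            ok &= used_volume + volumes <= constraints.volume_cap + 1e-9
        if not ok.any():
            violations.append("budget/volume cap binds before deficits close")
            break
        new_sup = supplied[None, :] + per_pack
        with np.errstate(invalid="ignore"):
            nd = np.where(
                pos[None, :],
                np.maximum(0.0, 1.0 - new_sup / np.where(pos, required, 1.0)[None, :]),
                0.0,
            ).sum(axis=1)
        gain = current - nd
        score = np.where(ok & (gain > 0), gain / weights, -np.inf)
        if not np.isfinite(score).any() or score.max() <= 0:
            violations.append("no affordable candidate reduces any deficit")
            break
        best_score = score.max()
        tied = list(np.flatnonzero(score == best_score))
        if len(tied) > 1 and priced:
            min_cost = min(costs[i] for i in tied)
            tied = [i for i in tied if costs[i] == min_cost]
        i = tied[0]  # candidates pre-sorted by id → lexicographic tie-break
        packs[i] += 1
        supplied = supplied + per_pack[i]
        if priced:
            spent += costs[i]
        if constraints.volume_cap is not None:
            used_volume += volumes[i]
    else:
        violations.append(f"pack limit {max_packs} reached")

    feasible = bool(np.all(supplied >= required))
    suggestions = tuple(
        PurchaseSuggestion(
            food_id=candidates[i].id,
            add_grams=float(packs[i] * pack_grams[i]),
            packs=int(packs[i]),
            cost=float(packs[i] * costs[i]) if priced else None,
        )
        for i in np.flatnonzero(packs)
    )
    objective = float(spent) if priced else float((packs * pack_grams).sum())
    achieved = {
        n: excess_deficiency_ratio(float(supplied[k]), float(required[k]))
        for k, n in enumerate(nutrients)
    }
    return PurchasePlan(
        mode="greedy",
        suggestions=suggestions,
        achieved_ratios=achieved,
        objective=objective,
        feasible=feasible,
        violations=tuple(violations) if not feasible else (),
    )


def lp_plan(
    report: AssessmentReport,
    catalog: FoodCatalog,
    constraints: PlanningConstraints = PlanningConstraints(),
) -> PurchasePlan:
    """Continuous-grams least-cost plan (the diet problem).

    minimize Σ cost_i·x_i (total grams when unpriced)
    s.t.     supplied_n + Σ x_i·content_i,n ≥ required_n  ∀ profile nutrients
             Σ x_i·cost/g ≤ budget, Σ x_i·vol/g ≤ volume cap (when given)
             x ≥ 0.

    The solver solution is post-scaled by the minimal factor that makes
    every coverage row hold with ≥ in floating point, so a feasible plan
    achieves ratio ≥ 100 % literally.
    """
    filtered = filter_stockpilable(catalog, constraints)
    candidates = sorted(filtered.items, key=lambda it: it.id)
    if not candidates:
        raise PlanningError("no candidate foods after stockpilable filtering")

    nutrients = [r.nutrient for r in report.rows]
    required = np.array([r.required for r in report.rows], float)
    supplied = np.array([r.supplied for r in report.rows], float)
    per_gram = _candidate_arrays(candidates, nutrients)  # (items, nutrients)
    pack_weights, priced = _cost_vectors(candidates, constraints)
    per_gram_weight = pack_weights / np.array([it.pack_grams for it in candidates])
    c = per_gram_weight if priced else np.ones(len(candidates))

    gap = required - supplied
    a_ub = [-per_gram.T]  # coverage rows: -A x <= -(required - supplied)
    b_ub = [-gap]
    cap_rows: list[str] = []
    if constraints.budget is not None:
        a_ub.append(per_gram_weight[None, :])
        b_ub.append(np.array([constraints.budget]))
        cap_rows.append("budget")
    if constraints.volume_cap is not None:
        vol_per_gram = np.array(
            [it.volume_per_pack / it.pack_grams for it in candidates]
        )
        a_ub.append(vol_per_gram[None, :])
        b_ub.append(np.array([constraints.volume_cap]))
        cap_rows.append("volume")

    res = linprog(
        c,
        A_ub=np.vstack(a_ub),
        b_ub=np.concatenate(b_ub),
        bounds=(0, None),
        method="highs",
    )

    current_ratios = {
        n: excess_deficiency_ratio(float(supplied[k]), float(required[k]))
        for k, n in enumerate(nutrients)
    }
    if not res.success:
        violations = [
            f"nutrient {n!r} deficient but no candidate supplies it"
            for k, n in enumerate(nutrients)
            if gap[k] > 0 and not np.any(per_gram[:, k] > 0)
        ]
        violations.extend(f"{r} cap" for r in cap_rows)
        if not violations:
            violations = ["model infeasible under the given constraints"]
        return PurchasePlan(
            mode="lp",
            suggestions=(),
            achieved_ratios=current_ratios,
            objective=0.0,
            feasible=False,
            violations=tuple(violations),
        )

    x = np.maximum(res.x, 0.0)
    added = per_gram.T @ x
    # Binding rows sit exactly at the requirement up to solver tolerance;
    # scale up until they hold in float, then add a 1e-10 relative margin
    # so the >= survives any re-ordering of the supply summation.
    factor = 1.0
    for k in range(len(nutrients)):
        if gap[k] > 0 and added[k] > 0:
            while supplied[k] + factor * added[k] < required[k]:
                factor *= 1.0 + 1e-12
    x = x * (factor * (1.0 + 1e-10))
    added = per_gram.T @ x

    final = supplied + added
    feasible = bool(np.all(final >= required))
    suggestions = tuple(
        PurchaseSuggestion(
            food_id=candidates[i].id,
            add_grams=float(x[i]),
            packs=None,
            cost=float(x[i] * per_gram_weight[i]) if priced else None,
        )
        for i in np.flatnonzero(x > 1e-9)
    )
    objective = float(c @ x)
    achieved = {
        n: excess_deficiency_ratio(float(final[k]), float(required[k]))
        for k, n in enumerate(nutrients)
    }
    return PurchasePlan(
        mode="lp",
        suggestions=suggestions,
        achieved_ratios=achieved,
        objective=objective,
        feasible=feasible,
        violations=() if feasible else ("solver solution violates coverage",),
    )


def verify_plan(
    plan: PurchasePlan,
    report: AssessmentReport,
    catalog: FoodCatalog,
    rel_tol: float = 1e-9,
) -> VerificationRecord:
    """Independently recompute the plan's achieved ratios via the
    assessment module and confirm they match within *rel_tol* relative.

    For feasible plans, also confirms every profile ratio is ≥ 100 %.
    Raises :class:`ConsistencyError` on any mismatch.
    """
    nutrients = [r.nutrient for r in report.rows]
    additions = Inventory(
        tuple(
            InventoryEntry(food_id=s.food_id, quantity_grams=s.add_grams)
            for s in plan.suggestions
        )
    )
    added = total_supply(additions, catalog, nutrients).totals
    achieved: dict[str, float] = {}
    max_rel = 0.0
    for r in report.rows:
        ratio = excess_deficiency_ratio(r.supplied + added[r.nutrient], r.required)
        achieved[r.nutrient] = ratio
        claimed = plan.achieved_ratios[r.nutrient]
        if np.isinf(ratio) or np.isinf(claimed):
            if ratio != claimed:
                raise ConsistencyError(
                    f"{r.nutrient}: recomputed ratio {ratio} vs claimed {claimed}"
                )
            continue
        scale = max(abs(ratio), abs(claimed), 1.0)
        rel = abs(ratio - claimed) / scale
        max_rel = max(max_rel, rel)
        if rel > rel_tol:
            raise ConsistencyError(
                f"{r.nutrient}: recomputed ratio {ratio!r} differs from "
                f"claimed {claimed!r} (rel {rel:.3e})"
            )
    if plan.feasible:
        low = [n for n, v in achieved.items() if v < 100.0]
        if low:
            raise ConsistencyError(
                f"plan claims feasibility but nutrients below 100%: {low}"
            )
    return VerificationRecord(ok=True, achieved_ratios=achieved, max_rel_diff=max_rel)
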