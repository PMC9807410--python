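"""Supply totals, excess/deficiency ratios, pass marks, people covered.

For each nutrient the stockpile's supply is summed over inventory entries
(quantity in grams / 100 × per-100 g content), compared with the
scenario's required total as

    ratio = supplied / required × 100 (%),

and marked Ο (pass, ratio ≥ 100 %) or × (deficient).  A people-covered
view re-expresses the same supply as

    people = floor(supplied / (per-capita daily × days)),

the number of people whose full-period reference intake the current
stock meets — easier to read than percentages.

Degenerate rows never crash a report: required 0 with supplied 0 reads
as 100 %, required 0 with positive supply as +∞ (still a pass).
Internal values keep full precision; rendering rounds ratios to one
decimal for display only.
"""
from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .reference_data import FoodCatalog, Inventory
from .requirements import (
    DemographicTable,
    DRITable,
    ScenarioConfig,
    nutrient_profile,
    total_required,
)

MARK_PASS = "Ο"  # Ο  (greek capital omicron, as printed)
MARK_FAIL = "×"  # ×
_ASCII_MARK = {MARK_PASS: "O", MARK_FAIL: "x"}
_GLYPH_MARK = {v: k for k, v in _ASCII_MARK.items()}


@dataclass(frozen=True)
class SupplyResult:
    """Total amount of each nutrient supplied by an inventory."""

    totals: Mapping[str, float]


@dataclass(frozen=True)
class NutrientAssessment:
    nutrient: str
    name: str
    unit: str
    required: float
    supplied: float
    ratio_pct: float
    mark: str
    people_covered: int


@dataclass(frozen=True)
class AssessmentReport:
    scenario: ScenarioConfig
    municipality: str
    victims: int
    rows: tuple[NutrientAssessment, ...]

    def row(self, nutrient: str) -> NutrientAssessment:
        for r in self.rows:
            if r.nutrient == nutrient:
                return r
        raise KeyError(nutrient)


def total_supply(
    inv: Inventory, catalog: FoodCatalog, nutrients: Sequence[str]
) -> SupplyResult:
    """Sum each nutrient over the inventory: Σ grams/100 × per-100 g content.

    Unresolved food ids raise; nutrients a food's composition omits
    contribute 0 (the Tr/— convention).
    """
    totals = {n: 0.0 for n in nutrients}
    for e in inv.entries:
        item = catalog.get(e.food_id)
        factor = e.quantity_grams / 100.0
        for n in nutrients:
            totals[n] += factor * item.content(n)
    return SupplyResult(totals=totals)


def excess_deficiency_ratio(supplied: float, required: float) -> float:
    """supplied / required × 100, in percent.

    Conventions for degenerate rows: required 0 & supplied 0 → 100;
    required 0 & supplied > 0 → +inf.
    """
    if supplied < 0 or required < 0:
        raise ValueError("supplied and required must be non-negative")
    if required == 0:
        return 100.0 if supplied == 0 else math.inf
    return supplied / required * 100.0


def mark(ratio_pct: float, *, boundary: str = "inclusive") -> str:
    """Ο at/above 100 % (or strictly above, with boundary='exclusive'), else ×."""
    if boundary == "inclusive":
        return MARK_PASS if ratio_pct >= 100.0 else MARK_FAIL
    if boundary == "exclusive":
        return MARK_PASS if ratio_pct > 100.0 else MARK_FAIL
    raise ConfigError(f"unknown mark boundary {boundary!r}")


def people_covered(supplied: float, per_capita_daily: float, days: int) -> int:
    """People whose full-period requirement the supply meets:
    floor(supplied / (per-capita daily × days)); 0 when the denominator is 0.

    The floor is float-safe: the returned k always satisfies
    k·d ≤ supplied < (k+1)·d for d = per_capita_daily × days > 0.
    """
    denom = per_capita_daily * days
    if denom <= 0:
        return 0
    k = math.floor(supplied / denom)
    # guard against division rounding straddling an exact multiple
    while (k + 1) * denom <= supplied:
        k += 1
    while k > 0 and k * denom > supplied:
        k -= 1
    return k


def assess(
    demo: DemographicTable,
    dri: DRITable,
    catalog: FoodCatalog,
    inv: Inventory,
    config: ScenarioConfig,
) -> AssessmentReport:
    """End-to-end assessment: one row per profile nutrient with required,
    supplied, ratio, mark and people covered.  Deterministic."""
    req = total_required(dri, demo, config)
    nutrients = nutrient_profile(config.profile, dri)
    sup = total_supply(inv, catalog, nutrients)
    rows = []
    for n in nutrients:
        spec = dri.nutrient(n)
        supplied = sup.totals[n]
        required = req.total_required[n]
        ratio = excess_deficiency_ratio(supplied, required)
        rows.append(
            NutrientAssessment(
                nutrient=n,
                name=spec.name,
                unit=spec.unit,
                required=required,
                supplied=supplied,
                ratio_pct=ratio,
                mark=mark(ratio, boundary=config.mark_boundary),
                people_covered=people_covered(
                    supplied, req.per_capita_daily[n], config.days
                ),
            )
        )
    return AssessmentReport(
        scenario=config,
        municipality=demo.municipality,
        victims=req.victims,
        rows=tuple(rows),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _display_ratio(ratio: float) -> str:
    return "inf" if math.isinf(ratio) else f"{ratio:.1f}"


def report_to_dict(report: AssessmentReport) -> dict:
    """JSON-ready mapping; ratios at full precision (inf serialized as the
    string "inf") plus 1-decimal display strings, marks as ASCII tokens
    with the display glyph alongside."""
    return {
        "municipality": report.municipality,
        "victims": report.victims,
        "scenario": report.scenario.to_dict(),
        "rows": [
            {
                "nutrient": r.nutrient,
                "name": r.name,
                "unit": r.unit,
                "required": r.required,
                "supplied": r.supplied,
                "ratio_pct": "inf" if math.isinf(r.ratio_pct) else r.ratio_pct,
                "ratio_pct_display": _display_ratio(r.ratio_pct),
                "mark": _ASCII_MARK[r.mark],
                "mark_display": r.mark,
                "people_covered": r.people_covered,
            }
            for r in report.rows
        ],
    }


def report_from_dict(data: Mapping) -> AssessmentReport:
    rows = tuple(
        NutrientAssessment(
            nutrient=r["nutrient"],
            name=r["name"],
            unit=r["unit"],
            required=float(r["required"]),
            supplied=float(r["supplied"]),
            ratio_pct=math.inf if r["ratio_pct"] == "inf" else float(r["ratio_pct"]),
            mark=_GLYPH_MARK[r["mark"]],
            people_covered=int(r["people_covered"]),
        )
        for r in data["rows"]
    )
    return AssessmentReport(
        scenario=ScenarioConfig(**data["scenario"]),
        municipality=data["municipality"],
        victims=int(data["victims"]),
        rows=rows,
    )


CSV_COLUMNS = (
    "nutrient",
    "name",
    "unit",
    "required",
    "supplied",
    "ratio_pct",
    "mark",
    "people_covered",
)


def render_report(report: AssessmentReport, format: str = "json") -> str:
    """Serialize a report; 'json' keeps full precision, 'csv' is the
    1-decimal display mirror with one row per nutrient plus a header."""
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, ensure_ascii=False)
    if format == "csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(CSV_COLUMNS)
        for r in report.rows:
            w.writerow(
                [
                    r.nutrient,
                    r.name,
                    r.unit,
                    repr(r.required),
                    repr(r.supplied),
                    _display_ratio(r.ratio_pct),
                    _ASCII_MARK[r.mark],
                    r.people_covered,
                ]
            )
        return buf.getvalue()
    raise ConfigError(f"unknown report format {format!r}")


def parse_report(text: str) -> AssessmentReport:
    """Inverse of ``render_report(..., 'json')``."""
    return report_from_dict(json.loads(text))
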