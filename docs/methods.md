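# Methods

## Model and procedure

The assessment treats a stockpile scenario as four inputs — a
demographic table, a DRI table, a food catalog, an inventory — and one
configuration (affected fraction, days, nutrient profile). The
computation is deterministic and purely arithmetic:

1. **Victims.** `V = rounding(f · P)` over total population `P`.
   Rounding defaults to ceiling, which is conservative for relief
   planning; `floor` and half-up `round` are available because real
   deployments differ and the choice is not standardized.
2. **Weighted requirement.** Per-capita daily requirement of nutrient
   `n` is the population-weighted mean of the per-stratum reference
   values. The engine treats the DRI table as an opaque "reference value
   per day": whether a supplier fills it with EAR, RDA or DG statistics
   is their choice. Strata are matched by exact label equality between
   the demographic and DRI tables — no fuzzy age-bin mapping, because
   silent re-binning corrupts the weighting. Pregnancy/lactation
   additions are not modeled; they would need extra strata.
3. **Supply.** `S_n = Σ_i q_i/100 · comp[i, n]` with quantities
   normalized to grams at read time (packs are a convenience dialect
   converted through `pack_grams`). Composition values absent for a
   declared nutrient count as 0 with a logged warning, mirroring the
   "Tr/—" entries of food-composition tables without blocking a run.
4. **Scoring.** Ratio `S_n/R_n × 100`; the passing mark Ο is awarded at
   exactly 100 %. The boundary is configurable (`mark_boundary:
   exclusive`) because the inclusive rule, while the documented one, is
   not the only reading in circulation; the default follows the stated
   "100 % or above" rule. Degenerate rows never crash a report:
   `R = 0, S = 0` reads as 100 % and `R = 0, S > 0` as +∞ (a pass).
5. **People covered.** `⌊S_n / (r_n · D)⌋`, with 0 for a zero
   denominator. The floor is float-safe: the returned `k` satisfies
   `k·d ≤ S < (k+1)·d` in IEEE arithmetic, not merely in exact
   arithmetic (the raw division can round across an exact multiple).

Internal values keep full precision; only rendering rounds ratios to
one decimal. Machine formats carry ASCII `O`/`x` marks with the display
glyphs (Ο, ×) in a separate field, so downstream tooling never parses
non-ASCII.

## Planner

Deficits are `max(0, R_n − S_n)`. Candidates are the catalog items
passing the stockpilable filters (shelf-stable, no cooking, optional
wheat-free, optional whitelist) — the filter exists because practitioner
feedback on stockpile tools consistently names perishable and
cooking-dependent list entries as the main obstacle.

* **Greedy (whole packs).** Score each candidate by the reduction in
  `Σ_n max(0, 1 − S_n/R_n)` per unit cost (per gram when the catalog is
  unpriced), add one pack of the best, repeat. Deficits are normalized
  to be unitless so kcal and mg nutrients are commensurable — raw-unit
  sums would be dominated by energy. Ties break toward lower cost, then
  lexicographic food id, making the suggestion sequence total and the
  planner deterministic. Stops feasible when every deficit reaches
  zero; infeasible when no candidate reduces any deficit or a
  budget/volume cap binds.
* **LP (continuous grams).** Minimize `Σ cost_i x_i` (total grams when
  unpriced) subject to coverage and optional budget/volume rows, solved
  with HiGHS (`scipy.optimize.linprog`). The LP is a relaxation of the
  pack-integral problem, so its objective is a lower bound on the
  greedy objective. No fractional-pack rounding is applied afterwards:
  silent rounding can break feasibility, so users pick the mode.
* Mixed priced/unpriced candidate sets under a budget cap are a
  configuration error rather than a silent guess; the same for volume.

`verify_plan` recomputes achieved ratios through the assessment module
(the independent code path) and raises on disagreement beyond 1e-9
relative; for feasible plans it also asserts every ratio ≥ 100 %.

### Numerical choices

Exactly-binding LP rows sit at the requirement only up to solver
tolerance, and recomputing supply in a different summation order can
push them an ulp below 100 %. The LP solution is therefore scaled up by
the minimal factor that makes every coverage row hold in float, plus a
1e-10 relative margin — invisible at reporting precision, but it makes
"feasible ⇒ ratio ≥ 100 %" literal. The exact-cover constructor applies
the same lift with a 1e-12 margin. Greedy needs no such guard: whole
packs overshoot by construction. CSV round-trips are bit-exact because
writers emit `repr` floats and readers parse with pandas'
`float_precision="round_trip"`.

## Synthetic data

The generators produce the study conditions, not a dial to turn:

* **Demographics** — 2 sexes × 3 age groups, 9000 residents by default,
  Dirichlet-distributed positive counts summing exactly to the total.
* **DRI grid** — seven nutrients (the five shelter nutrients plus fat
  and calcium, so the full profile strictly contains shelter5) with
  per-person per-day bases at realistic magnitudes (energy 2000 kcal,
  protein 50 g, fat 60 g, B1 1.1 mg, B2 1.3 mg, C 100 mg, calcium
  650 mg), scaled 0.85× for female strata and jittered ±20 % per
  stratum.
* **Catalog** — 6 staples (energy 330–380 kcal/100 g, vitamin-poor) and
  9 sides. The first six sides are deterministic specialist profiles
  modeled on real shelter foods (fortified balanced-nutrition ration,
  vegetable oil, small dried fish, pouched pork, canned fish in oil,
  dried vegetables) and one staple is a B1-rich germ rice; together
  with the plain items they anchor the catalog's nutrient cone so an
  exact-cover stockpile is always constructible. Flag patterns make
  some items perishable or cooking-required so the filter has work to
  do. Every generator draws from its own documented substream of the
  single integer seed, so outputs are bit-identical per seed.
* **Inventory** — total mass targets ≈ 60 % energy coverage of the
  default scenario and is split 85 : 15 between staples and sides
  (configurable `carb_skew`), stocking only the plain commodity items;
  the fortified/specialist foods are deliberately absent, since they
  are what a purchase plan should introduce. This reproduces the
  documented real-world pattern: energy ratios far above vitamin
  ratios, everything below 100 %.
* **Exact cover** — non-negative least squares on the row-normalized
  coverage system; a relative residual above 1e-9 raises a construction
  error instead of returning a near-miss.

What the generators do *not* emulate: realistic Japanese municipal age
pyramids, official DRI values, or actual food-composition data — the
bundled transcription of the official food lists carries names and
group membership only, with synthetic per-category stockpilability
flags. Passing tests therefore demonstrate the computation and its
invariants, not calibration against official datasets; users supply
their own DRI and composition tables for real assessments.

## Problem sizes

The test suite and the acceptance script run the default municipality
(9000 residents) for assessment-level checks, 100 planner instances at
populations of 150–1250 (both planning modes verified per instance),
and 1000 randomized triples for the people-covered bracket. These sizes
exercise every code path while keeping a full run in seconds.

## Known limitations

Single municipality per run (no aggregation); no day-time-population
adjustment; no shelf-life or rotation scheduling; no menu or
palatability modeling; charts are left to downstream consumers of the
JSON report. Curated "standard model" food combinations are content,
not algorithm, and belong in user-supplied catalog/template files.
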