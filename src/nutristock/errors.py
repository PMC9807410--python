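"""Exception hierarchy.

Every error a caller can meaningfully branch on derives from
:class:`NutristockError`.  The CLI maps these onto its exit-code contract
(I/O = 2, schema = 3, configuration = 4, planning = 5).
"""


class NutristockError(Exception):
    """Base class for all package-specific errors."""


class TableSchemaError(NutristockError):
    """An input table violates its structural contract (missing or
    duplicate columns/rows, unresolved references, undeclared nutrients)."""


class CompletenessError(TableSchemaError):
    """A reference-intake grid is missing a (nutrient, stratum) cell."""


class UnknownFoodError(TableSchemaError):
    """An inventory entry references a food id absent from the catalog."""


class ConfigError(NutristockError):
    """A scenario or planner configuration value is invalid."""


class ProfileError(ConfigError):
    """A nutrient profile cannot be resolved against the reference table."""


class PlanningError(NutristockError):
    """The purchase planner cannot run (e.g. no candidate foods)."""


class ConsistencyError(NutristockError):
    """Independent recomputation of a plan's achieved ratios disagrees
    with the ratios the plan itself reports."""


class ConstructionError(NutristockError):
    """A synthetic fixture with the requested property cannot be built
    (e.g. the catalog does not span the nutrient profile)."""
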