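"""liftrr: from data-mining lift to epidemiological effect measures.

Rule miners summarise an exposure->outcome association with lift, support
and confidence; health researchers want relative risks and odds ratios.
For any 2x2 exposure-outcome table the measures are linked exactly::

    RR = (1 - P(E)) lift / (1 - P(E) lift)
    OR = (RR - P(O) lift) / (1 - P(O) lift)

with P(E) = support/confidence and P(O) = confidence/lift, so mined indices
alone determine RR and OR.  The package provides the exact table algebra,
the conversion, a Fisher-screened enumerative rule miner and a synthetic
cohort generator for end-to-end checks.
"""

from .convert import (
    effects_from_indices,
    lift_upper_bound,
    or_from_lift,
    rr_from_lift,
    rr_lift_curve,
)
from .errors import (
    ConversionInputError,
    InconsistentIndicesError,
    InvalidTableError,
    LiftRRError,
    UndefinedIndexError,
)
from .measures import (
    fisher_exact_positive,
    lift,
    odds_ratio,
    prevalences,
    relative_risk,
)
from .miner import Rule, TransactionMatrix, mine_rules, rule_table
from .synth import ExpectedIndices, SimulationSpec, expected_indices, simulate_cohort
from .tables import (
    ContingencyTable,
    EffectEstimates,
    IndexSet,
    from_counts,
    indices_from_table,
    table_from_indices,
)

__version__ = "0.1.0"

__all__ = [
    "__version__",
    "ContingencyTable",
    "IndexSet",
    "EffectEstimates",
    "from_counts",
    "indices_from_table",
    "table_from_indices",
    "lift",
    "relative_risk",
    "odds_ratio",
    "prevalences",
    "fisher_exact_positive",
    "rr_from_lift",
    "or_from_lift",
    "effects_from_indices",
    "lift_upper_bound",
    "rr_lift_curve",
    "TransactionMatrix",
    "Rule",
    "rule_table",
    "mine_rules",
    "SimulationSpec",
    "ExpectedIndices",
    "simulate_cohort",
    "expected_indices",
    "worked_example",
]


def worked_example() -> "ContingencyTable":
    """The bundled worked example: a mined rule from a birth cohort.

    333,250 singleton births screened for small-for-gestational-age (SGA)
    outcome against exposure to a three-chemical airborne mixture; counts
    (a, b, c, d) = (7828, 64021, 21851, 239550).  Its indices round to
    lift 1.22, RR 1.30, OR 1.34.
    """
    return from_counts(7828, 64021, 21851, 239550)
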