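"""Exception hierarchy.

All domain errors derive from :class:`LiftRRError` so callers can catch one
base class; each also derives from ``ValueError`` because every one of them
signals invalid input rather than an internal failure.
"""


class LiftRRError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidTableError(LiftRRError):
    """A 2x2 table with negative cells or no observations at all."""


class UndefinedIndexError(LiftRRError):
    """An association index requested for a table on which it is undefined.

    Raised when a margin needed in a denominator is zero (nobody exposed,
    nobody non-exposed, no outcomes) or when a rule has zero support, so the
    (support, confidence, lift) summary carries no information.
    """


class InconsistentIndicesError(LiftRRError):
    """A (support, confidence, lift) triple that no 2x2 table can produce.

    Covers both violations of the probability-space constraints (e.g.
    support > confidence, or P(E) = support/confidence > 1) and, during cell
    reconstruction, rounded indices too coarse for the counts to be recovered
    self-consistently.  Reconstruction fails loudly with this error instead
    of returning wrong counts.
    """


class ConversionInputError(LiftRRError):
    """Lift/prevalence inputs violating lift <= min(1/P(E), 1/P(O)).

    No 2x2 table can produce such a combination, so conversion to relative
    risk or odds ratio is refused.
    """
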