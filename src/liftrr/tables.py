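"""Exact 2x2 exposure-outcome tables and data-mining index triples.

The two central value types live here:

* :class:`ContingencyTable` — the four cell counts of the classic
  epidemiological 2x2 table (exposed/non-exposed vs outcome/no-outcome),
* :class:`IndexSet` — the (support, confidence, lift) summary a rule-mining
  package prints for one association rule.

Both representations describe the same rule, and with the cohort size N they
are interconvertible without loss: :func:`indices_from_table` computes the
indices from counts, and :func:`table_from_indices` reconstructs the counts
and verifies the reconstruction, refusing to guess when the inputs were
rounded too coarsely.

Arithmetic is generic over :class:`numbers.Real`: pass ``fractions.Fraction``
values to stay in exact rational arithmetic end to end, or plain floats for
everyday use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from typing import Optional

from .errors import InconsistentIndicesError, InvalidTableError, UndefinedIndexError

__all__ = [
    "ContingencyTable",
    "IndexSet",
    "EffectEstimates",
    "from_counts",
    "indices_from_table",
    "table_from_indices",
]

#: slack used when validating index triples given as rounded decimals
_VALIDATION_TOL = 1e-9

_HALF = Fraction(1, 2)


def _round_half_away(x: Real) -> int:
    """Round to the nearest integer, ties away from zero.

    Works for ``float`` and ``Fraction`` alike (``Fraction`` stays exact
    until the final floor).
    """
    if x >= 0:
        return math.floor(x + _HALF)
    return -math.floor(-x + _HALF)


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of a 2x2 exposure-outcome table.

    Cells follow the standard epidemiological layout::

                    outcome   no outcome
        exposed        a          b
        non-exposed    c          d

    Parameters
    ----------
    a, b, c, d
        Non-negative integer cell counts; at least one must be positive.

    Notes
    -----
    Tables with a zero margin (e.g. nobody non-exposed) are representable —
    they arise naturally from degenerate cohorts — but effect estimation on
    them raises :class:`~liftrr.errors.UndefinedIndexError` rather than
    silently returning arbitrary values.  Use :attr:`has_zero_margin` to
    screen for them.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int,)):
                if isinstance(v, Real) and float(v).is_integer():
                    object.__setattr__(self, name, int(v))
                else:
                    raise InvalidTableError(
                        f"cell {name}={v!r} is not integer-valued"
                    )
            if getattr(self, name) < 0:
                raise InvalidTableError(f"cell {name}={v} is negative")
        if self.n == 0:
            raise InvalidTableError("all four cells are zero")

    @property
    def n(self) -> int:
        """Total number of subjects, a + b + c + d."""
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def n_outcome(self) -> int:
        return self.a + self.c

    @property
    def n_no_outcome(self) -> int:
        return self.b + self.d

    @property
    def has_zero_margin(self) -> bool:
        """True when any row or column margin is zero.

        Such tables cannot support effect estimation: a comparator group or
        an outcome level is empty.
        """
        return 0 in (
            self.n_exposed,
            self.n_unexposed,
            self.n_outcome,
            self.n_no_outcome,
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class IndexSet:
    """The (support, confidence, lift) summary of one association rule.

    With exposure E (the rule antecedent, possibly a conjunction) and
    outcome O (the consequent):

    * ``support``    = P(OE), joint probability of exposure and outcome,
    * ``confidence`` = P(O|E), outcome probability among the exposed,
    * ``lift``       = P(O|E) / P(O), confidence relative to the base rate.

    The triple implicitly carries both prevalences: P(E) = support/confidence
    and P(O) = confidence/lift, exposed as :attr:`p_exposure` and
    :attr:`p_outcome`.  Validation enforces the constraints every real 2x2
    table satisfies — 0 < support <= confidence <= 1, lift >= confidence,
    and both implied prevalences in (0, 1] — with a small slack so that
    triples printed at two or three decimals still validate.

    Parameters
    ----------
    support, confidence, lift
        Index values; ``Fraction`` inputs are kept exact.
    n_total
        Cohort size N, required for reconstructing cell counts.
    """

    support: Real
    confidence: Real
    lift: Real
    n_total: Optional[int] = None

    def __post_init__(self) -> None:
        tol = _VALIDATION_TOL
        s, c, l = self.support, self.confidence, self.lift
        if not (s > 0):
            raise InconsistentIndicesError(f"support={s} must be positive")
        if s > c * (1 + tol):
            raise InconsistentIndicesError(
                f"support={s} exceeds confidence={c} (P(E) would exceed 1)"
            )
        if c > 1 + tol:
            raise InconsistentIndicesError(f"confidence={c} exceeds 1")
        if l < c * (1 - tol):
            raise InconsistentIndicesError(
                f"lift={l} below confidence={c} (P(O) would exceed 1)"
            )
        if self.n_total is not None and self.n_total <= 0:
            raise InconsistentIndicesError(f"n_total={self.n_total} must be positive")

    @property
    def p_exposure(self) -> Real:
        """Implied exposure prevalence P(E) = support / confidence."""
        return self.support / self.confidence

    @property
    def p_outcome(self) -> Real:
        """Implied outcome prevalence P(O) = confidence / lift."""
        return self.confidence / self.lift


@dataclass(frozen=True)
class EffectEstimates:
    """The three association measures of one rule, plus the prevalences.

    Lift, relative risk and odds ratio share the null value 1 and always
    fall on the same side of it; when all three are finite their log
    magnitudes are ordered |log OR| >= |log RR| >= |log lift|.  ``rr`` and
    ``or_`` may be ``+inf`` (a structural zero cell in the source table).
    """

    lift: float
    rr: float
    or_: float
    p_exposure: float
    p_outcome: float

    def __post_init__(self) -> None:
        if not self.lift > 0:
            raise InconsistentIndicesError(f"lift={self.lift} must be positive")
        for name in ("rr", "or_"):
            v = getattr(self, name)
            if not (v >= 0):  # inf allowed, NaN rejected
                raise InconsistentIndicesError(f"{name}={v} must be >= 0")
        for name in ("p_exposure", "p_outcome"):
            p = getattr(self, name)
            if not (0 < p < 1):
                raise InconsistentIndicesError(
                    f"{name}={p} must lie strictly inside (0, 1)"
                )


def from_counts(a: int, b: int, c: int, d: int) -> ContingencyTable:
    """Build and validate a 2x2 table from its four cell counts.

    Parameters
    ----------
    a, b, c, d
        Exposed-with-outcome, exposed-without, non-exposed-with,
        non-exposed-without.

    Raises
    ------
    InvalidTableError
        If any cell is negative or non-integer, or all four are zero.

    Examples
    --------
    >>> t = from_counts(7828, 64021, 21851, 239550)
    >>> t.n
    333250
    """
    return ContingencyTable(a, b, c, d)


def indices_from_table(t: ContingencyTable, *, exact: bool = False) -> IndexSet:
    """Compute (support, confidence, lift) from a 2x2 table.

    Parameters
    ----------
    t
        Table with positive exposure and outcome margins and a > 0.
    exact
        When True, return ``Fraction`` values instead of floats.

    Raises
    ------
    UndefinedIndexError
        If nobody is exposed (a+b = 0), nobody has the outcome (a+c = 0) —
        the denominators of confidence and lift — or the rule has zero
        support (a = 0), in which case the triple carries no information.
    """
    if t.n_exposed == 0:
        raise UndefinedIndexError("zero exposure margin: confidence undefined")
    if t.n_outcome == 0:
        raise UndefinedIndexError("zero outcome margin: lift undefined")
    if t.a == 0:
        raise UndefinedIndexError("zero support: rule never co-occurs with outcome")
    support = Fraction(t.a, t.n)
    confidence = Fraction(t.a, t.n_exposed)
    lift = Fraction(t.a * t.n, t.n_exposed * t.n_outcome)
    if not exact:
        support, confidence, lift = float(support), float(confidence), float(lift)
    return IndexSet(support=support, confidence=confidence, lift=lift, n_total=t.n)


def table_from_indices(idx: IndexSet, *, rtol: float = 1e-6) -> ContingencyTable:
    """Reconstruct the 2x2 cell counts from (support, confidence, lift, N).

    The inverse of :func:`indices_from_table`.  Cell counts are recovered by
    rounding ``support*N`` (cell a), ``a/confidence`` (exposed margin) and
    ``N*confidence/lift`` (outcome margin) to the nearest integers — ties
    away from zero — and the reconstruction is then *verified*: the indices
    re-derived from the reconstructed table must match the inputs to within
    ``rtol`` relative.  Indices printed at low precision (two significant
    digits, say) generally cannot be reconstructed and are rejected rather
    than silently mapped to wrong counts.

    Parameters
    ----------
    idx
        Index triple with ``n_total`` set.  ``Fraction``-valued indices from
        :func:`indices_from_table` ``exact=True`` reconstruct perfectly.
    rtol
        Relative tolerance of the reconstruct-and-verify check.

    Raises
    ------
    InconsistentIndicesError
        If ``n_total`` is missing, a reconstructed cell is negative, or the
        re-derived indices disagree with the inputs beyond ``rtol``.
    """
    if idx.n_total is None:
        raise InconsistentIndicesError("n_total is required to reconstruct counts")
    n = idx.n_total
    a = _round_half_away(idx.support * n)
    if a <= 0:
        raise InconsistentIndicesError(
            f"support={idx.support} with N={n} rounds to a zero 'a' cell"
        )
    n_exposed = _round_half_away(a / idx.confidence)
    n_outcome = _round_half_away(n * idx.confidence / idx.lift)
    b = n_exposed - a
    c = n_outcome - a
    d = n - a - b - c
    if min(a, b, c, d) < 0:
        raise InconsistentIndicesError(
            f"indices {idx} reconstruct to negative cells ({a}, {b}, {c}, {d})"
        )
    t = ContingencyTable(a, b, c, d)
    redone = indices_from_table(t, exact=True)
    for name in ("support", "confidence", "lift"):
        got = float(getattr(redone, name))
        want = float(getattr(idx, name))
        if not math.isclose(got, want, rel_tol=rtol):
            raise InconsistentIndicesError(
                f"reconstructed table ({a}, {b}, {c}, {d}) yields {name}={got!r}, "
                f"input was {want!r} (beyond rtol={rtol}); the inputs are "
                "likely rounded too coarsely to recover counts"
            )
    return t
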