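"""Point estimation of association measures from 2x2 cell counts.

All estimators take a :class:`~liftrr.tables.ContingencyTable` and work
directly on the counts:

* :func:`lift`          — P(O|E) / P(O) = aN / ((a+b)(a+c)); null value 1,
* :func:`relative_risk` — P(O|E) / P(O|not-E) = (a/(a+b)) / (c/(c+d)),
* :func:`odds_ratio`    — (a/b) / (c/d) = ad / bc,
* :func:`prevalences`   — the margins P(E) = (a+b)/N and P(O) = (a+c)/N,
* :func:`fisher_exact_positive` — one-sided exact test of positive
  exposure-outcome dependence, the screen used to retain mined rules.

Zero cells are expected in mined rules, so ``+inf`` is a first-class return
value for the ratio measures (e.g. RR when no non-exposed subject has the
outcome), never an exception.  Only structurally undefined requests — an
empty exposure group, or no outcome events at all — raise.

Pass ``exact=True`` to the ratio measures to get ``fractions.Fraction``
results; the package-wide exhaustive identity checks run in exact rational
arithmetic this way.
"""

from __future__ import annotations

from fractions import Fraction
from numbers import Real

from scipy.stats import hypergeom

from .errors import UndefinedIndexError
from .tables import ContingencyTable

__all__ = [
    "lift",
    "relative_risk",
    "odds_ratio",
    "prevalences",
    "fisher_exact_positive",
]

_INF = float("inf")


def _finish(value: Fraction, exact: bool) -> Real:
    return value if exact else float(value)


def lift(t: ContingencyTable, *, exact: bool = False) -> Real:
    """Lift of exposure for outcome: P(O|E) / P(O) = aN / ((a+b)(a+c)).

    Symmetric in the roles of exposure and outcome, so the same value is the
    lift of outcome for exposure.  Requires a positive exposure margin and a
    positive outcome margin; raises :class:`UndefinedIndexError` otherwise.
    """
    if t.n_exposed == 0:
        raise UndefinedIndexError("zero exposure margin: lift undefined")
    if t.n_outcome == 0:
        raise UndefinedIndexError("zero outcome margin: lift undefined")
    return _finish(Fraction(t.a * t.n, t.n_exposed * t.n_outcome), exact)


def relative_risk(t: ContingencyTable, *, exact: bool = False) -> Real:
    """Relative risk: outcome risk in the exposed over the non-exposed.

    Returns ``+inf`` when the outcome occurs only among the exposed (c = 0,
    a > 0) and 0 when it occurs only among the non-exposed (a = 0, c > 0).

    Raises
    ------
    UndefinedIndexError
        If either exposure group is empty (a+b = 0 or c+d = 0), or no
        subject at all has the outcome (a = c = 0): risk ratios need both
        comparator groups and at least one event.
    """
    if t.n_exposed == 0 or t.n_unexposed == 0:
        raise UndefinedIndexError("empty exposure group: relative risk undefined")
    if t.a == 0 and t.c == 0:
        raise UndefinedIndexError("no outcome events: relative risk undefined")
    if t.c == 0:
        return _INF
    return _finish(Fraction(t.a * t.n_unexposed, t.c * t.n_exposed), exact)


def odds_ratio(
    t: ContingencyTable, *, exact: bool = False, haldane: bool = False
) -> Real:
    """Odds ratio ad / bc, optionally with the Haldane-Anscombe correction.

    Returns ``+inf`` for an uncorrected table with b*c = 0 and a*d > 0.
    ``haldane=True`` adds 0.5 to every cell first (the usual small-sample /
    zero-cell correction), which always yields a finite value.

    Raises as :func:`relative_risk`.
    """
    if t.n_exposed == 0 or t.n_unexposed == 0:
        raise UndefinedIndexError("empty exposure group: odds ratio undefined")
    if t.a == 0 and t.c == 0:
        raise UndefinedIndexError("no outcome events: odds ratio undefined")
    if haldane:
        num = (Fraction(t.a) + Fraction(1, 2)) * (Fraction(t.d) + Fraction(1, 2))
        den = (Fraction(t.b) + Fraction(1, 2)) * (Fraction(t.c) + Fraction(1, 2))
        return _finish(num / den, exact)
    if t.b * t.c == 0:
        if t.a * t.d == 0:
            raise UndefinedIndexError(
                "odds ratio 0/0: both diagonals contain a zero cell"
            )
        return _INF
    return _finish(Fraction(t.a * t.d, t.b * t.c), exact)


def prevalences(t: ContingencyTable, *, exact: bool = False) -> tuple[Real, Real]:
    """Exposure and outcome prevalence: ((a+b)/N, (a+c)/N)."""
    return (
        _finish(Fraction(t.n_exposed, t.n), exact),
        _finish(Fraction(t.n_outcome, t.n), exact),
    )


def fisher_exact_positive(t: ContingencyTable, *, two_sided: bool = False) -> float:
    """Fisher's exact test for exposure-outcome dependence.

    The default is the one-sided upper-tail p-value for *positive*
    dependence — the probability, under the hypergeometric null with all
    margins fixed, of an exposed-with-outcome cell at least as large as the
    observed ``a`` (the observed table's own probability is included in the
    tail).  This matches screening for rules with lift > 1; set
    ``two_sided=True`` for the conventional two-sided test.

    Returns a p-value in (0, 1].
    """
    if two_sided:
        # two-sided: sum of all hypergeometric outcomes no more probable
        # than the observed one
        from scipy.stats import fisher_exact as _fisher

        return float(
            _fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
        )
    # P(X >= a) for X ~ Hypergeom(N, a+b, a+c)
    p = float(hypergeom.sf(t.a - 1, t.n, t.n_exposed, t.n_outcome))
    return min(p, 1.0)
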