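"""Closed-form conversion from lift to relative risk and odds ratio.

A rule miner reports lift, but health researchers reason in relative risks
and odds ratios.  For any 2x2 exposure-outcome table the three measures are
algebraically linked through the exposure prevalence P(E) and outcome
prevalence P(O)::

    RR = (1 - P(E)) * lift / (1 - P(E) * lift)

    OR = (RR - P(O) * lift) / (1 - P(O) * lift)

so a (support, confidence, lift) triple — which carries P(E) =
support/confidence and P(O) = confidence/lift — determines RR and OR with no
access to the raw data.  These identities are exact: applied to the lift and
prevalences of any table they reproduce the directly cross-tabulated RR and
OR, including the infinite values produced by structural zero cells.

The conversion also exposes the structural ceiling on lift,
``lift <= min(1/P(E), 1/P(O))``: a rare exposure can in principle reach a
huge lift while a prevalent one cannot, which is why ranking rules by raw
lift penalises prevalent exposures and why converting to RR first is the
safer ranking key.

All functions do generic arithmetic: ``fractions.Fraction`` inputs give
exact rational results, floats give floats.
"""

from __future__ import annotations

from numbers import Real
from typing import Optional, Sequence

from .errors import ConversionInputError
from .tables import EffectEstimates, IndexSet

__all__ = [
    "rr_from_lift",
    "or_from_lift",
    "effects_from_indices",
    "lift_upper_bound",
    "rr_lift_curve",
]

#: slack on the products P(E)*lift and P(O)*lift that separates "structural
#: zero cell, infinite estimate" from "inputs inconsistent with any table";
#: printed two-decimal indices can stray slightly past the boundary.
DEFAULT_TOL = 1e-9

_INF = float("inf")


def rr_from_lift(lift: Real, p_exposure: Real, *, tol: float = DEFAULT_TOL) -> Real:
    """Relative risk implied by a lift value and the exposure prevalence.

    Evaluates ``(1 - P(E)) * lift / (1 - P(E) * lift)``.  The denominator
    ``1 - P(E)*lift`` equals c/(a+c) on any real table, so it is 0 exactly
    when no non-exposed subject has the outcome; values within ``tol`` of 0
    map to ``+inf`` accordingly, while a product beyond ``1 + tol`` means no
    table exists and raises.

    Parameters
    ----------
    lift
        Lift value, > 0 (1 is independence).
    p_exposure
        Exposure prevalence P(E), strictly inside (0, 1).
    tol
        Boundary slack, see :data:`DEFAULT_TOL`.

    Raises
    ------
    ConversionInputError
        If an input is out of range or ``p_exposure * lift > 1 + tol``.

    Examples
    --------
    >>> round(rr_from_lift(1.22, 0.22), 2)
    1.3
    """
    if not lift > 0:
        raise ConversionInputError(f"lift={lift} must be positive")
    if not (0 < p_exposure < 1):
        raise ConversionInputError(
            f"p_exposure={p_exposure} must lie strictly inside (0, 1); "
            "P(E)=1 leaves no non-exposed comparator group"
        )
    den = 1 - p_exposure * lift
    if den < -tol:
        raise ConversionInputError(
            f"p_exposure*lift = {float(p_exposure * lift)} exceeds 1: "
            "no 2x2 table is consistent with these inputs"
        )
    if den <= tol:
        return _INF
    return (1 - p_exposure) * lift / den


def or_from_lift(
    lift: Real,
    p_exposure: Real,
    p_outcome: Real,
    *,
    tol: float = DEFAULT_TOL,
) -> Real:
    """Odds ratio implied by lift and the two prevalences.

    Evaluates ``(RR - P(O)*lift) / (1 - P(O)*lift)`` with RR from
    :func:`rr_from_lift`.  Note ``P(O)*lift`` is the rule's confidence
    P(O|E); the denominator vanishes exactly when every exposed subject has
    the outcome (b = 0), and the result is then ``+inf``.

    Raises
    ------
    ConversionInputError
        If an input is out of range or either product P(E)*lift or
        P(O)*lift exceeds ``1 + tol``.
    """
    if not (0 < p_outcome < 1):
        raise ConversionInputError(
            f"p_outcome={p_outcome} must lie strictly inside (0, 1); "
            "P(O)=1 makes the outcome universal"
        )
    confidence = p_outcome * lift
    den = 1 - confidence
    if den < -tol:
        raise ConversionInputError(
            f"p_outcome*lift = {float(confidence)} exceeds 1 (confidence > 1): "
            "no 2x2 table is consistent with these inputs"
        )
    rr = rr_from_lift(lift, p_exposure, tol=tol)
    if den <= tol or rr == _INF:
        return _INF
    return (rr - confidence) / den


def effects_from_indices(
    idx: IndexSet, *, tol: float = DEFAULT_TOL
) -> EffectEstimates:
    """Convert one rule's (support, confidence, lift) to all effect measures.

    The prevalences are recovered from the triple itself — P(E) =
    support/confidence, P(O) = confidence/lift — and fed through
    :func:`rr_from_lift` and :func:`or_from_lift`.

    Beware rounded inputs: indices printed at two decimals drift (converting
    support=0.023, confidence=0.11, lift=1.22 gives RR ~ 1.29 where the
    exact fractions give 1.30).  Feed full-precision values when available.

    Raises
    ------
    ConversionInputError
        If the implied P(E) or P(O) is 1 (degenerate cohort) or the inputs
        are mutually inconsistent.
    """
    p_exposure = idx.p_exposure
    p_outcome = idx.p_outcome
    rr = rr_from_lift(idx.lift, p_exposure, tol=tol)
    or_ = or_from_lift(idx.lift, p_exposure, p_outcome, tol=tol)
    return EffectEstimates(
        lift=float(idx.lift),
        rr=float(rr),
        or_=float(or_),
        p_exposure=float(p_exposure),
        p_outcome=float(p_outcome),
    )


def lift_upper_bound(
    p_exposure: Real, p_outcome: Optional[Real] = None
) -> Real:
    """Largest lift any 2x2 table with these prevalences can attain.

    ``1/P(E)`` (reached when every exposed subject has the outcome), or
    ``min(1/P(E), 1/P(O))`` when the outcome prevalence is also known.

    Raises
    ------
    ConversionInputError
        If a prevalence is outside (0, 1).
    """
    if not (0 < p_exposure < 1):
        raise ConversionInputError(f"p_exposure={p_exposure} must be in (0, 1)")
    bound = 1 / p_exposure
    if p_outcome is not None:
        if not (0 < p_outcome < 1):
            raise ConversionInputError(f"p_outcome={p_outcome} must be in (0, 1)")
        bound = min(bound, 1 / p_outcome)
    return bound


def rr_lift_curve(
    p_exposure: Real, lift_grid: Sequence[Real], *, tol: float = DEFAULT_TOL
) -> list[tuple[Real, Real]]:
    """Trace RR as a function of lift at a fixed exposure prevalence.

    Returns ``(lift, rr)`` pairs for each grid value; the curve is convex in
    lift and the ratio RR/lift grows along it, steeper for higher
    prevalence — for rare exposures the curve hugs the diagonal RR = lift.

    Raises
    ------
    ConversionInputError
        If any grid value reaches or exceeds the ceiling 1/P(E); the
        message lists the offending values.
    """
    bound = lift_upper_bound(p_exposure)
    offending = [x for x in lift_grid if not x < bound]
    if offending:
        raise ConversionInputError(
            f"lift values {offending} are at or above the ceiling "
            f"1/P(E) = {float(bound)} for p_exposure={float(p_exposure)}"
        )
    return [(x, rr_from_lift(x, p_exposure, tol=tol)) for x in lift_grid]
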