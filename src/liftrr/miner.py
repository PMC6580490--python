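"""Desk-scale enumerative association-rule mining over binary cohorts.

The miner screens every conjunction of up to ``max_order`` binary exposures
against a single binary outcome, the way statistically-sound rule miners
screen "chemical(s) => adverse outcome" rules: a candidate is kept when it
is positively associated with the outcome (lift > 1) and its one-sided
Fisher's exact p-value falls below the significance level.

Two conventions matter and are fixed here:

* The *exposed* group of a rule is the subjects exposed to **all** of its
  antecedents; everyone else — including subjects exposed to a proper
  subset — forms the non-exposed comparator.
* Support means P(outcome AND all antecedents), which can only shrink as
  antecedents are added, so a minimum-support threshold prunes the search
  anti-monotonically (apriori-style) without ever discarding a rule the
  brute-force enumeration would keep.

Output ordering is fully deterministic (ascending p-value, then descending
lift, then antecedents lexicographically) so repeated runs are
byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import measures
from .convert import effects_from_indices
from .errors import LiftRRError
from .tables import ContingencyTable, EffectEstimates, IndexSet, indices_from_table

__all__ = ["TransactionMatrix", "Rule", "rule_table", "mine_rules"]


@dataclass(frozen=True)
class TransactionMatrix:
    """A cohort as binary transactions: subjects x exposures, plus outcome.

    Parameters
    ----------
    exposure_names
        Unique column identifiers, one per exposure.
    exposures
        ``(n_subjects, n_exposures)`` array of 0/1 indicators.
    outcome
        Length ``n_subjects`` array of 0/1 outcome indicators.
    """

    exposure_names: tuple[str, ...]
    exposures: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        exposures = np.asarray(self.exposures)
        outcome = np.asarray(self.outcome)
        if exposures.ndim != 2 or exposures.shape[0] == 0 or exposures.shape[1] == 0:
            raise LiftRRError("exposures must be a non-empty subjects x K matrix")
        if outcome.shape != (exposures.shape[0],):
            raise LiftRRError("outcome length must match the number of subjects")
        if len(self.exposure_names) != exposures.shape[1]:
            raise LiftRRError("one exposure name per exposure column required")
        if len(set(self.exposure_names)) != len(self.exposure_names):
            raise LiftRRError("exposure names must be unique")
        for arr, what in ((exposures, "exposure"), (outcome, "outcome")):
            if not np.isin(arr, (0, 1)).all():
                raise LiftRRError(f"{what} indicators must be 0/1")
        object.__setattr__(self, "exposures", exposures.astype(bool))
        object.__setattr__(self, "outcome", outcome.astype(bool))

    @property
    def n_subjects(self) -> int:
        return self.exposures.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.exposures.shape[1]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome_col: str = "outcome"
    ) -> "TransactionMatrix":
        """Build from a 0/1 data frame with a designated outcome column."""
        if outcome_col not in df.columns:
            raise LiftRRError(f"outcome column {outcome_col!r} not found")
        names = tuple(str(col) for col in df.columns if col != outcome_col)
        return cls(
            exposure_names=names,
            exposures=df[list(names)].to_numpy(),
            outcome=df[outcome_col].to_numpy(),
        )

    def to_dataframe(self, outcome_col: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(
            self.exposures.astype(np.int8), columns=list(self.exposure_names)
        )
        df[outcome_col] = self.outcome.astype(np.int8)
        return df


@dataclass(frozen=True)
class Rule:
    """One screened association rule: antecedent conjunction => outcome."""

    antecedents: tuple[str, ...]
    table: ContingencyTable
    indices: IndexSet
    effects: EffectEstimates
    p_value: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ante = " & ".join(self.antecedents)
        return (
            f"{ante} => outcome  (lift={self.effects.lift:.3g}, "
            f"RR={self.effects.rr:.3g}, p={self.p_value:.3g})"
        )


def _conjunction_mask(m: TransactionMatrix, idx: Sequence[int]) -> np.ndarray:
    return m.exposures[:, list(idx)].all(axis=1)


def rule_table(m: TransactionMatrix, antecedents: Iterable[str]) -> ContingencyTable:
    """Cross-tabulate "exposed to ALL antecedents" against the outcome.

    Subjects exposed to every antecedent form the exposed row; all others
    (no exposure, or exposure to only some antecedents) form the
    non-exposed row.

    Raises
    ------
    LiftRRError
        If the antecedent set is empty or names an unknown exposure.
    """
    names = sorted(set(antecedents))
    if not names:
        raise LiftRRError("antecedent set must be non-empty")
    lookup = {name: i for i, name in enumerate(m.exposure_names)}
    try:
        idx = [lookup[name] for name in names]
    except KeyError as exc:
        raise LiftRRError(f"unknown exposure name: {exc.args[0]!r}") from None
    exposed = _conjunction_mask(m, idx)
    a = int(np.count_nonzero(exposed & m.outcome))
    n_exposed = int(np.count_nonzero(exposed))
    n_outcome = int(np.count_nonzero(m.outcome))
    b = n_exposed - a
    c = n_outcome - a
    d = m.n_subjects - a - b - c
    return ContingencyTable(a, b, c, d)


def mine_rules(
    m: TransactionMatrix,
    max_order: int = 3,
    min_support: float = 0.001,
    alpha: float = 0.05,
    *,
    bonferroni: bool = False,
) -> list[Rule]:
    """Enumerate and screen all antecedent conjunctions up to ``max_order``.

    Breadth-first, apriori-style: level-k candidates are joins of frequent
    level-(k-1) sets, and a candidate is dropped as soon as its support
    P(outcome AND antecedents) falls below ``min_support`` — valid pruning
    because support is anti-monotone in the antecedent set.  Every surviving
    candidate with a non-degenerate table is tested; rules with lift > 1
    and a one-sided Fisher's exact p-value below the significance threshold
    are returned.

    Parameters
    ----------
    m
        The cohort.
    max_order
        Largest antecedent conjunction size to enumerate.
    min_support
        Minimum P(outcome AND antecedents) for a candidate to survive.
    alpha
        Per-rule significance level of the Fisher screen.
    bonferroni
        Divide ``alpha`` by the number of candidates actually tested.

    Returns
    -------
    list of Rule
        Sorted by ascending p-value, ties by descending lift, then by
        antecedent names.
    """
    if max_order < 1:
        raise LiftRRError(f"max_order={max_order} must be >= 1")
    if not (0 < alpha < 1):
        raise LiftRRError(f"alpha={alpha} must be in (0, 1)")
    if not (0 <= min_support <= 1):
        raise LiftRRError(f"min_support={min_support} must be in [0, 1]")

    n = m.n_subjects
    outcome = m.outcome
    n_outcome = int(np.count_nonzero(outcome))
    min_joint = min_support * n

    # breadth-first frequent-conjunction enumeration over column indices
    frequent: list[tuple[tuple[int, ...], np.ndarray]] = []
    level: list[tuple[tuple[int, ...], np.ndarray]] = []
    for j in range(m.n_exposures):
        mask = m.exposures[:, j]
        if np.count_nonzero(mask & outcome) >= min_joint:
            level.append(((j,), mask))
    frequent.extend(level)
    order = 1
    while level and order < max_order:
        prev_keys = {key for key, _ in level}
        nxt: list[tuple[tuple[int, ...], np.ndarray]] = []
        for (key_a, mask_a), (key_b, _) in combinations(level, 2):
            # prefix join keeps each candidate generated exactly once
            if key_a[:-1] != key_b[:-1]:
                continue
            cand = key_a + (key_b[-1],)
            if any(
                cand[:i] + cand[i + 1 :] not in prev_keys for i in range(len(cand))
            ):
                continue
            mask = mask_a & m.exposures[:, cand[-1]]
            if np.count_nonzero(mask & outcome) >= min_joint:
                nxt.append((cand, mask))
        frequent.extend(nxt)
        level = nxt
        order += 1

    # test every frequent candidate whose table supports effect estimation
    testable: list[tuple[tuple[int, ...], ContingencyTable]] = []
    for key, mask in frequent:
        a = int(np.count_nonzero(mask & outcome))
        n_exposed = int(np.count_nonzero(mask))
        t = ContingencyTable(
            a, n_exposed - a, n_outcome - a, n - n_exposed - n_outcome + a
        )
        if t.has_zero_margin or t.a == 0:
            continue
        testable.append((key, t))

    threshold = alpha / len(testable) if (bonferroni and testable) else alpha
    rules: list[Rule] = []
    for key, t in testable:
        lift = measures.lift(t)
        if not lift > 1:
            continue
        p = measures.fisher_exact_positive(t)
        if not p < threshold:
            continue
        names = tuple(sorted(m.exposure_names[j] for j in key))
        idx = indices_from_table(t)
        rules.append(
            Rule(
                antecedents=names,
                table=t,
                indices=idx,
                effects=effects_from_indices(idx),
                p_value=p,
            )
        )
    rules.sort(key=lambda r: (r.p_value, -r.effects.lift, r.antecedents))
    return rules
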