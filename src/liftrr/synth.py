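"""Synthetic cohorts for exercising the mine -> convert chain end to end.

The generator emulates the structure of an administrative birth cohort
crossed with binary environmental exposures: each subject carries
independent 0/1 exposure indicators with specified prevalences, and a
binary outcome whose risk is ``p0`` at baseline and ``rule_rr * p0`` for
subjects exposed to *all* members of one designated target conjunction.
That risk model makes the target rule's population indices available in
closed form (:func:`expected_indices`), so simulation output can be checked
against exact expectations rather than against another simulation.

Real exposure data of this kind are spatially correlated; by default the
generator draws exposures independently, with an optional shared
latent-factor (Gaussian copula) knob for correlated draws.  See the package
methods note for what this does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .errors import LiftRRError
from .miner import TransactionMatrix

__all__ = ["SimulationSpec", "ExpectedIndices", "simulate_cohort", "expected_indices"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_subjects
        Cohort size.
    exposure_prevalences
        Marginal prevalence of each exposure, each strictly inside (0, 1).
    target_rule
        Names of the exposures whose conjunction carries the risk effect.
    p0
        Baseline outcome risk P(outcome | not fully exposed to target).
    rule_rr
        Relative risk of the target conjunction; the fully exposed have
        outcome risk ``rule_rr * p0`` (must not exceed 1).
    seed
        Seed for all random draws; identical seeds give identical cohorts.
    exposure_names
        Optional names; defaults to E1..EK.
    latent_correlation
        Optional pairwise exposure correlation via one shared Gaussian
        latent factor; 0 (the default) draws exposures independently.
    """

    n_subjects: int
    exposure_prevalences: tuple[float, ...]
    target_rule: tuple[str, ...]
    p0: float
    rule_rr: float
    seed: int = 0
    exposure_names: tuple[str, ...] = ()
    latent_correlation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "exposure_prevalences", tuple(self.exposure_prevalences)
        )
        if self.n_subjects <= 0:
            raise LiftRRError("n_subjects must be positive")
        if not self.exposure_prevalences:
            raise LiftRRError("at least one exposure is required")
        for p in self.exposure_prevalences:
            if not (0 < p < 1):
                raise LiftRRError(f"exposure prevalence {p} must be in (0, 1)")
        names = self.exposure_names or tuple(
            f"E{i + 1}" for i in range(len(self.exposure_prevalences))
        )
        if len(names) != len(self.exposure_prevalences):
            raise LiftRRError("one name per exposure prevalence required")
        object.__setattr__(self, "exposure_names", tuple(names))
        target = tuple(sorted(set(self.target_rule)))
        if not target:
            raise LiftRRError("target_rule must name at least one exposure")
        unknown = set(target) - set(names)
        if unknown:
            raise LiftRRError(f"target_rule names unknown exposures: {sorted(unknown)}")
        object.__setattr__(self, "target_rule", target)
        if not (0 < self.p0 < 1):
            raise LiftRRError(f"baseline risk p0={self.p0} must be in (0, 1)")
        if self.rule_rr <= 0 or self.rule_rr * self.p0 > 1:
            raise LiftRRError(
                f"rule_rr={self.rule_rr} with p0={self.p0} gives an exposed "
                "risk outside (0, 1]"
            )
        if not (0 <= self.latent_correlation < 1):
            raise LiftRRError("latent_correlation must be in [0, 1)")


class ExpectedIndices(NamedTuple):
    """Population values of the target rule's indices under the risk model."""

    p_outcome: float
    support: float
    confidence: float
    lift: float


def expected_indices(
    p_rule_exposure: float, p0: float, rule_rr: float
) -> ExpectedIndices:
    """Closed-form population indices of the target rule.

    With exposure prevalence ``pE`` (probability of carrying the whole
    target conjunction), baseline risk ``p0`` and exposed risk
    ``p1 = rule_rr * p0``::

        P(O)       = pE * p1 + (1 - pE) * p0
        support    = pE * p1
        confidence = p1
        lift       = p1 / P(O)

    and feeding (lift, pE) back through the lift-to-RR conversion recovers
    ``rule_rr`` exactly — the simulation law and the conversion algebra are
    two views of the same identity.
    """
    if not (0 < p_rule_exposure < 1):
        raise LiftRRError(f"p_rule_exposure={p_rule_exposure} must be in (0, 1)")
    if not (0 < p0 < 1):
        raise LiftRRError(f"p0={p0} must be in (0, 1)")
    p1 = rule_rr * p0
    if p1 > 1:
        raise LiftRRError(f"exposed risk rule_rr*p0={p1} exceeds 1")
    p_outcome = p_rule_exposure * p1 + (1 - p_rule_exposure) * p0
    return ExpectedIndices(
        p_outcome=p_outcome,
        support=p_rule_exposure * p1,
        confidence=p1,
        lift=p1 / p_outcome,
    )


def simulate_cohort(spec: SimulationSpec) -> TransactionMatrix:
    """Draw one cohort under the spec's risk model.

    Exposures are thresholded standard-normal draws (a Gaussian copula),
    which reduces to independent Bernoulli draws when
    ``latent_correlation`` is 0; the outcome is Bernoulli with risk ``p0``
    or ``rule_rr * p0`` depending on full exposure to the target rule.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, len(spec.exposure_prevalences)
    rho = spec.latent_correlation
    z = rng.standard_normal((n, k))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
    thresholds = norm.ppf(np.asarray(spec.exposure_prevalences))
    exposures = (z < thresholds).astype(np.int8)

    name_to_col = {name: j for j, name in enumerate(spec.exposure_names)}
    target_cols = [name_to_col[name] for name in spec.target_rule]
    fully_exposed = exposures[:, target_cols].all(axis=1)
    risk = np.where(fully_exposed, spec.rule_rr * spec.p0, spec.p0)
    outcome = (rng.random(n) < risk).astype(np.int8)
    return TransactionMatrix(
        exposure_names=spec.exposure_names, exposures=exposures, outcome=outcome
    )
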