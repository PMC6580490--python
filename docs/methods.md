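# Methods

## The model

Everything in this package reduces to the algebra of one 2×2
exposure–outcome table:

|               | outcome | no outcome | total |
|---------------|---------|------------|-------|
| exposed       | a       | b          | a+b   |
| non-exposed   | c       | d          | c+d   |
| total         | a+c     | b+d        | N     |

with the data-mining indices support = a/N, confidence = a/(a+b), lift =
aN/((a+b)(a+c)), and the epidemiological measures RR = (a/(a+b))/(c/(c+d))
and OR = ad/bc. Substituting the margins P(E) = (a+b)/N and P(O) = (a+c)/N
gives the two conversion identities

    RR = (1 − P(E)) lift / (1 − P(E) lift)
    OR = (RR − P(O) lift) / (1 − P(O) lift)

whose denominators have direct cell interpretations: 1 − P(E)·lift =
c/(a+c) and 1 − P(O)·lift = 1 − confidence = b/(a+b). Hence both
denominators lie in [0, 1], vanish exactly when the corresponding cell (c
or b) is zero, and the converted estimate is +∞ exactly when the direct
cross-tabulated estimate is. These are identities, not approximations; the
test suite verifies them in exact rational arithmetic over every table with
cells 0–20 and positive margins (~190k tables).

Consequences used throughout:

* shared null: lift = 1 ⇔ RR = 1 ⇔ OR = 1, and all three fall on the same
  side of 1;
* |log OR| ≥ |log RR| ≥ |log lift| whenever all are finite;
* lift ≤ min(1/P(E), 1/P(O)), with equality iff c = 0 (resp. b = 0);
* RR/lift = (1 − P(E))/(1 − P(E)·lift) is ≥ 1 for positive associations
  and increases with both lift and P(E) — the reason lift-based ranking
  under-appreciates prevalent exposures.

## Numerical choices

**Exact vs floating arithmetic.** All measure and conversion functions do
generic arithmetic: `Fraction` in, `Fraction` out (`exact=True` on the
count-based estimators). Floats are the default for user data. The
boundary tolerance `tol = 1e-9` on the products P(E)·lift and P(O)·lift
separates "structural zero cell ⇒ infinite estimate" (product within tol
of 1) from "inputs inconsistent with any table ⇒ error" (product beyond
1 + tol); printed two-decimal indices can legitimately stray slightly past
the boundary, which is why the margin is not zero.

**Count reconstruction.** `table_from_indices` rounds support·N,
a/confidence and N·confidence/lift to the nearest integers (ties away from
zero) and then *verifies* by re-deriving the indices from the
reconstructed table, requiring agreement within `rtol` (default 1e-6).
Indices printed at two or three significant digits generally fail this
check and are rejected loudly; silent wrong counts are considered worse
than no counts. The CLI likewise warns when inputs carry ≤ 3 significant
digits, because converted estimates then drift (the worked example's
printed triple converts to RR 1.295 where the exact fractions give 1.303).

**Zero cells and degenerate tables.** Tables with a zero margin are
representable (they arise from degenerate cohorts and from conjunctions
covering everyone) but flagged, and effect estimation on them raises.
A rule with a = 0 has support 0; its index triple carries no information
and `indices_from_table` refuses it. RR and OR return +∞ for structural
zeros rather than raising, since screened rule sets routinely contain
them; an optional Haldane–Anscombe +0.5 correction is available on the
odds ratio. P(E) = 1 and P(O) = 1 are rejected by the conversion: the
non-exposed comparator (or the outcome contrast) does not exist.

**Fisher screen.** The rule screen uses the one-sided upper-tail exact
p-value P(X ≥ a) under the hypergeometric null with all margins fixed,
including the observed table's own probability — the standard convention,
and the side that matches screening for lift > 1. The implementation is
the scipy hypergeometric survival function; the test suite checks it
against exact integer enumeration on every table with N ≤ 40. No
multiple-testing correction is applied by default (the screen is
per-rule at α = 0.05); a Bonferroni flag divides α by the number of
candidates actually tested.

## The miner

A breadth-first apriori enumeration over antecedent conjunctions, screened
by lift > 1 and Fisher p < α. The exposed group of a rule is the subjects
exposed to *all* antecedents; everyone else — including the partially
exposed — is the comparator. Support here means P(outcome AND all
antecedents), which is anti-monotone in the antecedent set, so pruning at
`min_support` never removes a rule the brute-force screen would keep (the
suite verifies this against an unpruned oracle on small matrices).
Defaults: `max_order = 3` (conjunctions beyond three exposures explode
combinatorially and are rarely interpretable at desk scale),
`min_support = 0.001`, `alpha = 0.05`. Output ordering is total
(p-value, then −lift, then antecedent names), making runs byte-for-byte
reproducible. This is an enumerative screen for desk-scale cohorts, not a
branch-and-bound dependency-rule search; its retained set is defined by
the filter, not by search heuristics.

## The simulator

`simulate_cohort` draws K binary exposures per subject at specified
marginal prevalences and one binary outcome whose risk is `p0` at baseline
and `rule_rr * p0` for subjects exposed to the whole target conjunction.
A single designated rule carries the effect; overlapping multi-rule
effects would need an arbitration convention and are out of scope. Under
this law the target rule's population indices are closed-form
(`expected_indices`): p1 = rule_rr·p0, P(O) = pE·p1 + (1−pE)·p0, support =
pE·p1, confidence = p1, lift = p1/P(O), and feeding (lift, pE) back
through `rr_from_lift` returns `rule_rr` identically — the simulation law
and the conversion algebra are two views of the same identity, which is
what makes simulation-based recovery a meaningful check of the chain
rather than a tautology about one function.

The reference conditions used in the recovery tests mirror the bundled
worked example: P(E) = 0.22, rule RR = 1.30, and baseline risk p0 =
0.089/(0.22·1.30 + 0.78) so that P(O) ≈ 0.089; cohort size 200,000 keeps
the Monte-Carlo standard error of log RR near 0.02 while running in
seconds. The demo pipeline test uses 40,000 subjects and four exposures
with prevalences 0.08–0.65, spanning the range where the RR/lift ratio
visibly grows with prevalence.

Exposures are drawn independently by default (thresholded standard
normals, i.e. a Gaussian copula); real environmental exposures are
spatially correlated, and an optional `latent_correlation` knob adds one
shared latent factor for all exposures. One integer seed drives all draws
through a single `numpy` generator; identical seeds give identical
cohorts, tested byte-for-byte through the CLI. What the simulator does
*not* emulate: spatial exposure assignment, covariates (gestational or
otherwise), confounding, multiple overlapping causal rules, and
exposure-prevalence distributions of any particular registry. Passing
recovery tests therefore show that the estimation and conversion chain is
correct under the stated sampling law — not that mined associations in
real, confounded, spatially structured data are causal or correctly
screened.

## Design decisions that were genuinely open

* **Reconstruction contract**: reconstruct-and-verify with loud failure,
  rather than best-effort rounding, because the main consumer is
  third-party rule-table output of unknown precision.
* **Support definition in the miner**: joint P(outcome AND antecedents)
  rather than antecedent-only P(antecedents); it is the quantity the index
  triple calls support, and it is the anti-monotone one.
* **One-sided screen by default**: the retained set is defined as
  positive-dependence rules, so the upper tail is the matching test; the
  two-sided variant is a flag, not the default.
* **Infinities as values**: zero cells are data, not errors, in screened
  rule sets; formatting renders them as `Inf` and the reader reparses
  them.

## Known limitations

* Confidence intervals are out of scope throughout; all estimates are
  points.
* The miner is O(2^K) in the worst case and intended for tens of
  exposures, not thousands.
* `IndexSet` validation tolerates rounded inputs only up to a 1e-9
  boundary slack; extremely coarse triples (one significant digit) may
  validate yet convert with large drift — the significant-digit warning
  in the CLI is the guard.
* Stratified (2×2×K) tables and covariate adjustment are not modelled;
  the conversion is exact only for the crude (collapsed) table.
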