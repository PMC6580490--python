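# liftrr

Convert the data-mining index **lift** into the epidemiological effect
measures **relative risk (RR)** and **odds ratio (OR)** — exactly, from the
rule-mining output alone.

Association-rule miners applied to health cohorts (electronic records,
birth registries crossed with environmental exposures, claims data) report
each rule "exposure(s) ⇒ outcome" with the indices *support* = P(OE),
*confidence* = P(O|E) and *lift* = P(O|E)/P(O). Health researchers,
however, reason in relative risks and odds ratios, which compare the
exposed with the non-exposed and do not depend on how prevalent the
exposure is. For any 2×2 exposure–outcome table the measures are linked in
closed form:

    RR = (1 − P(E)) · lift / (1 − P(E) · lift)

    OR = (RR − P(O) · lift) / (1 − P(O) · lift)

where the mined triple itself supplies both prevalences, P(E) =
support/confidence and P(O) = confidence/lift. The identities are exact:
fed the lift and prevalences of any table they reproduce the directly
cross-tabulated RR and OR, down to the infinities caused by structural zero
cells. Lift is also structurally bounded, lift ≤ min(1/P(E), 1/P(O)), and
the ratio RR/lift = (1 − P(E))/(1 − P(E)·lift) grows with both the
association strength and the exposure prevalence — which is why ranking
rules by raw lift systematically under-ranks prevalent exposures, and why
converting to RR first gives a prevalence-robust ranking.

The package provides:

* **exact 2×2 table algebra** (`liftrr.tables`): validated cell counts,
  index triples, and lossless reconstruction of counts from
  (support, confidence, lift, N) with a reconstruct-and-verify contract;
* **association measures** (`liftrr.measures`): lift, RR, OR, prevalences,
  and the one-sided Fisher's exact test used to screen rules, with optional
  exact rational arithmetic throughout;
* **the conversion** (`liftrr.convert`): `rr_from_lift`, `or_from_lift`,
  whole-rule conversion, the lift ceiling, and RR-vs-lift curve data;
* **a desk-scale rule miner** (`liftrr.miner`): apriori-style enumeration of
  exposure conjunctions screened by lift > 1 and Fisher p < α;
* **a synthetic cohort simulator** (`liftrr.synth`) with closed-form
  expected indices, so the whole chain is testable end to end;
* **a CLI** (`liftrr convert | mine | simulate | curve`) over CSV files.

## Worked example

The bundled example is one mined rule from a 333,250-birth cohort: exposure
to a three-chemical airborne mixture versus small-for-gestational-age (SGA)
birth, with counts a=7828, b=64,021, c=21,851, d=239,550.

```python
>>> import liftrr as L
>>> t = L.worked_example()
>>> L.prevalences(t)
(0.21560090022505626, 0.08905926481620405)
>>> idx = L.indices_from_table(t)
>>> round(idx.support, 3), round(idx.confidence, 2), round(idx.lift, 2)
(0.023, 0.11, 1.22)
>>> eff = L.effects_from_indices(idx)
>>> round(eff.rr, 2), round(eff.or_, 2)
(1.3, 1.34)
```

Read: 22 % of the cohort is exposed (P(E) ≈ 0.22) and 8.9 % of all births
are SGA (P(O) ≈ 0.089). Among the exposed, 11 % are SGA (confidence), which
is 1.22× the population rate (lift). Converting that lift with the exposure
prevalence gives RR = 1.30 — the exposed risk is 30 % higher than the
*non-exposed* risk — and OR = 1.34. The same numbers come from the CLI:

```sh
$ liftrr convert tests/data/table2_rules.csv effects.csv --display-dp 2
$ cat effects.csv   # lift 1.22, rr 1.30, or 1.34, counts reconstructed
```

A full synthetic pipeline:

```sh
$ liftrr simulate cohort.csv --n-subjects 20000 --prevalences 0.3,0.2 \
      --target E1,E2 --baseline-risk 0.1 --rule-rr 2.0 --seed 5
$ liftrr mine cohort.csv rules.csv --max-order 2
$ liftrr convert rules.csv effects.csv --display-dp 2
```

mines three rules; the target conjunction `E1 & E2` tops the list with
lift 1.96 and converted RR 2.08 (truth: 2.0), and per rule the converted RR
equals the RR cross-tabulated directly from the raw cohort.

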