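# thresholdlogic

Exact, single-pass synthesis of **polynomial threshold neurons** — neuron
models that realize *any* switching function, linearly separable or not —
with an application to interpretable symptom→diagnosis rule learning.

## The problem

The classical linear neuron computes `y = [Σᵢ wᵢxᵢ > θ]` and can only
realize **linearly separable** Boolean functions. That class is vanishingly
small: of the `T(n) = 2^(2^n)` switching functions of `n` inputs, only
`L(n)` are linearly separable — 1,882 of 65,536 at `n = 4`, and by `n = 7`
the ratio `T/L` exceeds 4 × 10²⁸. XOR is the canonical casualty.

A complete **polynomial threshold template** removes the limitation. The
neuron's activation is an integer-weighted sum with one product term
available per non-empty subset of the inputs,

```
F_n({X}) = Σᵢ Wᵢ Xᵢ  +  Σᵢ<ⱼ Wᵢⱼ Xᵢ Xⱼ  +  …  +  W₁…ₙ X₁⋯Xₙ ,
f_n({x}) = 1  ⇔  F_n({X}) ≥ θ ,     θ = 1 (fixed),
```

and a term is "absent" when its weight is zero. Any switching function with
`f(0,…,0) = 0` is realizable by a single such neuron — there is no
constant term and the empty sum is 0, so the all-zero input always yields 0.

Neurons are built **directly** from training pairs, not tuned iteratively:

* **Affirmation** — to make an input set fire, add the smallest positive
  integer weight to the term keyed by exactly that set (`W_a = θ − F`).
* **Refutation** — to silence a superset that fires by inclusion, add the
  smallest-magnitude negative weight (`W_r = −F`).
* **Subsumption** — optionally drop affirmation terms whose variable set
  strictly contains a newly affirmed set (they became superfluous).
* **Verify & repair** — re-test all trained pairs and re-run
  Affirmation/Refutation on failures, which fixes any training-order
  mistakes in about one round.

A diagnosis network is then just one neuron per diagnosis over a shared
symptom registry; it reproduces exactly the cases it was trained on and —
in strict-recognition mode — answers "unknown" rather than inventing a
diagnosis for symptom sets it has never seen.

## Worked example

Six training pairs over eight symptoms, one diagnosis:

```python
from thresholdlogic import InputPattern, TrainingPair, TrainingOptions, train_sequence

pairs = [
    TrainingPair(InputPattern(8, frozenset(on)), out)
    for on, out in [
        ({1}, 1), ({2, 3}, 1), ({3, 4, 5}, 1),
        ({1, 2, 3}, 0), ({3, 4, 6, 7, 8}, 1), ({4, 8}, 1),
    ]
]
F, report = train_sequence(pairs, TrainingOptions(order="given", subsumption=True))
for step in report.steps:
    print(step.step_index, step.algorithm.value, "->", step.f_after)
```

prints the full training narrative — seven steps, one pass:

```
1 affirmation -> S1
2 affirmation -> S1 + S2S3
3 affirmation -> S1 + S2S3 + S3S4S5
4 refutation -> S1 + S2S3 + S3S4S5 - 2S1S2S3
5 affirmation -> S1 + S2S3 + S3S4S5 - 2S1S2S3 + S3S4S6S7S8
6 affirmation -> S1 + S2S3 + S3S4S5 - 2S1S2S3 + S3S4S6S7S8 + S4S8
7 subsumption -> S1 + S2S3 + S3S4S5 - 2S1S2S3 + S4S8
```

Step 4's `−2 S1S2S3` silences `{s1, s2, s3}` (which fired at 2 through the
included `S1` and `S2S3` terms); step 7 removes `S3S4S6S7S8`, made
superfluous once `{s4, s8}` was affirmed. The final five-term neuron
reproduces all six pairs exactly, and its full 256-row truth table equals
the switching expression
`(s1 + s2s3)(s1s2s3)' + s3s4s5 + s3s4s6s7s8 + s4s8`.

The same flows are available from the shell:

```bash
thresholdlogic demo diagnosis_training_sequence   # the table above
thresholdlogic table1 --n-max 4                   # L(n), T(n), T/L
thresholdlogic train pairs.jsonl -o model.json --subsumption --log steps.tsv
thresholdlogic predict network.json "s4,s8"
```

`table1` reproduces the versatility comparison by exhaustive enumeration
(an LP feasibility check per permutation class of unate truth tables):
`L(1..4) = 4, 14, 104, 1882` against `T(n) = 4, 16, 256, 65536`, ratios
`1, 1.143, 2.462, 34.82`; published `L(5..7)` are echoed for context and
flagged as such, never recomputed.

## Layout

* `thresholdlogic.model` — neuron/term/pattern/truth-table types, exact
  integer evaluation, rendering.
* `thresholdlogic.training` — Affirmation, Refutation, Subsumption, the
  sequence driver, verify/repair, one-pass exact truth-table synthesis.
* `thresholdlogic.diagnosis` — label registry, per-diagnosis neurons,
  tri-state prediction, contradiction scanning.
* `thresholdlogic.separability` — LP separability decision with exact
  rational witnesses, exhaustive `L(n)` counting, the versatility table.
* `thresholdlogic.fixtures` — seeded random functions/corpora and the
  hard-coded worked examples.
* `thresholdlogic.formats` / `thresholdlogic.cli` — byte-stable JSON/JSONL
  file formats and the `thresholdlogic` command.
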