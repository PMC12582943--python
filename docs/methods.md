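# Methods

## Model

A neuron over `n` binary inputs is a sparse integer polynomial
`F(X) = Σ_T W_T · Π_{i∈T} X_i` over non-empty subsets `T ⊆ {1..n}`,
thresholded at the fixed per-unit value `θ = 1`: the output is
`f(x) = [F(X) ≥ 1]`. Three modeling commitments follow the neuron model the
package implements and are not configurable:

* **θ = 1, always.** A zero threshold is unstable (the empty neuron would
  fire on everything), and treating the threshold as a learned parameter is
  exactly what the template avoids; raising a term's weight substitutes for
  lowering the threshold. Constructors reject any other value.
* **No constant term.** Hence `F(∅) = 0 < 1`: the all-zero input always
  outputs 0, and a training pair `(∅, 1)` is *unrealizable* — surfaced as
  an explicit `UnrealizablePairError`, never guessed around.
* **Exact integer arithmetic.** Weights are Python integers; evaluation is
  an exact subset-sum (a product fires iff its variable set is inside the
  input's on-set). No floating point anywhere in the model or training.

Truth-table enumeration is exponential and guarded at `n ≤ 16`
(65,536 rows), configurable per call.

## Training operators

Training starts from the empty neuron. For a desired-1 pair, **Affirmation**
adds `W_a = 1 − F(p)` to the term keyed by exactly the pattern's on-set —
the minimum positive integer reaching the threshold — and no-ops when the
pattern already fires. For a desired-0 pair, **Refutation** adds
`W_r = −F(p)`, the minimum-magnitude negative weight dropping the sum to 0,
and no-ops when the pattern is already silent. Both *sum into* an existing
term's weight rather than replacing it (the template is additive; one term
per subset is an invariant), and a resulting zero deletes the term.

**Subsumption**, invoked after a term-adding affirmation when enabled,
removes terms whose variable set strictly contains the new set. We restrict
it to positive-weight terms by default even though the procedure nominally
visits every term: deleting a negative (refutation) term would silently
re-fire an input that training explicitly silenced. The literal behavior is
available as `strict=True`. Subsumption is cosmetic for correctness on the
trained pairs at the moment it runs — the new smaller term alone reaches
threshold on any superset input — but it changes the function elsewhere,
which is why it is optional and logged.

**Ordering.** Affirming a set makes every superset fire (inclusion), so the
canonical schedule is all affirmations in ascending cardinality, then all
refutations likewise (`order="canonical"`). The default `order="given"`
replays sequences as supplied, which is what the worked examples expect and
what exposes ordering errors. The **verify-and-repair** pass re-tests all
pairs and re-applies Affirmation then Refutation to the failures (ascending
cardinality) each round. A fix at a pattern only disturbs strict supersets,
so the failure frontier rises in cardinality and the loop settles in ≤ n
rounds in every case we have enumerated (all 128 realizable `n = 3`
functions × 10 shuffled orders); because we have no general proof, rounds
are bounded at `2n + 2` and exhaustion is an explicit non-converged report,
never silent.

`synthesize_exact` schedules affirm/refute over an entire truth table in
ascending (cardinality, lexicographic) order. This provably recovers the
table in one pass: `F` at a pattern depends only on terms keyed by subsets
of its on-set, all finalized before the pattern is visited, and later
steps touch only non-subsets. It doubles as the oracle route against which
sequence training is property-tested.

Contradictory pairs (one pattern carrying both 0 and 1) are detected before
any training; don't-care pairs (`"dc"`) are skipped by training,
verification and repair alike. Tie-breaking everywhere is ascending
cardinality then lexicographic on index tuples, so logs and models are
bit-reproducible.

**Rendering.** Step logs and `render_function` list terms in the order
training introduced them — the narrative order worked-example tables use —
with unit weights implicit (`S1 + S2S3 - 2S1S2S3`). Serialized model files
instead sort terms by (cardinality, lexicographic) for byte-stable output;
function equality is term-set equality, independent of either order.

## Diagnosis networks

One neuron per diagnosis over a shared symptom registry (indices in
first-appearance order, persisted in the network file). For diagnosis `d`,
every case contributes a pair: desired 1 when the case lists `d`, else
desired 0 — negative evidence is what drives the refutations that keep one
diagnosis's affirmations from firing another case's symptoms; most such
pairs are no-ops. Per-neuron training uses the canonical order with repair,
so corpus order never matters. Prediction is tri-state: with
`strict_recognition` the network answers `unknown` for any symptom set not
seen verbatim in training — the conservative "I don't know" convention —
because threshold generalization (supersets of an affirmed set fire) may
or may not be wanted; we expose the choice as a flag, default off, rather
than deciding silently.

## Linear separability

`is_linearly_separable` decides strict separability (`w·x > t` on ones,
`w·x < t` on zeros) via a margin-1 LP feasibility problem
(`w·x ≥ t + 1` / `w·x ≤ t − 1`, free variables, HiGHS). Strict separation
of finite point sets is scale-invariant, so margin 1 loses no generality,
and the undefined tie case `w·x = t` can never arise. A feasible point is
rounded to rationals (smallest denominator that re-verifies, starting at
integers) and the witness is re-checked *exactly* against all `2^n` rows
with `fractions.Fraction` before being returned; the decision is also
cross-checked in the tests against brute-force integer-weight enumeration
on all 16 + 256 functions of 2–3 variables.

`count_linearly_separable(n ≤ 4)` enumerates all `2^(2^n)` truth tables.
Two sound reductions keep `L(4)` under a second of CPU: non-unate tables
are discarded without an LP (unateness — monotonicity up or down in each
variable — is a classical necessary condition for threshold realizability),
and the LP runs once per variable-permutation equivalence class, its
verdict weighted by class size (separability is permutation-invariant,
itself property-tested). `n = 5` would mean 2³² tables and is refused; the
published counts for `n = 5..7` are carried as constants and flagged
`published` in the versatility table, never recomputed. Ratio formatting
follows the table's precision conventions: 4 significant figures below
10⁴, nearest integer to 10⁷, scientific notation above.

## Synthetic data

`random_function(n ≤ 12, p_one, seed)` draws each non-empty pattern's
output as an independent Bernoulli(`p_one`) and forces the all-zero row to
0, so every generated function is realizable by the template — the
generator deliberately produces *arbitrary* switching functions, not
linearly separable ones, since realizing the full class is the point.
`random_diagnosis_corpus` draws symptom sets uniformly within a size range
and reuses the first-seen diagnosis set for repeated symptom sets, making
corpora contradiction-free by construction. Generators are pure functions
of their seeds. What they do *not* emulate: label noise or contradictory
records (training presumes consistent data and detects contradictions
rather than resolving them), correlated symptom co-occurrence, and
class-imbalanced diagnosis prevalence — so passing tests certify exact
recovery of consistent training data, not robustness to noisy clinical
records.

Problem sizes used by the test suite and acceptance script — exhaustive
`n = 3` function sweeps (128 functions × 10 shuffled orders), 500 random
`n = 6` functions, 50-case corpora over 20 symptoms, and the full `L(4)`
enumeration — were chosen as the smallest scales that exercise every code
path exhaustively where exhaustion is feasible.

## Known limitations

* Exact recovery is guaranteed only on trained pairs; behavior on untrained
  inputs is whatever the constructed polynomial implies (or `unknown` in
  strict mode). No probability calibration is attempted.
* The repair loop's convergence is verified exhaustively at small `n` and
  bounded defensively, not proven in general.
* Multi-layer network construction, inter-neuron linking and online
  learning during deployment are out of scope.
* `L(n)` counting beyond `n = 4` and fast threshold-function enumeration
  (e.g. via Chow parameters) are out of scope.
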