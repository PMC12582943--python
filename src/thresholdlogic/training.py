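"""Single-pass rule training for polynomial threshold neurons.

Three constructive operators build a neuron directly from (input-set,
desired-output) pairs — no gradients, no epochs:

* **Affirmation** — to make a pattern fire, add the smallest positive
  integer weight to the product term keyed by exactly that pattern's on-set
  so the weighted sum reaches the unit threshold.
* **Refutation** — to silence a pattern that erroneously fires (every
  superset of an affirmed set fires, by inclusion), add the smallest-
  magnitude negative weight to the pattern's own term so the sum drops
  below threshold.
* **Subsumption** — optional cleanup: after an affirmation adds a term,
  remove affirmation terms whose variable set strictly contains the new
  one; they are superfluous because the smaller term already fires them.

Training starts from the empty neuron (all weights zero, so every output is
0) and, because ordering mistakes are possible, finishes with a
verify-and-repair pass: re-test every trained pair and re-run Affirmation /
Refutation on the failures until none remain.

``synthesize_exact`` schedules the two operators over a whole truth table in
ascending-cardinality order, which provably recovers the table in one pass:
the weighted sum at a pattern depends only on terms keyed by subsets of its
on-set, and those are all finalized before the pattern is visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

from .model import (
    THETA,
    InputPattern,
    ThresholdFunction,
    TruthTable,
    canonical_key,
    evaluate_output,
    evaluate_threshold,
    render_function,
    term_sort_key,
)

__all__ = [
    "DONT_CARE",
    "Desired",
    "TrainingPair",
    "StepRecord",
    "VerifyFailure",
    "TrainingReport",
    "TrainingOptions",
    "UnrealizablePairError",
    "ContradictionError",
    "NonConvergenceError",
    "affirm",
    "refute",
    "subsume",
    "train_sequence",
    "verify",
    "repair",
    "synthesize_exact",
]

#: Sentinel for a don't-care output: the pair is skipped by training,
#: verification and repair alike.
DONT_CARE = "dc"

Desired = Literal[0, 1, "dc"]


class UnrealizablePairError(ValueError):
    """The all-zero input with desired output 1 cannot be realized: with no
    constant term the weighted sum at the empty on-set is 0 < theta."""


class ContradictionError(ValueError):
    """The same input pattern carries both desired 0 and desired 1."""

    def __init__(self, offenders: list["TrainingPair"]):
        self.offenders = offenders
        listed = "; ".join(f"{p.pattern} -> {p.desired}" for p in offenders)
        super().__init__(f"contradictory training pairs: {listed}")


class NonConvergenceError(RuntimeError):
    """Verify-and-repair did not empty the failure list within max_rounds."""


@dataclass(frozen=True)
class TrainingPair:
    """One training example: an input pattern and its desired output,
    0, 1 or don't-care (``"dc"``)."""

    pattern: InputPattern
    desired: Desired

    def __post_init__(self) -> None:
        if self.desired not in (0, 1, DONT_CARE):
            raise ValueError(f"desired must be 0, 1 or {DONT_CARE!r}")


class Algorithm(str, Enum):
    AFFIRMATION = "affirmation"
    REFUTATION = "refutation"
    SUBSUMPTION = "subsumption"


@dataclass(frozen=True)
class StepRecord:
    """One logged training step, rendered in canonical term order so a run's
    log reproduces the worked-example tables row for row."""

    step_index: int
    algorithm: Algorithm
    f_before: str
    applied: tuple[int, ...]
    f_after: str
    no_op: bool
    weight_delta: int | None = None
    removed: tuple[tuple[int, ...], ...] = ()


class FailureKind(str, Enum):
    NEEDS_AFFIRMATION = "needs_affirmation"
    NEEDS_REFUTATION = "needs_refutation"


@dataclass(frozen=True)
class VerifyFailure:
    pattern: InputPattern
    desired: int
    kind: FailureKind


@dataclass
class TrainingReport:
    steps: list[StepRecord] = field(default_factory=list)
    repair_rounds: int = 0
    converged: bool = True
    failures: list[VerifyFailure] = field(default_factory=list)

    def non_noop_steps(self) -> list[StepRecord]:
        return [s for s in self.steps if not s.no_op]

    def raise_if_not_converged(self) -> None:
        if not self.converged:
            raise NonConvergenceError(
                f"{len(self.failures)} training pair(s) still fail after "
                f"{self.repair_rounds} repair round(s)"
            )


@dataclass(frozen=True)
class TrainingOptions:
    """Driver configuration.

    order
        ``"given"`` applies the pairs in the order supplied (reproduces the
        worked-example tables); ``"canonical"`` applies all affirmations in
        ascending-cardinality order first, then all refutations likewise —
        the robust schedule, since an affirmed set must exist before a
        superset of it can need refutation.
    subsumption
        Invoke Subsumption after every term-adding affirmation.
    strict_subsumption
        Remove *all* strict-superset terms, including negative refutation
        terms. Off by default: deleting a refutation term would silently
        re-fire an input that training explicitly silenced.
    repair / max_rounds
        Run the verify-and-repair pass; ``max_rounds=None`` means 2n + 2.
    """

    order: Literal["given", "canonical"] = "given"
    subsumption: bool = False
    strict_subsumption: bool = False
    repair: bool = False
    max_rounds: int | None = None

    def rounds_for(self, n: int) -> int:
        return self.max_rounds if self.max_rounds is not None else 2 * n + 2


def _pattern_order(p: InputPattern) -> tuple[int, tuple[int, ...]]:
    return (len(p.on), p.sorted_on())


def affirm(
    F: ThresholdFunction, pattern: InputPattern, *, step_index: int = 0
) -> tuple[ThresholdFunction, StepRecord]:
    """Make ``pattern`` fire with the minimum positive integer weight.

    If the weighted sum already reaches threshold the call is a no-op
    (inclusion: a superset of an affirmed set already fires). Otherwise the
    deficit ``W_a = theta - F(pattern)`` is summed into the term keyed by
    the pattern's on-set; ``W_a`` is by construction the smallest positive
    integer that lifts the sum to the threshold.
    """
    if not pattern.on:
        raise UnrealizablePairError(
            "the all-zero input cannot be affirmed: F(empty) = 0 < theta and "
            "the expansion has no constant term"
        )
    before = render_function(F)
    value = evaluate_threshold(F, pattern)
    if value >= THETA:
        record = StepRecord(
            step_index, Algorithm.AFFIRMATION, before, pattern.sorted_on(), before, True
        )
        return F, record
    delta = THETA - value
    new_F = F.with_weight_added(pattern.on, delta)
    record = StepRecord(
        step_index,
        Algorithm.AFFIRMATION,
        before,
        pattern.sorted_on(),
        render_function(new_F),
        False,
        weight_delta=delta,
    )
    return new_F, record


def refute(
    F: ThresholdFunction, pattern: InputPattern, *, step_index: int = 0
) -> tuple[ThresholdFunction, StepRecord]:
    """Silence ``pattern`` with the smallest-magnitude negative weight.

    A no-op when the output is already 0. Otherwise ``W_r = -F(pattern)``
    is summed into the pattern's own term, dropping the sum to 0 < theta;
    any smaller-magnitude weight would leave the sum at or above threshold.
    """
    before = render_function(F)
    if evaluate_output(F, pattern) == 0:
        record = StepRecord(
            step_index, Algorithm.REFUTATION, before, pattern.sorted_on(), before, True
        )
        return F, record
    delta = -evaluate_threshold(F, pattern)
    new_F = F.with_weight_added(pattern.on, delta)
    record = StepRecord(
        step_index,
        Algorithm.REFUTATION,
        before,
        pattern.sorted_on(),
        render_function(new_F),
        False,
        weight_delta=delta,
    )
    return new_F, record


def subsume(
    F: ThresholdFunction,
    new_set: Iterable[int],
    *,
    strict: bool = False,
    step_index: int = 0,
) -> tuple[ThresholdFunction, StepRecord]:
    """Remove terms made superfluous by a newly affirmed set.

    Every term whose variable set strictly contains ``new_set`` is
    superfluous for firing (the new term alone reaches threshold on those
    inputs) and is removed. By default only positive-weight (affirmation)
    terms are dropped; ``strict=True`` removes negative terms too, which
    honors the literal "each term" reading but can silently re-fire a
    refuted input.
    """
    key = canonical_key(new_set)
    if key not in F.terms:
        raise ValueError(f"no term keyed by {key} in the function")
    before = render_function(F)
    target = set(key)
    removed = tuple(
        sorted(
            (
                k
                for k, w in F.terms.items()
                if set(k) > target and (strict or w > 0)
            ),
            key=term_sort_key,
        )
    )
    new_F = F.without_terms(removed) if removed else F
    record = StepRecord(
        step_index,
        Algorithm.SUBSUMPTION,
        before,
        key,
        render_function(new_F),
        not removed,
        removed=removed,
    )
    return new_F, record


def _find_contradictions(pairs: Sequence[TrainingPair]) -> list[TrainingPair]:
    seen: dict[frozenset[int], dict[int, TrainingPair]] = {}
    offenders: list[TrainingPair] = []
    for pair in pairs:
        if pair.desired == DONT_CARE:
            continue
        by_output = seen.setdefault(pair.pattern.on, {})
        other = by_output.get(1 - pair.desired)
        if other is not None and not offenders:
            offenders = [other, pair]
        by_output[pair.desired] = pair
    return offenders


def train_sequence(
    pairs: Sequence[TrainingPair],
    options: TrainingOptions = TrainingOptions(),
    *,
    n: int | None = None,
) -> tuple[ThresholdFunction, TrainingReport]:
    """Train a neuron from scratch on a sequence of pairs.

    Starts from the empty neuron; applies Affirmation to desired-1 pairs and
    Refutation to desired-0 pairs in the selected order, optionally invoking
    Subsumption after each term-adding affirmation, then optionally runs the
    verify-and-repair pass. Don't-care pairs are skipped. Effective
    subsumptions are logged as their own steps; subsumption no-ops are not.
    """
    offenders = _find_contradictions(pairs)
    if offenders:
        raise ContradictionError(offenders)
    live = [p for p in pairs if p.desired != DONT_CARE]
    if n is None:
        if not live and not pairs:
            raise ValueError("cannot infer n from an empty pair list")
        n = (live or list(pairs))[0].pattern.n
    for pair in pairs:
        if pair.pattern.n != n:
            raise ValueError("all training pairs must share the same n")
    for pair in live:
        if pair.desired == 1 and not pair.pattern.on:
            raise UnrealizablePairError(
                "training pair maps the all-zero input to 1, which no "
                "unit-threshold expansion without a constant term can realize"
            )

    if options.order == "canonical":
        schedule = sorted(
            (p for p in live if p.desired == 1), key=lambda p: _pattern_order(p.pattern)
        ) + sorted(
            (p for p in live if p.desired == 0), key=lambda p: _pattern_order(p.pattern)
        )
    else:
        schedule = list(live)

    F = ThresholdFunction.empty(n)
    report = TrainingReport()
    step = 1
    for pair in schedule:
        if pair.desired == 1:
            F, record = affirm(F, pair.pattern, step_index=step)
            report.steps.append(record)
            step += 1
            if options.subsumption and not record.no_op:
                F, sub_record = subsume(
                    F,
                    pair.pattern.on,
                    strict=options.strict_subsumption,
                    step_index=step,
                )
                if not sub_record.no_op:
                    report.steps.append(sub_record)
                    step += 1
        else:
            if not pair.pattern.on:
                # Desired 0 on the all-zero input holds vacuously.
                continue
            F, record = refute(F, pair.pattern, step_index=step)
            report.steps.append(record)
            step += 1

    if options.repair:
        F, repair_report = repair(
            F, live, max_rounds=options.rounds_for(n), _step_start=step
        )
        report.steps.extend(repair_report.steps)
        report.repair_rounds = repair_report.repair_rounds
        report.converged = repair_report.converged
        report.failures = repair_report.failures
    else:
        report.failures = verify(F, live)
        report.converged = not report.failures
    return F, report


def verify(
    F: ThresholdFunction, pairs: Sequence[TrainingPair]
) -> list[VerifyFailure]:
    """Re-test every non-don't-care pair; list those whose output disagrees
    with the desired bit, tagged with the operator that would fix them."""
    failures: list[VerifyFailure] = []
    for pair in pairs:
        if pair.desired == DONT_CARE:
            continue
        got = evaluate_output(F, pair.pattern)
        if got != pair.desired:
            kind = (
                FailureKind.NEEDS_AFFIRMATION
                if pair.desired == 1
                else FailureKind.NEEDS_REFUTATION
            )
            failures.append(VerifyFailure(pair.pattern, pair.desired, kind))
    return failures


def repair(
    F: ThresholdFunction,
    pairs: Sequence[TrainingPair],
    max_rounds: int | None = None,
    *,
    _step_start: int = 1,
) -> tuple[ThresholdFunction, TrainingReport]:
    """Verify-and-repair loop for ordering errors.

    Each round re-tests all pairs, then affirms the failures that need a 1
    (ascending cardinality) and refutes those that need a 0 (likewise).
    A fix at one pattern can only disturb strict supersets, whose on-sets
    are strictly larger, so the failure cardinality frontier rises every
    round and the loop converges within about n rounds; ``max_rounds``
    (default 2n + 2) bounds it defensively, and exhausting the bound raises
    nothing silently — the report comes back with ``converged=False`` and
    the remaining failures listed.
    """
    offenders = _find_contradictions(pairs)
    if offenders:
        raise ContradictionError(offenders)
    if max_rounds is None:
        max_rounds = 2 * F.n + 2
    report = TrainingReport()
    step = _step_start
    for _ in range(max_rounds):
        failures = verify(F, pairs)
        if not failures:
            report.converged = True
            report.failures = []
            return F, report
        report.repair_rounds += 1
        for failure in sorted(
            (f for f in failures if f.kind is FailureKind.NEEDS_AFFIRMATION),
            key=lambda f: _pattern_order(f.pattern),
        ):
            F, record = affirm(F, failure.pattern, step_index=step)
            report.steps.append(record)
            step += 1
        for failure in sorted(
            (f for f in failures if f.kind is FailureKind.NEEDS_REFUTATION),
            key=lambda f: _pattern_order(f.pattern),
        ):
            F, record = refute(F, failure.pattern, step_index=step)
            report.steps.append(record)
            step += 1
    report.failures = verify(F, pairs)
    report.converged = not report.failures
    return F, report


def synthesize_exact(table: TruthTable) -> ThresholdFunction:
    """Build the neuron realizing ``table`` exactly, in one deterministic
    pass: visit every pattern in ascending (cardinality, lexicographic)
    order and affirm the ones, refute the zeros.

    Correct because the weighted sum at a pattern involves only terms keyed
    by subsets of its on-set — all settled before the pattern is visited —
    and later steps touch only non-subsets.
    """
    empty = InputPattern(table.n)
    if table[empty] == 1:
        raise UnrealizablePairError(
            "the table maps the all-zero input to 1; no unit-threshold "
            "expansion without a constant term realizes it"
        )
    F = ThresholdFunction.empty(table.n)
    patterns = sorted(
        (InputPattern.from_index(table.n, i) for i in range(2**table.n)),
        key=_pattern_order,
    )
    for pattern in patterns:
        if not pattern.on:
            continue
        if table[pattern] == 1:
            F, _ = affirm(F, pattern)
        else:
            F, _ = refute(F, pattern)
    return F
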