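"""Seeded generators and hard-coded worked examples.

Two kinds of inputs feed the tests and demos:

* **Generators** — pure functions of their seed: random switching functions
  (with the all-zero input forced to 0, so every generated function is
  realizable by a unit-threshold expansion without a constant term), random
  contradiction-free diagnosis corpora, and a truth-table-to-training-pairs
  converter with ordering and don't-care policies.
* **Worked examples** — the XOR neuron, the eight-symptom single-diagnosis
  training sequence with its expected step-by-step renderings, the
  equivalent switching expression, and the three-variable ordering-error
  example (target function, flawed intermediate, repaired neuron). Each
  fixture that carries both an expected neuron and a target table
  self-checks at construction and fails fast on disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .diagnosis import DiagnosisCase
from .model import InputPattern, ThresholdFunction, TruthTable, functions_equal
from .training import DONT_CARE, TrainingPair

__all__ = [
    "FixtureSet",
    "random_function",
    "truth_table_to_pairs",
    "random_diagnosis_corpus",
    "worked_examples",
]


@dataclass(frozen=True)
class FixtureSet:
    """A named bundle of example inputs, with the expected neuron and/or
    expected step renderings where the worked example states them."""

    name: str
    truth_table: TruthTable | None = None
    pairs: tuple[TrainingPair, ...] | None = None
    cases: tuple[DiagnosisCase, ...] | None = None
    expected_function: ThresholdFunction | None = None
    expected_steps: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.expected_function is not None and self.truth_table is not None:
            ok, mismatch = functions_equal(self.expected_function, self.truth_table)
            if not ok:
                raise AssertionError(
                    f"fixture {self.name!r} is inconsistent: expected neuron "
                    f"disagrees with its target table at {mismatch}"
                )


def random_function(n: int, p_one: float, seed: int) -> TruthTable:
    """Random switching function: each non-empty pattern's output is an
    independent Bernoulli(p_one) draw; the all-zero input is forced to 0 so
    the function is realizable. Deterministic in ``seed``."""
    if not 1 <= n <= 12:
        raise ValueError(f"n must be in 1..12, got {n}")
    if not 0 < p_one < 1:
        raise ValueError(f"p_one must be strictly between 0 and 1, got {p_one}")
    rng = np.random.default_rng(seed)
    bits = (rng.random(2**n) < p_one).astype(int)
    bits[0] = 0
    return TruthTable(n, tuple(int(b) for b in bits))


def truth_table_to_pairs(
    table: TruthTable,
    order: Literal["ascending", "descending", "shuffled"] = "ascending",
    *,
    seed: int | None = None,
    dontcare_fraction: float = 0.0,
) -> list[TrainingPair]:
    """One training pair per truth-table row.

    ``order`` is ascending/descending (cardinality, then lexicographic) or a
    seeded shuffle; a seeded fraction of the pairs is demoted to don't-care.
    """
    if not 0.0 <= dontcare_fraction <= 1.0:
        raise ValueError("dontcare_fraction must be in [0, 1]")
    patterns = sorted(
        (InputPattern.from_index(table.n, i) for i in range(2**table.n)),
        key=lambda p: (len(p.on), p.sorted_on()),
    )
    if order == "descending":
        patterns.reverse()
    elif order == "shuffled":
        rng = np.random.default_rng(seed)
        patterns = [patterns[i] for i in rng.permutation(len(patterns))]
    elif order != "ascending":
        raise ValueError(f"unknown order {order!r}")
    pairs: list[TrainingPair] = []
    rng = np.random.default_rng(None if seed is None else seed + 1)
    for pattern in patterns:
        desired: int | str = table[pattern]
        if dontcare_fraction and rng.random() < dontcare_fraction:
            desired = DONT_CARE
        pairs.append(TrainingPair(pattern, desired))
    return pairs


def random_diagnosis_corpus(
    n_symptoms: int,
    n_diagnoses: int,
    n_cases: int,
    symptoms_per_case: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> list[DiagnosisCase]:
    """Random contradiction-free corpus.

    Symptom sets are drawn uniformly within the requested size range; a
    repeated symptom set always receives the diagnosis set of its first
    occurrence, so the corpus is contradiction-free by construction.
    Deterministic in ``seed``.
    """
    low, high = symptoms_per_case
    if not 1 <= low <= high <= n_symptoms:
        raise ValueError(
            f"symptoms_per_case range {symptoms_per_case} invalid for "
            f"{n_symptoms} symptoms"
        )
    rng = np.random.default_rng(seed)
    symptom_labels = [f"s{i}" for i in range(1, n_symptoms + 1)]
    diagnosis_labels = [f"d{i}" for i in range(1, n_diagnoses + 1)]
    seen: dict[frozenset[str], frozenset[str]] = {}
    cases: list[DiagnosisCase] = []
    for _ in range(n_cases):
        size = int(rng.integers(low, high + 1))
        symptoms = frozenset(
            symptom_labels[i] for i in rng.choice(n_symptoms, size, replace=False)
        )
        if symptoms in seen:
            diagnoses = seen[symptoms]
        else:
            count = int(rng.integers(1, max(2, n_diagnoses // 2 + 1)))
            diagnoses = frozenset(
                diagnosis_labels[i]
                for i in rng.choice(n_diagnoses, min(count, n_diagnoses), replace=False)
            )
            seen[symptoms] = diagnoses
        cases.append(DiagnosisCase(symptoms, diagnoses))
    return cases


def _pattern(n: int, *on: int) -> InputPattern:
    return InputPattern(n, frozenset(on))


def _pairs(n: int, spec: Sequence[tuple[tuple[int, ...], int]]) -> tuple[TrainingPair, ...]:
    return tuple(TrainingPair(_pattern(n, *on), desired) for on, desired in spec)


def _diagnosis_switching_table() -> TruthTable:
    """Exhaustive tabulation of the worked example's switching expression

        f({s}) = (s1 + s2 s3)(s1 s2 s3)' + s3 s4 s5 + s3 s4 s6 s7 s8 + s4 s8

    over all 256 patterns of the eight symptoms."""

    def expression(on: frozenset[int]) -> bool:
        s = {i: i in on for i in range(1, 9)}
        return bool(
            ((s[1] or (s[2] and s[3])) and not (s[1] and s[2] and s[3]))
            or (s[3] and s[4] and s[5])
            or (s[3] and s[4] and s[6] and s[7] and s[8])
            or (s[4] and s[8])
        )

    return TruthTable.from_callable(8, expression)


def _ordering_error_table() -> TruthTable:
    """Target of the ordering-error example over three symptoms:

        f({s}) = (s1 + s2 + s3)(s1 s2)'(s1 s3)'(s2 s3)' + s1 s2 s3

    i.e. fire on exactly one symptom or on all three."""

    def expression(on: frozenset[int]) -> bool:
        return len(on) == 1 or len(on) == 3

    return TruthTable.from_callable(3, expression)


def worked_examples() -> dict[str, FixtureSet]:
    """The hard-coded worked examples, keyed by name.

    ``xor`` — the two-input exclusive-or and its three-term neuron.
    ``diagnosis_training_sequence`` — six symptom-set pairs over eight
        symptoms plus the expected rendering after each of the seven
        effective steps (subsumption enabled) and the expected final neuron.
    ``diagnosis_switching_table`` — the equivalent switching expression,
        tabulated over all 256 patterns.
    ``ordering_error_target`` / ``ordering_error_intermediate`` /
    ``ordering_error_repaired`` — the three-variable example where refuting
        the pairs after affirming the singletons drives the all-ones input
        to -3, and one repair affirmation of weight +4 fixes it.
    """
    xor_table = TruthTable(2, (0, 1, 1, 0))
    xor_F = ThresholdFunction(2, {(1,): 1, (2,): 1, (1, 2): -2})

    sequence_pairs = _pairs(
        8,
        [
            ((1,), 1),
            ((2, 3), 1),
            ((3, 4, 5), 1),
            ((1, 2, 3), 0),
            ((3, 4, 6, 7, 8), 1),
            ((4, 8), 1),
        ],
    )
    sequence_steps = (
        "S1",
        "S1 + S2S3",
        "S1 + S2S3 + S3S4S5",
        "S1 + S2S3 + S3S4S5 - 2S1S2S3",
        "S1 + S2S3 + S3S4S5 - 2S1S2S3 + S3S4S6S7S8",
        "S1 + S2S3 + S3S4S5 - 2S1S2S3 + S3S4S6S7S8 + S4S8",
        "S1 + S2S3 + S3S4S5 - 2S1S2S3 + S4S8",
    )
    diagnosis_F = ThresholdFunction(
        8,
        {
            (1,): 1,
            (2, 3): 1,
            (3, 4, 5): 1,
            (1, 2, 3): -2,
            (4, 8): 1,
        },
    )
    diagnosis_table = _diagnosis_switching_table()

    ordering_target = _ordering_error_table()
    ordering_intermediate = ThresholdFunction(
        3,
        {
            (1,): 1,
            (2,): 1,
            (3,): 1,
            (1, 2): -2,
            (1, 3): -2,
            (2, 3): -2,
        },
    )
    ordering_repaired = ThresholdFunction(
        3,
        {
            (1,): 1,
            (2,): 1,
            (3,): 1,
            (1, 2): -2,
            (1, 3): -2,
            (2, 3): -2,
            (1, 2, 3): 4,
        },
    )

    fixtures = {
        "xor": FixtureSet(
            "xor",
            truth_table=xor_table,
            pairs=_pairs(2, [((1,), 1), ((2,), 1), ((1, 2), 0)]),
            expected_function=xor_F,
        ),
        "diagnosis_training_sequence": FixtureSet(
            "diagnosis_training_sequence",
            truth_table=diagnosis_table,
            pairs=sequence_pairs,
            expected_function=diagnosis_F,
            expected_steps=sequence_steps,
        ),
        "diagnosis_switching_table": FixtureSet(
            "diagnosis_switching_table", truth_table=diagnosis_table
        ),
        "ordering_error_target": FixtureSet(
            "ordering_error_target",
            truth_table=ordering_target,
            pairs=_pairs(
                3,
                [
                    ((1,), 1),
                    ((2,), 1),
                    ((3,), 1),
                    ((1, 2, 3), 1),
                    ((1, 2), 0),
                    ((1, 3), 0),
                    ((2, 3), 0),
                ],
            ),
        ),
        "ordering_error_intermediate": FixtureSet(
            "ordering_error_intermediate",
            expected_function=ordering_intermediate,
        ),
        "ordering_error_repaired": FixtureSet(
            "ordering_error_repaired",
            truth_table=ordering_target,
            expected_function=ordering_repaired,
        ),
    }
    return fixtures
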