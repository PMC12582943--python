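"""Symptom-to-diagnosis networks: one neuron per diagnosis.

Every binary network output is realizable by a single polynomial threshold
neuron, so a diagnosis network is simply a shared symptom registry plus one
independently trained neuron per diagnosis label. Training a diagnosis's
neuron uses every case: cases listing the diagnosis contribute desired-1
pairs, all other cases contribute desired-0 pairs (mostly no-ops, but they
drive the refutations that stop one diagnosis's affirmations from firing
another case's symptoms).

Prediction is tri-state. By default a diagnosis is ``positive`` when its
neuron fires and ``negative`` otherwise; with ``strict_recognition`` the
network answers ``unknown`` for any symptom set never seen in training —
the "I don't know" convention that trades generalization (supersets of an
affirmed set fire by inclusion) for the guarantee of never manufacturing an
answer the training data did not license.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import InputPattern, ThresholdFunction, evaluate_output
from .training import (
    TrainingOptions,
    TrainingPair,
    TrainingReport,
    train_sequence,
)

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "UNKNOWN",
    "LabelRegistry",
    "DiagnosisCase",
    "DiagnosisNetwork",
    "Contradiction",
    "CorpusContradictionError",
    "UnknownLabelError",
    "detect_contradictions",
    "build_network",
    "predict",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

#: Default options for per-diagnosis training: canonical order with the
#: verify-and-repair pass, so a corpus's case order never matters.
DEFAULT_TRAINING = TrainingOptions(order="canonical", repair=True)


class UnknownLabelError(KeyError):
    def __init__(self, labels: Sequence[str]):
        self.labels = list(labels)
        super().__init__(f"unknown symptom label(s): {', '.join(labels)}")


@dataclass(frozen=True)
class Contradiction:
    """Two cases with identical symptoms that disagree on one diagnosis."""

    symptoms: tuple[str, ...]
    diagnosis: str
    case_ids: tuple[int, int]


class CorpusContradictionError(ValueError):
    def __init__(self, contradictions: Sequence[Contradiction]):
        self.contradictions = list(contradictions)
        first = contradictions[0]
        super().__init__(
            f"contradictory corpus: cases {first.case_ids[0]} and "
            f"{first.case_ids[1]} share symptoms {set(first.symptoms)} but "
            f"disagree on diagnosis {first.diagnosis!r} "
            f"({len(contradictions)} contradiction(s) total)"
        )


@dataclass(frozen=True)
class DiagnosisCase:
    """One training case: a non-empty symptom set and the (possibly empty)
    set of diagnoses it carries."""

    symptoms: frozenset[str]
    diagnoses: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))
        if not self.symptoms:
            raise ValueError("a case must list at least one symptom")


@dataclass(frozen=True)
class LabelRegistry:
    """Bijective maps between textual labels and model indices: symptoms get
    contiguous 1-based variable indices (first-appearance order over the
    corpus), diagnoses get a stable output order."""

    symptoms: tuple[str, ...]
    diagnoses: tuple[str, ...]

    def __post_init__(self) -> None:
        for kind, labels in (("symptom", self.symptoms), ("diagnosis", self.diagnoses)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {kind} label")

    @classmethod
    def from_cases(cls, cases: Sequence[DiagnosisCase]) -> "LabelRegistry":
        symptoms: list[str] = []
        diagnoses: list[str] = []
        for case in cases:
            for s in sorted(case.symptoms):
                if s not in symptoms:
                    symptoms.append(s)
            for d in sorted(case.diagnoses):
                if d not in diagnoses:
                    diagnoses.append(d)
        return cls(tuple(symptoms), tuple(diagnoses))

    @property
    def n(self) -> int:
        return len(self.symptoms)

    def symptom_index(self, label: str) -> int:
        try:
            return self.symptoms.index(label) + 1
        except ValueError:
            raise UnknownLabelError([label]) from None

    def pattern(self, labels: Iterable[str]) -> InputPattern:
        labels = list(labels)
        unknown = sorted(l for l in labels if l not in self.symptoms)
        if unknown:
            raise UnknownLabelError(unknown)
        return InputPattern(self.n, frozenset(self.symptom_index(l) for l in labels))


@dataclass(frozen=True)
class DiagnosisNetwork:
    registry: LabelRegistry
    neurons: Mapping[str, ThresholdFunction]
    trained_patterns: frozenset[frozenset[int]] = frozenset()

    def __post_init__(self) -> None:
        for label, neuron in self.neurons.items():
            if label not in self.registry.diagnoses:
                raise ValueError(f"neuron for unregistered diagnosis {label!r}")
            if neuron.n != self.registry.n:
                raise ValueError(
                    f"neuron {label!r} has n={neuron.n}, registry has "
                    f"{self.registry.n} symptoms"
                )


def detect_contradictions(cases: Sequence[DiagnosisCase]) -> list[Contradiction]:
    """Exhaustively scan the corpus for identical symptom sets that disagree
    on any diagnosis. Empty result guarantees ``build_network`` will not
    raise a contradiction error."""
    first_seen: dict[frozenset[str], tuple[int, DiagnosisCase]] = {}
    found: list[Contradiction] = []
    for case_id, case in enumerate(cases):
        earlier = first_seen.get(case.symptoms)
        if earlier is None:
            first_seen[case.symptoms] = (case_id, case)
            continue
        earlier_id, earlier_case = earlier
        for diagnosis in sorted(case.diagnoses ^ earlier_case.diagnoses):
            found.append(
                Contradiction(
                    tuple(sorted(case.symptoms)), diagnosis, (earlier_id, case_id)
                )
            )
    return found


def build_network(
    cases: Sequence[DiagnosisCase],
    options: TrainingOptions = DEFAULT_TRAINING,
) -> tuple[DiagnosisNetwork, dict[str, TrainingReport]]:
    """Train one neuron per diagnosis over the whole corpus.

    For each diagnosis d, case c yields the pair (symptoms(c), 1) when
    d is among c's diagnoses and (symptoms(c), 0) otherwise.
    """
    contradictions = detect_contradictions(cases)
    if contradictions:
        raise CorpusContradictionError(contradictions)
    registry = LabelRegistry.from_cases(cases)
    neurons: dict[str, ThresholdFunction] = {}
    reports: dict[str, TrainingReport] = {}
    for diagnosis in registry.diagnoses:
        pairs = [
            TrainingPair(
                registry.pattern(case.symptoms),
                1 if diagnosis in case.diagnoses else 0,
            )
            for case in cases
        ]
        neurons[diagnosis], reports[diagnosis] = train_sequence(
            pairs, options, n=registry.n
        )
    trained = frozenset(registry.pattern(case.symptoms).on for case in cases)
    return DiagnosisNetwork(registry, neurons, trained), reports


def predict(
    network: DiagnosisNetwork,
    symptoms: Iterable[str],
    *,
    strict_recognition: bool = False,
) -> dict[str, str]:
    """Tri-state status per diagnosis for the given symptom labels.

    With ``strict_recognition`` a symptom set absent from training makes
    every status ``unknown``; otherwise each diagnosis is ``positive`` iff
    its neuron fires.
    """
    pattern = network.registry.pattern(symptoms)
    if strict_recognition and pattern.on not in network.trained_patterns:
        return {d: UNKNOWN for d in network.registry.diagnoses}
    return {
        d: POSITIVE if evaluate_output(network.neurons[d], pattern) else NEGATIVE
        for d in network.registry.diagnoses
    }
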