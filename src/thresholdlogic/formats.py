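"""Byte-stable readers and writers for the package's file formats.

Formats (all plain text, UTF-8, newline-terminated):

* **Model** — JSON object ``{"n", "theta", "terms": [{"vars", "weight"}…]}``
  with terms sorted by (cardinality, lexicographic); optional ``"labels"``
  recording the textual input labels and ``"config"`` recording the run
  configuration that produced the model.
* **Network** — JSON bundling the label registry, one model object per
  diagnosis, the trained symptom patterns and the config used.
* **Training pairs** — JSON lines, one object per line:
  ``{"inputs": ["s1", "s3"], "output": 0 | 1 | "dc"}``.
* **Corpus** — JSON lines: ``{"symptoms": [...], "diagnoses": [...]}``.
* **Truth table** — JSON ``{"n", "ones": [bit-string…]}`` where a
  bit-string's leftmost character is variable 1.

Input labels in pairs files may be arbitrary strings. When every label is a
letter prefix plus a number (``s7``, ``x3``) the number is used as the
variable index — so the worked examples' ``s1…s8`` land on S1…S8 —
otherwise indices follow first appearance. The chosen mapping is recorded
in the model file either way.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from .diagnosis import DiagnosisCase, DiagnosisNetwork, LabelRegistry
from .model import InputPattern, ThresholdFunction, TruthTable
from .training import DONT_CARE, StepRecord, TrainingOptions, TrainingPair

__all__ = [
    "RunConfig",
    "FormatError",
    "assign_indices",
    "model_to_dict",
    "model_from_dict",
    "write_model",
    "read_model",
    "write_network",
    "read_network",
    "write_pairs",
    "read_pairs",
    "write_corpus",
    "read_corpus",
    "write_truth_table",
    "read_truth_table",
    "write_step_log",
]

_NUMERIC_LABEL = re.compile(r"^[A-Za-z]+0*([1-9]\d*)$")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """The knobs of a training/prediction run, serialized into every file a
    run produces so results are reproducible from the artifact alone."""

    order: str = "given"
    subsumption: bool = False
    strict_subsumption: bool = False
    repair: bool = True
    max_rounds: int | None = None
    strict_recognition: bool = False
    seed: int = 0
    exhaustive_limit: int = 16

    def training_options(self) -> TrainingOptions:
        return TrainingOptions(
            order=self.order,  # type: ignore[arg-type]
            subsumption=self.subsumption,
            strict_subsumption=self.strict_subsumption,
            repair=self.repair,
            max_rounds=self.max_rounds,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


def _dump(payload: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def assign_indices(labels: Iterable[str]) -> list[str]:
    """Ordered label list defining the label -> 1-based index map.

    If every distinct label is a letter prefix plus a positive number and
    the numbers are distinct, labels are placed at their own numbers (gaps
    filled with synthetic ``s<k>`` placeholders never used by any pair);
    otherwise first-appearance order is kept.
    """
    ordered: list[str] = []
    for label in labels:
        if label not in ordered:
            ordered.append(label)
    matches = [_NUMERIC_LABEL.match(label) for label in ordered]
    if ordered and all(matches):
        numbers = [int(m.group(1)) for m in matches]  # type: ignore[union-attr]
        if len(set(numbers)) == len(numbers):
            n = max(numbers)
            slots: list[str | None] = [None] * n
            for label, number in zip(ordered, numbers):
                slots[number - 1] = label
            return [
                slot if slot is not None else f"_unused{i + 1}"
                for i, slot in enumerate(slots)
            ]
    return ordered


# ----------------------------------------------------------------- models


def model_to_dict(
    F: ThresholdFunction,
    labels: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> dict[str, Any]:
    payload: dict[str, Any] = {
        "n": F.n,
        "theta": 1,
        "terms": [
            {"vars": list(key), "weight": weight} for key, weight in F.sorted_terms()
        ],
    }
    if labels is not None:
        payload["labels"] = list(labels)
    if config is not None:
        payload["config"] = config.to_dict()
    return payload


def model_from_dict(data: dict[str, Any]) -> ThresholdFunction:
    if data.get("theta", 1) != 1:
        raise FormatError(f"theta must be 1, got {data.get('theta')!r}")
    terms = {
        tuple(entry["vars"]): int(entry["weight"]) for entry in data.get("terms", [])
    }
    return ThresholdFunction(int(data["n"]), terms)


def write_model(
    path: str | Path,
    F: ThresholdFunction,
    labels: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> None:
    _dump(model_to_dict(F, labels, config), path)


def read_model(path: str | Path) -> tuple[ThresholdFunction, list[str] | None]:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    return model_from_dict(data), data.get("labels")


# --------------------------------------------------------------- networks


def write_network(
    path: str | Path, network: DiagnosisNetwork, config: RunConfig | None = None
) -> None:
    index_to_label = dict(enumerate(network.registry.symptoms, start=1))
    payload: dict[str, Any] = {
        "symptoms": list(network.registry.symptoms),
        "diagnoses": list(network.registry.diagnoses),
        "neurons": {
            d: model_to_dict(network.neurons[d]) for d in network.registry.diagnoses
        },
        "trained_patterns": sorted(
            sorted(index_to_label[i] for i in pattern)
            for pattern in network.trained_patterns
        ),
    }
    if config is not None:
        payload["config"] = config.to_dict()
    _dump(payload, path)


def read_network(path: str | Path) -> tuple[DiagnosisNetwork, RunConfig]:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    registry = LabelRegistry(tuple(data["symptoms"]), tuple(data["diagnoses"]))
    neurons = {d: model_from_dict(m) for d, m in data["neurons"].items()}
    trained = frozenset(
        registry.pattern(labels).on for labels in data.get("trained_patterns", [])
    )
    config = RunConfig.from_dict(data.get("config", {}))
    return DiagnosisNetwork(registry, neurons, trained), config


# ------------------------------------------------------------ pairs files


def write_pairs(
    path: str | Path, pairs: Sequence[TrainingPair], labels: Sequence[str]
) -> None:
    lines = []
    for pair in pairs:
        inputs = [labels[i - 1] for i in pair.pattern.sorted_on()]
        lines.append(json.dumps({"inputs": inputs, "output": pair.desired}))
    Path(path).write_text("\n".join(lines) + "\n" if lines else "", encoding="utf-8")


def read_pairs(path: str | Path) -> tuple[list[TrainingPair], list[str]]:
    """Parse a JSON-lines pairs file; returns the pairs and the ordered
    label list defining the index map (see ``assign_indices``)."""
    raw: list[tuple[int, list[str], int | str]] = []
    for line_no, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {exc}", line_no) from exc
        if not isinstance(obj, dict) or "inputs" not in obj or "output" not in obj:
            raise FormatError('expected {"inputs": [...], "output": ...}', line_no)
        output = obj["output"]
        if output not in (0, 1, DONT_CARE):
            raise FormatError(f"output must be 0, 1 or \"{DONT_CARE}\"", line_no)
        raw.append((line_no, [str(s) for s in obj["inputs"]], output))
    labels = assign_indices(label for _, inputs, _ in raw for label in inputs)
    index = {label: i + 1 for i, label in enumerate(labels)}
    n = len(labels)
    pairs = [
        TrainingPair(InputPattern(n, frozenset(index[s] for s in inputs)), output)
        for _, inputs, output in raw
    ]
    return pairs, labels


# ----------------------------------------------------------- corpus files


def write_corpus(path: str | Path, cases: Sequence[DiagnosisCase]) -> None:
    lines = [
        json.dumps(
            {
                "symptoms": sorted(case.symptoms),
                "diagnoses": sorted(case.diagnoses),
            }
        )
        for case in cases
    ]
    Path(path).write_text("\n".join(lines) + "\n" if lines else "", encoding="utf-8")


def read_corpus(path: str | Path) -> list[DiagnosisCase]:
    cases: list[DiagnosisCase] = []
    for line_no, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {exc}", line_no) from exc
        if not isinstance(obj, dict) or "symptoms" not in obj:
            raise FormatError('expected {"symptoms": [...], "diagnoses": [...]}', line_no)
        try:
            cases.append(
                DiagnosisCase(
                    frozenset(str(s) for s in obj["symptoms"]),
                    frozenset(str(d) for d in obj.get("diagnoses", [])),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), line_no) from exc
    return cases


# ------------------------------------------------------------ truth tables


def write_truth_table(path: str | Path, table: TruthTable) -> None:
    ones = sorted(
        "".join("1" if i + 1 in p.on else "0" for i in range(table.n))
        for p in table.ones()
    )
    _dump({"n": table.n, "ones": ones}, path)


def read_truth_table(path: str | Path) -> TruthTable:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    n = int(data["n"])
    ones = []
    for bit_string in data.get("ones", []):
        if len(bit_string) != n or set(bit_string) - {"0", "1"}:
            raise FormatError(f"bad bit-string {bit_string!r} for n={n}")
        ones.append([i + 1 for i, c in enumerate(bit_string) if c == "1"])
    return TruthTable.from_ones(n, ones)


# --------------------------------------------------------------- step logs


def write_step_log(
    path: str | Path, steps: Sequence[StepRecord], fmt: str | None = None
) -> None:
    """Write a training step log: TSV mirroring the worked-example tables
    (columns step, algorithm, F_before, input, F_after) or machine-readable
    JSON. Format inferred from the extension unless given."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "tsv"
    if fmt == "json":
        payload = [
            {
                "step": s.step_index,
                "algorithm": s.algorithm.value,
                "f_before": s.f_before,
                "input": list(s.applied),
                "f_after": s.f_after,
                "no_op": s.no_op,
                "weight_delta": s.weight_delta,
                "removed": [list(k) for k in s.removed],
            }
            for s in steps
        ]
        _dump(payload, path)
        return
    rows = ["step\talgorithm\tF_before\tinput\tF_after"]
    for s in steps:
        pattern = "{" + ", ".join(f"s{i}" for i in s.applied) + "}"
        rows.append(
            f"{s.step_index}\t{s.algorithm.value}\t{s.f_before}\t{pattern}\t{s.f_after}"
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
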