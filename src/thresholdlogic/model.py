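"""Core data model: the complete polynomial threshold neuron.

A neuron over ``n`` binary inputs is an integer-weighted sum of product
terms, one term per non-empty subset of the input variables::

    F_n({X}) = sum_p  W_p * X_i ... X_m        (one product per subset)

compared against the fixed per-unit threshold theta = 1:

    f_n({x}) = 1  iff  F_n({X}) >= 1.

Because every non-empty subset may carry its own weight, the expansion can
realize *any* switching function whose output on the all-zero input is 0
(the sum over an empty on-set is 0 < 1, so f(0,...,0) = 0 always). Weights
are exact signed integers; a zero weight means the term is absent. The
threshold is not a parameter: a zero threshold would make the neuron
unstable, and unit threshold matches the per-unit normalization of
neurological measurements, so theta = 1 throughout.

Variable indices are 1-based everywhere in the public API (``X1`` is the
first input), matching threshold-logic convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "THETA",
    "EXHAUSTIVE_LIMIT",
    "DimensionMismatchError",
    "ExhaustiveLimitError",
    "VariableSet",
    "Term",
    "InputPattern",
    "ThresholdFunction",
    "TruthTable",
    "canonical_key",
    "term_sort_key",
    "template_term_count",
    "evaluate_threshold",
    "evaluate_output",
    "to_truth_table",
    "functions_equal",
    "render_function",
]

#: The fixed per-unit threshold. Not configurable by design.
THETA = 1

#: Default guard on exhaustive 2^n enumeration (65,536 rows at n = 16).
EXHAUSTIVE_LIMIT = 16


class DimensionMismatchError(ValueError):
    """Raised when a pattern / table / function disagree on the input count."""


class ExhaustiveLimitError(ValueError):
    """Raised when a 2^n enumeration would exceed the configured limit."""


def canonical_key(variables: Iterable[int]) -> tuple[int, ...]:
    """Canonical form of a variable set: strictly ascending tuple of 1-based
    indices. Rejects empty sets (the template has no constant term),
    duplicates and non-positive indices."""
    key = tuple(sorted(variables))
    if not key:
        raise ValueError("a term's variable set must be non-empty")
    if key[0] < 1:
        raise ValueError(f"variable indices are 1-based, got {key[0]}")
    if len(set(key)) != len(key):
        raise ValueError(f"duplicate variable index in {key}")
    return key


def term_sort_key(key: tuple[int, ...]) -> tuple[int, tuple[int, ...]]:
    """Canonical term order: ascending cardinality, then lexicographic."""
    return (len(key), key)


@dataclass(frozen=True)
class VariableSet:
    """An ascending, duplicate-free, non-empty set of 1-based variable
    indices — the subscript set of one product term."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", canonical_key(self.indices))

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class Term:
    """One weighted product ``weight * X_i ... X_m``; the weight is a nonzero
    signed integer (zero weight means the term does not appear)."""

    variables: VariableSet
    weight: int

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise ValueError("a present term must have a nonzero weight")


@dataclass(frozen=True)
class InputPattern:
    """A binary input vector given by its on-set: the 1-based indices of the
    variables equal to 1 (all others are 0). Synaptic transduction is
    value-preserving, so the same pattern serves for the pre-synaptic {x}/{s}
    and post-synaptic {X}/{S} views."""

    n: int
    on: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        on = frozenset(self.on)
        object.__setattr__(self, "on", on)
        bad = [i for i in on if not 1 <= i <= self.n]
        if bad:
            raise ValueError(f"indices {sorted(bad)} outside [1, {self.n}]")

    @classmethod
    def from_index(cls, n: int, index: int) -> "InputPattern":
        """Pattern from a row index whose bit ``i-1`` is variable ``i``."""
        return cls(n, frozenset(i + 1 for i in range(n) if index >> i & 1))

    @property
    def index(self) -> int:
        """Row index of this pattern (bit ``i-1`` set iff variable ``i`` on)."""
        return sum(1 << (i - 1) for i in self.on)

    def sorted_on(self) -> tuple[int, ...]:
        return tuple(sorted(self.on))

    def __str__(self) -> str:
        inner = ", ".join(f"x{i}" for i in self.sorted_on())
        return "{" + inner + "}"


@dataclass(frozen=True)
class ThresholdFunction:
    """A neuron: ``n`` inputs and a sparse map from variable subsets to
    nonzero integer weights, evaluated against the fixed threshold 1.

    ``terms`` maps canonical ascending index tuples to weights. The mapping
    is copied and validated on construction and must never be mutated; all
    training operators return new instances.
    """

    n: int
    terms: Mapping[tuple[int, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        clean: dict[tuple[int, ...], int] = {}
        for raw_key, weight in self.terms.items():
            key = canonical_key(raw_key)
            if key[-1] > self.n:
                raise ValueError(f"term {key} uses variables beyond n={self.n}")
            if weight == 0:
                raise ValueError(f"term {key} has zero weight; omit it instead")
            if key in clean:
                raise ValueError(f"duplicate term for variable set {key}")
            clean[key] = int(weight)
        # Insertion order is preserved: it is the narrative order in which
        # training introduced the terms, and renderings follow it. Equality
        # is order-insensitive (dict equality); serialization sorts.
        object.__setattr__(self, "terms", clean)

    @classmethod
    def empty(cls, n: int) -> "ThresholdFunction":
        return cls(n, {})

    def sorted_terms(self) -> list[tuple[tuple[int, ...], int]]:
        """Terms in canonical order (cardinality, then lexicographic) —
        the byte-stable order used by the file format."""
        return sorted(self.terms.items(), key=lambda kv: term_sort_key(kv[0]))

    def weight(self, variables: Iterable[int]) -> int:
        """Weight of the term on ``variables`` (0 if absent)."""
        return self.terms.get(canonical_key(variables), 0)

    def with_weight_added(self, variables: Iterable[int], delta: int) -> "ThresholdFunction":
        """New function with ``delta`` summed into the term on ``variables``;
        a resulting zero weight removes the term."""
        key = canonical_key(variables)
        terms = dict(self.terms)
        new_weight = terms.pop(key, 0) + delta
        if new_weight != 0:
            terms[key] = new_weight
        return ThresholdFunction(self.n, terms)

    def without_terms(self, keys: Iterable[tuple[int, ...]]) -> "ThresholdFunction":
        drop = {canonical_key(k) for k in keys}
        return ThresholdFunction(
            self.n, {k: w for k, w in self.terms.items() if k not in drop}
        )

    def __call__(self, pattern: InputPattern) -> int:
        return evaluate_output(self, pattern)

    def __str__(self) -> str:
        return render_function(self)


@dataclass(frozen=True)
class TruthTable:
    """All 2^n output bits of a switching function, indexed by pattern row
    index (bit ``i-1`` of the index is variable ``i``)."""

    n: int
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        outputs = tuple(int(b) for b in self.outputs)
        if len(outputs) != 2**self.n:
            raise ValueError(
                f"need exactly 2^{self.n} = {2**self.n} outputs, got {len(outputs)}"
            )
        if any(b not in (0, 1) for b in outputs):
            raise ValueError("outputs must be bits")
        object.__setattr__(self, "outputs", outputs)

    @classmethod
    def from_callable(cls, n: int, fn) -> "TruthTable":
        """Tabulate ``fn(on_set: frozenset[int]) -> bool-ish`` over all rows."""
        return cls(
            n,
            tuple(
                1 if fn(InputPattern.from_index(n, i).on) else 0 for i in range(2**n)
            ),
        )

    @classmethod
    def from_ones(cls, n: int, ones: Iterable[Iterable[int]]) -> "TruthTable":
        """Table that is 1 exactly on the given on-sets."""
        bits = [0] * 2**n
        for on in ones:
            bits[InputPattern(n, frozenset(on)).index] = 1
        return cls(n, tuple(bits))

    def __getitem__(self, pattern: InputPattern) -> int:
        if pattern.n != self.n:
            raise DimensionMismatchError(
                f"pattern has n={pattern.n}, table has n={self.n}"
            )
        return self.outputs[pattern.index]

    def ones(self) -> list[InputPattern]:
        """Patterns mapped to 1, in (cardinality, lexicographic) order."""
        pats = [
            InputPattern.from_index(self.n, i)
            for i, b in enumerate(self.outputs)
            if b
        ]
        return sorted(pats, key=lambda p: (len(p.on), p.sorted_on()))

    def count_ones(self) -> int:
        return sum(self.outputs)


def template_term_count(n: int, m: int) -> int:
    """Number of product terms with exactly ``m`` of the ``n`` variables in
    the complete expansion: the binomial coefficient C(n, m)."""
    if n < 1 or m < 1 or m > n:
        raise ValueError(f"need 1 <= m <= n, got n={n}, m={m}")
    return math.comb(n, m)


def _check_dims(F: ThresholdFunction, other_n: int) -> None:
    if F.n != other_n:
        raise DimensionMismatchError(f"function has n={F.n}, input has n={other_n}")


def evaluate_threshold(F: ThresholdFunction, pattern: InputPattern) -> int:
    """Exact integer value of the weighted sum at ``pattern``: the sum of the
    weights of every term whose variable set lies inside the on-set (a
    product X_i...X_m is 1 exactly when all of its variables are on)."""
    _check_dims(F, pattern.n)
    on = pattern.on
    return sum(w for key, w in F.terms.items() if on.issuperset(key))


def evaluate_output(F: ThresholdFunction, pattern: InputPattern) -> int:
    """The neuron's binary output: 1 iff the weighted sum reaches the unit
    threshold."""
    return 1 if evaluate_threshold(F, pattern) >= THETA else 0


def to_truth_table(
    F: ThresholdFunction, *, exhaustive_limit: int = EXHAUSTIVE_LIMIT
) -> TruthTable:
    """Tabulate the neuron's switching function over all 2^n inputs.

    Guarded by ``exhaustive_limit`` (default 16, i.e. 65,536 rows) since the
    enumeration is exponential in ``n``.
    """
    if F.n > exhaustive_limit:
        raise ExhaustiveLimitError(
            f"n={F.n} exceeds the exhaustive-enumeration limit {exhaustive_limit}"
        )
    size = 2**F.n
    values = np.zeros(size, dtype=np.int64)
    masks = np.arange(size, dtype=np.int64)
    for key, weight in F.terms.items():
        term_mask = sum(1 << (i - 1) for i in key)
        values[(masks & term_mask) == term_mask] += weight
    return TruthTable(F.n, tuple(int(b) for b in (values >= THETA).astype(int)))


def functions_equal(
    F: ThresholdFunction, table: TruthTable, *, exhaustive_limit: int = EXHAUSTIVE_LIMIT
) -> tuple[bool, InputPattern | None]:
    """Does the neuron realize exactly the given switching function?

    Returns ``(True, None)`` on agreement over all 2^n rows; otherwise
    ``(False, p)`` where ``p`` is the lexicographically smallest (by sorted
    on-set) disagreeing pattern.
    """
    _check_dims(F, table.n)
    realized = to_truth_table(F, exhaustive_limit=exhaustive_limit)
    if realized.outputs == table.outputs:
        return True, None
    mismatches = [
        InputPattern.from_index(F.n, i)
        for i, (a, b) in enumerate(zip(realized.outputs, table.outputs))
        if a != b
    ]
    first = min(mismatches, key=lambda p: p.sorted_on())
    return False, first


def render_function(F: ThresholdFunction, symbol: str = "S") -> str:
    """Human-readable rendering in threshold-logic table typography: terms
    in the order training introduced them, unit weights implicit, e.g.
    ``S1 + S2S3 + S3S4S5 - 2S1S2S3 + S4S8``. An empty neuron renders as
    ``0 (No terms)``."""
    items = list(F.terms.items())
    if not items:
        return "0 (No terms)"
    parts: list[str] = []
    for position, (key, weight) in enumerate(items):
        product = "".join(f"{symbol}{i}" for i in key)
        magnitude = "" if abs(weight) == 1 else str(abs(weight))
        if position == 0:
            sign = "" if weight > 0 else "-"
            parts.append(f"{sign}{magnitude}{product}")
        else:
            sign = "+" if weight > 0 else "-"
            parts.append(f" {sign} {magnitude}{product}")
    return "".join(parts)
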