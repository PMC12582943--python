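"""Linear separability: decision, counting, and the versatility table.

A switching function f on n inputs is *linearly separable* when some real
weights w and threshold t satisfy w.x > t on every one of f and w.x < t on
every zero — the class realized by the classical linear neuron. Strict
separation of two finite point sets is scale invariant, so feasibility is
decided by a margin-1 linear program (w.x >= t + 1 on ones, w.x <= t - 1 on
zeros) with a free threshold variable; ties w.x = t, which the strict
definition leaves unclassified, never arise in this encoding. A feasible
solution is rounded to exact rationals and re-verified against all 2^n rows
before being returned as a witness.

Counting all linearly separable functions L(n) by exhausting the 2^(2^n)
truth tables is desk-scale only through n = 4 (65,536 tables); the known
values continue 94,572; 15,028,134; 8,378,070,864 for n = 5..7, and this
module consumes those as printed constants rather than recomputing them.
The total number of switching functions is T(n) = 2^(2^n); the ratio
T(n)/L(n) quantifies how small the linearly separable class is — the
versatility a complete polynomial threshold neuron gains over a linear one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import InputPattern, TruthTable

__all__ = [
    "PRINTED_L",
    "SeparabilityWitness",
    "is_linearly_separable",
    "count_linearly_separable",
    "total_functions",
    "versatility_ratio",
    "format_ratio",
    "reproduce_table1",
]

#: Published counts of linearly separable functions for n beyond desk scale
#: (enumerating 2^32+ truth tables); consumed as constants, never computed.
PRINTED_L: dict[int, int] = {5: 94_572, 6: 15_028_134, 7: 8_378_070_864}

#: LP decision limit: 2^n constraint rows.
_LP_LIMIT = 6


@dataclass(frozen=True)
class SeparabilityWitness:
    """Exact rational weights and threshold strictly separating the ones
    from the zeros of a witnessed function."""

    weights: tuple[Fraction, ...]
    threshold: Fraction

    def separates(self, table: TruthTable) -> bool:
        """Exact re-verification of the strict inequalities on all rows."""
        if len(self.weights) != table.n:
            return False
        for index, bit in enumerate(table.outputs):
            value = sum(
                w for i, w in enumerate(self.weights) if index >> i & 1
            )
            if bit == 1 and not value > self.threshold:
                return False
            if bit == 0 and not value < self.threshold:
                return False
        return True


def _feasible_point(table: TruthTable) -> np.ndarray | None:
    """Solve the margin-1 feasibility LP; returns (w_1..w_n, t) or None."""
    n = table.n
    rows = []
    rhs = []
    for index, bit in enumerate(table.outputs):
        x = [float(index >> i & 1) for i in range(n)]
        if bit == 1:
            # -(w.x) + t <= -1
            rows.append([-v for v in x] + [1.0])
        else:
            # w.x - t <= -1
            rows.append(x + [-1.0])
        rhs.append(-1.0)
    result = linprog(
        c=np.zeros(n + 1),
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(None, None)] * (n + 1),
        method="highs",
    )
    return result.x if result.status == 0 else None


def is_linearly_separable(
    table: TruthTable,
) -> tuple[bool, SeparabilityWitness | None]:
    """Decide strict linear separability of a switching function.

    Returns ``(True, witness)`` with an exactly re-verified rational witness,
    or ``(False, None)``. Limited to n <= 6 (the LP has 2^n rows).
    """
    if table.n > _LP_LIMIT:
        raise ValueError(f"n={table.n} exceeds the LP decision limit {_LP_LIMIT}")
    point = _feasible_point(table)
    if point is None:
        return False, None
    # The margin-1 slack dwarfs float error, so a modest rational rounding
    # of the solver's point re-verifies exactly; fall back to finer
    # denominators defensively.
    for denominator_cap in (1, 16, 4096, 1 << 20, 1 << 40):
        witness = SeparabilityWitness(
            tuple(
                Fraction(v).limit_denominator(denominator_cap) for v in point[:-1]
            ),
            Fraction(point[-1]).limit_denominator(denominator_cap),
        )
        if witness.separates(table):
            return True, witness
    raise ArithmeticError(
        "LP reported feasibility but no rational rounding verified; "
        "this should be unreachable at the margin-1 encoding"
    )


def _unate_mask(n: int) -> np.ndarray:
    """Boolean mask over all 2^(2^n) packed truth tables (row index = bit
    position) marking the unate ones — in each variable the function is
    monotone non-decreasing or non-increasing, a classical necessary
    condition for threshold realizability."""
    size = 1 << n
    tables = np.arange(1 << size, dtype=np.uint32)
    unate = np.ones(tables.shape, dtype=bool)
    for i in range(n):
        stride = 1 << i
        low = np.uint32(
            sum(1 << index for index in range(size) if not index >> i & 1)
        )
        f0 = tables & low
        f1 = (tables >> np.uint32(stride)) & low
        increasing_violated = (f0 & ~f1 & low) != 0
        decreasing_violated = (~f0 & f1 & low) != 0
        unate &= ~(increasing_violated & decreasing_violated)
    return unate


def _permutation_canonical(tables: np.ndarray, n: int) -> np.ndarray:
    """Canonical representative of each packed table under variable
    permutation: the minimum over all n! relabelings."""
    size = 1 << n
    canon = tables.copy()
    for perm in itertools.permutations(range(n)):
        target = np.zeros(tables.shape, dtype=np.uint32)
        for index in range(size):
            src = 0
            for i in range(n):
                if index >> i & 1:
                    src |= 1 << perm[i]
            target |= ((tables >> np.uint32(src)) & np.uint32(1)) << np.uint32(index)
        np.minimum(canon, target, out=canon)
    return canon


def count_linearly_separable(n: int) -> int:
    """Exhaustively count the linearly separable functions of n variables.

    Enumerates all 2^(2^n) truth tables; desk-scale through n = 4 only, and
    refused beyond. Non-unate tables are rejected without an LP solve, and
    the LP runs once per variable-permutation class (separability is
    permutation invariant), its verdict weighted by the class size.
    """
    if not 1 <= n <= 4:
        raise ValueError(
            f"exhaustive counting covers n in 1..4; n={n} means 2^(2^{n}) "
            "tables, beyond desk scale — use the published constant instead"
        )
    size = 1 << n
    tables = np.arange(1 << size, dtype=np.uint32)
    survivors = tables[_unate_mask(n)]
    canon = _permutation_canonical(survivors, n)
    representatives, members = np.unique(canon, return_counts=True)
    count = 0
    for bits, weight in zip(representatives, members):
        bits = int(bits)
        table = TruthTable(n, tuple(bits >> i & 1 for i in range(size)))
        separable, _ = is_linearly_separable(table)
        if separable:
            count += int(weight)
    return count


def total_functions(n: int) -> int:
    """T(n) = 2^(2^n), the number of switching functions of n variables,
    as an exact integer (guarded at n <= 16)."""
    if not 1 <= n <= 16:
        raise ValueError(f"n must be in 1..16, got {n}")
    return 2 ** (2**n)


def versatility_ratio(n: int, L: int | None = None) -> Fraction:
    """Exact ratio T(n)/L(n). For n <= 4, L is enumerated when not supplied;
    for n >= 5 a published L must be passed in (see ``PRINTED_L``)."""
    if L is None:
        if n > 4:
            raise ValueError(
                f"L({n}) is not desk-computable; supply the published count"
            )
        L = count_linearly_separable(n)
    return Fraction(total_functions(n), L)


def format_ratio(ratio: Fraction) -> str:
    """Render a ratio the way versatility tables print it: 4 significant
    figures below 10^4, nearest integer (comma-grouped) up to 10^7, and
    4-significant-figure scientific notation above."""
    value = ratio.numerator / ratio.denominator
    if ratio == 1:
        return "1"
    if value < 1e4:
        return f"{float(f'{value:.4g}'):g}"
    if value < 1e7:
        return f"{round(value):,}"
    exponent = math.floor(math.log10(value))
    mantissa = value / 10**exponent
    return f"{mantissa:.3f} x 10^{exponent}"


def reproduce_table1(
    n_max: int = 4,
    printed_L: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Versatility table: one row per n with L(n), T(n) and T(n)/L(n).

    Rows with n <= 4 are computed by exhaustive enumeration; larger n are
    included only when ``printed_L`` supplies the published count and are
    flagged ``published`` in the source column. ``printed_L`` defaults to
    the module's ``PRINTED_L`` constants for n_max > 4.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if printed_L is None:
        printed_L = PRINTED_L
    rows = []
    for n in range(1, n_max + 1):
        if n <= 4:
            L = count_linearly_separable(n)
            source = "computed"
        elif n in printed_L:
            L = printed_L[n]
            source = "published"
        else:
            raise ValueError(f"no published L({n}) supplied for n > 4")
        ratio = versatility_ratio(n, L)
        rows.append(
            {
                "n": n,
                "L": L,
                "T": total_functions(n),
                "ratio": format_ratio(ratio),
                "ratio_exact": ratio,
                "source": source,
            }
        )
    return pd.DataFrame(rows)
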