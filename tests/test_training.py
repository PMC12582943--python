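"""Affirmation / Refutation / Subsumption, the driver, and verify-repair."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thresholdlogic.model import (
    InputPattern,
    ThresholdFunction,
    TruthTable,
    evaluate_output,
    evaluate_threshold,
    functions_equal,
    render_function,
    to_truth_table,
)
from thresholdlogic.training import (
    ContradictionError,
    TrainingOptions,
    TrainingPair,
    UnrealizablePairError,
    affirm,
    refute,
    repair,
    subsume,
    synthesize_exact,
    train_sequence,
    verify,
)
from thresholdlogic.fixtures import random_function, truth_table_to_pairs

from conftest import random_threshold_function


def pattern(n, *on):
    return InputPattern(n, frozenset(on))


def pairs_of(n, spec):
    return [TrainingPair(pattern(n, *on), desired) for on, desired in spec]


class TestAffirmation:
    def test_first_affirmation_creates_unit_term(self):
        F, record = affirm(ThresholdFunction.empty(8), pattern(8, 1))
        assert F.terms == {(1,): 1}
        assert record.weight_delta == 1 and not record.no_op
        assert record.f_before == "0 (No terms)" and record.f_after == "S1"

    def test_disjoint_set_gets_its_own_term(self):
        start = ThresholdFunction(8, {(1,): 1})
        F, _ = affirm(start, pattern(8, 2, 3))
        assert render_function(F) == "S1 + S2S3"

    def test_superset_of_affirmed_set_is_a_no_op(self):
        start = ThresholdFunction(8, {(1,): 1})
        F, record = affirm(start, pattern(8, 1, 4))
        assert record.no_op and F == start

    def test_weight_covers_negative_deficit(self, examples):
        F = examples["ordering_error_intermediate"].expected_function
        fixed, record = affirm(F, pattern(3, 1, 2, 3))
        assert record.weight_delta == 4
        assert fixed.weight((1, 2, 3)) == 4

    def test_all_zero_input_is_unrealizable(self):
        with pytest.raises(UnrealizablePairError):
            affirm(ThresholdFunction.empty(3), InputPattern(3))

    def test_assigned_weight_is_minimal_and_idempotent(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            F = random_threshold_function(rng, n)
            index = int(rng.integers(1, 2**n))
            p = InputPattern.from_index(n, index)
            after, record = affirm(F, p)
            assert evaluate_output(after, p) == 1
            if not record.no_op:
                # One unit less would miss the threshold: minimality.
                lesser = F.with_weight_added(p.on, record.weight_delta - 1)
                assert evaluate_output(lesser, p) == 0
                again, second = affirm(after, p)
                assert second.no_op and again == after
                assert render_function(again) == render_function(after)


class TestRefutation:
    def test_refutes_included_affirmations(self):
        start = ThresholdFunction(8, {(1,): 1, (2, 3): 1, (3, 4, 5): 1})
        F, record = refute(start, pattern(8, 1, 2, 3))
        assert record.weight_delta == -2
        assert render_function(F) == "S1 + S2S3 + S3S4S5 - 2S1S2S3"

    def test_xor_refutation(self):
        start = ThresholdFunction(2, {(1,): 1, (2,): 1})
        F, _ = refute(start, pattern(2, 1, 2))
        assert F.terms[(1, 2)] == -2

    def test_silent_pattern_is_a_no_op(self):
        start = ThresholdFunction(3, {(1,): 1})
        F, record = refute(start, pattern(3, 2))
        assert record.no_op and F == start

    def test_empty_pattern_is_always_a_no_op(self):
        F, record = refute(ThresholdFunction(2, {(1,): 1}), InputPattern(2))
        assert record.no_op

    def test_weight_is_smallest_magnitude_negative(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            F = random_threshold_function(rng, n)
            index = int(rng.integers(1, 2**n))
            p = InputPattern.from_index(n, index)
            after, record = refute(F, p)
            assert evaluate_output(after, p) == 0
            if not record.no_op:
                weaker = F.with_weight_added(p.on, record.weight_delta + 1)
                assert evaluate_output(weaker, p) == 1


class TestSubsumption:
    def test_removes_strict_positive_supersets(self, examples):
        fixture = examples["diagnosis_training_sequence"]
        before_subsume = ThresholdFunction(
            8,
            {
                (1,): 1,
                (2, 3): 1,
                (3, 4, 5): 1,
                (1, 2, 3): -2,
                (3, 4, 6, 7, 8): 1,
                (4, 8): 1,
            },
        )
        F, record = subsume(before_subsume, (4, 8))
        assert record.removed == ((3, 4, 6, 7, 8),)
        assert F == fixture.expected_function

    def test_no_superset_terms_means_no_op(self):
        start = ThresholdFunction(4, {(1,): 1, (2, 3): 1})
        F, record = subsume(start, (1,))
        assert record.no_op and F == start

    def test_missing_target_term_is_an_error(self):
        with pytest.raises(ValueError):
            subsume(ThresholdFunction(3, {(1,): 1}), (2,))

    def test_planted_supersets_are_exactly_the_removed_ones(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = 6
            F = random_threshold_function(rng, n)
            F = F.with_weight_added((1, 2), 1 - F.weight((1, 2)))
            planted = [(1, 2, 3), (1, 2, 5), (1, 2, 4, 6)]
            for key in planted:
                if F.weight(key) <= 0:
                    F = F.with_weight_added(key, 2 - F.weight(key))
            after, record = subsume(F, (1, 2))
            expected = sorted(
                k
                for k, w in F.terms.items()
                if set(k) > {1, 2} and w > 0
            )
            assert sorted(record.removed) == expected
            # Brute-force superset scan: nothing else changed.
            for key, weight in F.terms.items():
                if key in record.removed:
                    assert after.weight(key) == 0
                else:
                    assert after.weight(key) == weight

    def test_default_mode_spares_negative_terms_strict_removes_them(self):
        F = ThresholdFunction(4, {(1,): 1, (1, 2): -2, (1, 3): 2})
        spared, _ = subsume(F, (1,))
        assert spared.terms == {(1,): 1, (1, 2): -2}
        stripped, _ = subsume(F, (1,), strict=True)
        assert stripped.terms == {(1,): 1}

    def test_subsumption_preserves_output_at_the_new_set(self):
        F = ThresholdFunction(4, {(1, 2): 1, (1, 2, 3): 3})
        after, _ = subsume(F, (1, 2))
        assert evaluate_output(after, pattern(4, 1, 2)) == evaluate_output(
            F, pattern(4, 1, 2)
        )


class TestTrainSequence:
    def test_worked_example_reproduces_the_step_table(self, examples):
        fixture = examples["diagnosis_training_sequence"]
        F, report = train_sequence(
            list(fixture.pairs), TrainingOptions(order="given", subsumption=True)
        )
        assert [s.f_after for s in report.steps] == list(fixture.expected_steps)
        assert len(report.steps) == 7
        assert F == fixture.expected_function

    def test_single_pair_yields_single_term(self):
        F, _ = train_sequence(pairs_of(1, [((1,), 1)]))
        assert F.terms == {(1,): 1}

    def test_contradictory_pairs_are_rejected_before_training(self):
        with pytest.raises(ContradictionError) as err:
            train_sequence(pairs_of(2, [((1,), 1), ((2,), 0), ((1,), 0)]))
        offending = {p.pattern.sorted_on() for p in err.value.offenders}
        assert offending == {(1,)}

    def test_all_zero_desired_one_is_unrealizable(self):
        with pytest.raises(UnrealizablePairError):
            train_sequence(pairs_of(2, [((), 1)]))

    def test_dont_care_pairs_are_skipped(self):
        F, report = train_sequence(
            pairs_of(3, [((1,), 1), ((2,), "dc"), ((1, 3), "dc")])
        )
        assert F.terms == {(1,): 1}
        assert len(report.steps) == 1

    def test_canonical_order_matches_exact_synthesis(self):
        for seed in range(20):
            table = random_function(4, 0.4, seed)
            pairs = truth_table_to_pairs(table, order="shuffled", seed=seed)
            trained, report = train_sequence(
                pairs, TrainingOptions(order="canonical", repair=True)
            )
            assert report.converged
            reference = synthesize_exact(table)
            assert to_truth_table(trained).outputs == to_truth_table(reference).outputs


class TestVerifyRepair:
    def test_ordering_error_is_detected_then_repaired_in_one_round(self, examples):
        fixture = examples["ordering_error_target"]
        flawed, _ = train_sequence(
            list(fixture.pairs), TrainingOptions(order="given", repair=False)
        )
        assert flawed == examples["ordering_error_intermediate"].expected_function
        failures = verify(flawed, list(fixture.pairs))
        assert len(failures) == 1
        failure = failures[0]
        assert failure.pattern.sorted_on() == (1, 2, 3)
        assert failure.kind.value == "needs_affirmation"

        fixed, report = repair(flawed, list(fixture.pairs))
        assert fixed == examples["ordering_error_repaired"].expected_function
        assert report.repair_rounds == 1 and report.converged
        assert verify(fixed, list(fixture.pairs)) == []

    def test_correct_model_needs_no_repair(self, examples):
        fixture = examples["diagnosis_training_sequence"]
        F = fixture.expected_function
        fixed, report = repair(F, list(fixture.pairs))
        assert fixed == F and report.repair_rounds == 0 and not report.steps

    def test_empty_function_satisfies_all_zero_pairs(self):
        F = ThresholdFunction.empty(3)
        assert verify(F, pairs_of(3, [((1,), 0), ((1, 2), 0)])) == []

    def test_exhausted_rounds_reported_not_silent(self, examples):
        fixture = examples["ordering_error_target"]
        flawed, _ = train_sequence(
            list(fixture.pairs), TrainingOptions(order="given", repair=False)
        )
        _, report = repair(flawed, list(fixture.pairs), max_rounds=0)
        assert not report.converged and report.failures

    def test_every_three_variable_function_trains_exactly_in_any_order(self):
        """All 128 realizable n=3 switching functions, 10 shuffled orders
        each, recover their truth table after repair."""
        rng = np.random.default_rng(31)
        for bits in range(128):
            table = TruthTable(3, (0,) + tuple(bits >> i & 1 for i in range(7)))
            for _ in range(10):
                pairs = truth_table_to_pairs(
                    table, order="shuffled", seed=int(rng.integers(2**31))
                )
                trained, report = train_sequence(
                    pairs, TrainingOptions(order="given", repair=True)
                )
                assert report.converged
                equal, mismatch = functions_equal(trained, table)
                assert equal, f"table {bits:08b} mismatched at {mismatch}"


class TestSynthesizeExact:
    def test_xor(self, examples):
        F = synthesize_exact(examples["xor"].truth_table)
        assert F == examples["xor"].expected_function

    def test_all_zero_table_yields_empty_function(self):
        F = synthesize_exact(TruthTable(3, (0,) * 8))
        assert F.terms == {}

    def test_all_one_on_empty_input_is_unrealizable(self):
        with pytest.raises(UnrealizablePairError):
            synthesize_exact(TruthTable(2, (1, 0, 0, 0)))

    def test_every_realizable_three_variable_table_is_recovered(self):
        for bits in range(128):
            table = TruthTable(3, (0,) + tuple(bits >> i & 1 for i in range(7)))
            F = synthesize_exact(table)
            equal, _ = functions_equal(F, table)
            assert equal

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=6),
        data=st.data(),
    )
    def test_recovery_is_exact_for_arbitrary_tables(self, n, data):
        bits = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=1),
                min_size=2**n - 1,
                max_size=2**n - 1,
            )
        )
        table = TruthTable(n, (0, *bits))
        F = synthesize_exact(table)
        equal, _ = functions_equal(F, table)
        assert equal
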