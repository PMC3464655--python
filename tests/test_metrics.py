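import numpy as np
import pytest

from rnascfg.metrics import (
    aggregate,
    combined_best,
    compare_structures,
    default_gamma_grid,
    gamma_sweep,
    mountain_distance,
    relative_metrics,
)
from rnascfg.structure import Structure, StructuredSequence, parse_dotbracket


def _s(text):
    return parse_dotbracket(text)


def _pairs(length, pairs):
    return Structure(length=length, pairs=frozenset(pairs))


class TestCompareStructures:
    def test_counts_and_ratios(self):
        trusted = _pairs(10, {(0, 9), (1, 8), (2, 7)})
        predicted = _pairs(10, {(0, 9), (1, 8), (3, 6)})
        rep = compare_structures(predicted, trusted)
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 1)
        assert rep.sensitivity == pytest.approx(2 / 3)
        assert rep.ppv == pytest.approx(2 / 3)
        assert rep.fscore == pytest.approx(2 / 3)

    def test_identical_structures_score_one(self):
        s = _s("((..))")
        rep = compare_structures(s, s)
        assert rep.sensitivity == rep.ppv == rep.fscore == 1.0

    def test_zero_denominator_conventions(self):
        rep = compare_structures(_s("...."), _s("(..)"))
        assert rep.sensitivity == 0.0 and rep.ppv == 0.0 and rep.fscore == 0.0
        rep2 = compare_structures(_s("...."), _s("...."))
        assert rep2.sensitivity == 0.0 and rep2.ppv == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_structures(_s("..."), _s(".."))


class TestMountainMetric:
    def test_identical_structures_distance_zero(self):
        assert mountain_distance(_s("((..))"), _s("((..))")) == 0.0

    def test_hand_computed_example(self):
        # heights (1,2,1,0) vs (1,0,1,0)
        assert mountain_distance(_s("(())"), _s("()()")) == 2.0

    def test_metric_axioms_on_random_triples(self, rng):
        from _oracle import random_structure_text
        for _ in range(30):
            a, b, c = (
                _s(random_structure_text(rng, 12)) for _ in range(3)
            )
            assert mountain_distance(a, b) == mountain_distance(b, a)
            assert (
                mountain_distance(a, c)
                <= mountain_distance(a, b) + mountain_distance(b, c) + 1e-12
            )


class TestAggregation:
    def _rec(self, rid, struct):
        return StructuredSequence(rid, "A" * len(struct), _s(struct))

    def test_single_record_equals_compare(self):
        rec = self._rec("a", "(..)")
        rep = aggregate([rec], [_s("(..)")])
        assert rep == compare_structures(_s("(..)"), rec.structure)

    def test_micro_average_sums_counts(self):
        recs = [self._rec("a", "(..)"), self._rec("b", "(...)")]
        preds = [_s("(..)"), _s(".(.).")]
        rep = aggregate(recs, preds)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 1)
        assert rep.sensitivity == pytest.approx(1 / 2)
        assert rep.ppv == pytest.approx(1 / 2)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], [])

    def test_macro_averaging(self):
        recs = [self._rec("a", "(..)"), self._rec("b", "(...)")]
        preds = [_s("(..)"), _s(".....")]
        rep = aggregate(recs, preds, macro=True)
        assert rep.sensitivity == pytest.approx(0.5)


class TestRelativeMetrics:
    def test_self_comparison_is_perfect(self):
        preds = [("a", _s("(..)")), ("b", _s("((..))"))]
        assert relative_metrics(preds, preds) == (1.0, 1.0)

    def test_all_dots_against_pairs(self):
        a = [("x", _s("...."))]
        b = [("x", _s("(..)"))]
        assert relative_metrics(a, b) == (0.0, 0.0)

    def test_role_swap_swaps_sensitivity_and_ppv(self):
        a = [("x", _s("(......)")), ("y", _s("(..)"))]
        b = [("x", _s("(.(..).)")), ("y", _s("...."))]
        sens_ab, ppv_ab = relative_metrics(a, b)
        sens_ba, ppv_ba = relative_metrics(b, a)
        assert sens_ab == ppv_ba and ppv_ab == sens_ba

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            relative_metrics([("x", _s("."))], [("y", _s("."))])


class TestGammaSweep:
    def test_default_grid_has_100_points(self):
        grid = default_gamma_grid()
        assert len(grid) == 100
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(5.0)
        assert np.allclose(np.diff(grid), 0.05)

    def test_single_gamma_matches_direct_prediction(self, toy_grammars, synthetic_records):
        from rnascfg.decode import predict_mea

        g, p = toy_grammars[3]
        records = synthetic_records[:8]
        ((gamma, sens, ppv),) = gamma_sweep(g, p, records, gamma_grid=[2.0])
        preds = [predict_mea(g, p, r.sequence, 2.0) for r in records]
        rep = aggregate(records, preds)
        assert (sens, ppv) == (rep.sensitivity, rep.ppv)

    def test_nonpositive_gamma_rejected(self, toy_grammars):
        g, p = toy_grammars[3]
        with pytest.raises(ValueError):
            gamma_sweep(g, p, [], gamma_grid=[0.0])


class TestCombinedBest:
    def _rec(self, rid, struct):
        return StructuredSequence(rid, "A" * len(struct), _s(struct))

    def test_single_set_equals_aggregate(self):
        recs = [self._rec("a", "(..)")]
        preds = [_s("(..)")]
        assert combined_best(recs, [preds]) == aggregate(recs, preds)

    def test_two_complementary_sets_combine_perfectly(self):
        recs = [self._rec("a", "(..)"), self._rec("b", "((..))")]
        set1 = [_s("(..)"), _s("......")]
        set2 = [_s("...."), _s("((..))")]
        rep = combined_best(recs, [set1, set2])
        assert rep.sensitivity == rep.ppv == 1.0

    def test_per_record_choice_dominates_each_set(self):
        recs = [self._rec("a", "(..)"), self._rec("b", "((..))")]
        set1 = [_s("(..)"), _s("(....)")]
        set2 = [_s("...."), _s("((..))")]
        combined = combined_best(recs, [set1, set2])
        for preds in (set1, set2):
            rep = aggregate(recs, preds)
            assert combined.fscore >= rep.fscore
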