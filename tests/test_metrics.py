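"""Strict/relaxed matching, F1 arithmetic, pairing optimality, confusion matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slrminer.corpus import EntityMention
from slrminer.metrics import (
    MatchCounts,
    confusion,
    evaluate,
    evaluate_relations,
    f1,
    match_entities,
    match_relations,
)


def M(typ, start, end, mid="T"):
    return EntityMention(f"{mid}{start}_{end}", typ, start, end, "x" * (end - start))


class TestF1:
    @pytest.mark.parametrize("p,r,expected", [
        (0.7, 0.7, 0.7),
        (1.0, 0.0, 0.0),
        (0.5, 1.0, 2 / 3),
        (0.0, 0.0, 0.0),
    ])
    def test_harmonic_mean(self, p, r, expected):
        assert f1(p, r) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            f1(1.2, 0.5)
        with pytest.raises(ValueError):
            f1(0.5, -0.1)


class TestMatchCounts:
    def test_invariant(self):
        with pytest.raises(ValueError):
            MatchCounts(3, 2, 5)

    def test_rates(self):
        c = MatchCounts(1, 2, 3)
        assert c.precision == 0.5
        assert c.recall == pytest.approx(1 / 3)
        assert c.f1 == pytest.approx(0.4)


class TestEntityMatching:
    def test_reviewer_boundary_disagreement_on_dosage(self):
        """A dosage predicted as just the amount overlaps the full annotated phrase:
        a relaxed match but not a strict one."""
        text = "We treated patients with drug X at 1.3 mg/m^2"
        gold = [EntityMention("G1", "arm_dosage", 0, len(text), text)]
        pred = [EntityMention("P1", "arm_dosage", 35, len(text), "1.3 mg/m^2")]
        relaxed, _ = match_entities(pred, gold, "relaxed")
        strict, _ = match_entities(pred, gold, "strict")
        assert relaxed.correct == 1
        assert strict.correct == 0

    def test_identical_sets_match_fully(self):
        ms = [M("a", 0, 5), M("b", 10, 15), M("a", 20, 30)]
        for mode in ("strict", "relaxed"):
            counts, _ = match_entities(ms, list(ms), mode)
            assert (counts.correct, counts.predicted, counts.actual) == (3, 3, 3)

    def test_same_span_different_type_never_matches(self):
        pred = [M("a", 0, 5)]
        gold = [M("b", 0, 5)]
        for mode in ("strict", "relaxed"):
            counts, _ = match_entities(pred, gold, mode)
            assert counts.correct == 0

    def test_one_to_one(self):
        # two predictions overlap one gold: only one may pair
        pred = [M("a", 0, 4), M("a", 3, 8)]
        gold = [M("a", 2, 6)]
        counts, pairs = match_entities(pred, gold, "relaxed")
        assert counts.correct == 1 and len(pairs) == 1

    def test_exact_priority_preserves_strict_matches(self):
        # a long overlapping prediction must not steal the exactly-matching gold
        pred = [M("a", 0, 10), M("a", 2, 6)]
        gold = [M("a", 2, 6), M("a", 11, 15)]
        counts, pairs = match_entities(pred, gold, "relaxed")
        paired_gold = {g for _, g in pairs}
        assert (1, 0) in pairs  # prediction 1 took its exact twin


class TestEvaluate:
    def test_hand_counted_report(self):
        gold = [M("a", 0, 5), M("a", 10, 15), M("a", 20, 25)]
        pred = [M("a", 0, 5), M("a", 30, 35)]
        rep = evaluate([(pred, gold)])
        assert rep.strict.precision == 0.5
        assert rep.strict.recall == pytest.approx(1 / 3)
        assert rep.strict.f1 == pytest.approx(0.4)

    def test_no_predictions_flagged(self):
        gold = [M("a", 0, 5)]
        rep = evaluate([([], gold)])
        d = rep.strict.as_dict()
        assert d["precision"] == 0 and d["recall"] == 0 and d["f1"] == 0
        assert d["precision_defined"] is False

    def test_perfect_predictions(self):
        gold = [M("a", 0, 5), M("b", 6, 9)]
        rep = evaluate([(list(gold), gold)])
        assert rep.strict.f1 == 1.0 and rep.relaxed.f1 == 1.0
        assert all(c.f1 == 1.0 for c in rep.per_type_relaxed.values())

    def test_matching_never_crosses_documents(self):
        d1 = ([M("a", 0, 5)], [])
        d2 = ([], [M("a", 0, 5)])
        rep = evaluate([d1, d2])
        assert rep.relaxed.correct == 0

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6),
                              st.sampled_from("ab")), max_size=8),
           st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6),
                              st.sampled_from("ab")), max_size=8))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_relaxed_never_below_strict(self, pred_raw, gold_raw):
        pred = [M(t, s, s + l, f"P{i}_") for i, (s, l, t) in enumerate(pred_raw)]
        gold = [M(t, s, s + l, f"G{i}_") for i, (s, l, t) in enumerate(gold_raw)]
        rep = evaluate([(pred, gold)])
        assert rep.relaxed.f1 >= rep.strict.f1 - 1e-12

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(1, 6),
                              st.sampled_from("ab")), max_size=8),
           st.permutations(range(8)))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_permutation_invariance(self, pred_raw, perm):
        pred = [M(t, s, s + l, f"P{i}_") for i, (s, l, t) in enumerate(pred_raw)]
        gold = [M("a", 3, 9), M("b", 12, 14), M("a", 20, 24)]
        base = match_entities(pred, gold, "relaxed")[0]
        shuffled = [pred[i] for i in perm if i < len(pred)]
        again = match_entities(shuffled, gold, "relaxed")[0]
        assert base.correct == again.correct


def _max_bipartite_count(pred, gold, mode):
    """Independent oracle: maximum bipartite matching via networkx."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(f"p{i}" for i in range(len(pred)))
    g.add_nodes_from(f"g{i}" for i in range(len(gold)))
    for i, p in enumerate(pred):
        for j, q in enumerate(gold):
            if p.entity_type != q.entity_type:
                continue
            if mode == "strict" and (p.start, p.end) == (q.start, q.end):
                g.add_edge(f"p{i}", f"g{j}")
            if mode == "relaxed" and min(p.end, q.end) > max(p.start, q.start):
                g.add_edge(f"p{i}", f"g{j}")
    return len(nx.algorithms.matching.max_weight_matching(g, maxcardinality=True))


def test_greedy_pairing_is_maximum_on_small_instances():
    rng = np.random.default_rng(12)
    for _ in range(300):
        def mk(prefix):
            out = []
            for i in range(int(rng.integers(0, 9))):
                s = int(rng.integers(0, 25))
                out.append(M(str(rng.choice(["a", "b"])), s, s + int(rng.integers(1, 6)),
                             f"{prefix}{i}_"))
            return out
        pred, gold = mk("P"), mk("G")
        for mode in ("strict", "relaxed"):
            counts, _ = match_entities(pred, gold, mode)
            assert counts.correct == _max_bipartite_count(pred, gold, mode)


class TestRelations:
    def _rel(self, label, a, b):
        return (label, a, b)

    def test_identical_sets(self):
        rels = [self._rel("refers_to", M("a", 0, 5), M("b", 10, 15))]
        counts, _ = match_relations(rels, list(rels))
        assert (counts.correct, counts.predicted, counts.actual) == (1, 1, 1)

    def test_relaxed_vs_strict_arguments(self):
        gold = [self._rel("refers_to", M("a", 0, 10), M("b", 20, 30))]
        pred = [self._rel("refers_to", M("a", 0, 10), M("b", 25, 30))]
        relaxed, _ = match_relations(pred, gold, "relaxed")
        strict, _ = match_relations(pred, gold, "strict")
        assert relaxed.correct == 1
        assert strict.correct == 0

    def test_equivalent_matches_with_swapped_arguments(self):
        a, b = M("a", 0, 5), M("a", 10, 15)
        counts, _ = match_relations([("equivalent", b, a)], [("equivalent", a, b)])
        assert counts.correct == 1

    def test_refers_to_does_not_match_swapped(self):
        a, b = M("a", 0, 5), M("b", 10, 15)
        counts, _ = match_relations([("refers_to", b, a)], [("refers_to", a, b)])
        assert counts.correct == 0

    def test_label_must_agree(self):
        a, b = M("a", 0, 5), M("b", 10, 15)
        counts, _ = match_relations([("equivalent", a, b)], [("refers_to", a, b)])
        assert counts.correct == 0

    def test_per_pair_breakdown(self):
        a, b, c = M("a", 0, 5), M("b", 10, 15), M("a", 20, 25)
        gold = [("refers_to", a, b), ("equivalent", a, c)]
        pred = [("refers_to", a, b)]
        rep = evaluate_relations([(pred, gold)])
        assert rep.per_pair[("refers_to", "a", "b")].f1 == 1.0
        assert rep.per_pair[("equivalent", "a", "a")].recall == 0.0


class TestConfusion:
    def test_all_correct_is_diagonal(self, slr2):
        gold = [M("arm_dosage", 0, 5), M("egfr_metric", 10, 18)]
        cm = confusion([(list(gold), gold)], slr2)
        pct = cm.percentages()
        assert pct["arm_dosage"]["arm_dosage"] == 100.0
        assert pct["egfr_metric"]["egfr_metric"] == 100.0

    def test_unmatched_gold_goes_to_unlabelled(self, slr2):
        gold = [M("arm_dosage", 0, 5)]
        cm = confusion([([], gold)], slr2)
        assert cm.counts["arm_dosage"]["unlabelled"] == 1

    def test_row_percentages_hand_computed(self, slr2):
        gold = [M("arm_dosage", 0, 5), M("arm_dosage", 10, 15), M("arm_dosage", 20, 25)]
        pred = [M("arm_dosage", 0, 5), M("arm_dosage", 10, 15), M("egfr_metric", 20, 25)]
        cm = confusion([(pred, gold)], slr2)
        pct = cm.percentages()
        assert pct["arm_dosage"]["arm_dosage"] == 66.7
        assert pct["arm_dosage"]["egfr_metric"] == 33.3

    def test_row_sums_conserve_actual_positives(self, slr2):
        rng = np.random.default_rng(7)
        types = list(slr2.entity_names)
        def mk(prefix):
            out = []
            for i in range(12):
                s = int(rng.integers(0, 60))
                out.append(M(str(rng.choice(types)), s, s + int(rng.integers(1, 5)),
                             f"{prefix}{i}_"))
            return out
        gold, pred = mk("G"), mk("P")
        cm = confusion([(pred, gold)], slr2)
        for t in slr2.entity_names:
            assert sum(cm.counts[t].values()) == sum(1 for m in gold if m.entity_type == t)
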