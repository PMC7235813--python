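"""Strict span-level scoring: worked examples, the brute-force oracle
twin, and the metric's algebraic properties."""

import numpy as np
import pytest

import layerfuse as lf
from layerfuse.metrics import evaluate, evaluate_bruteforce
from layerfuse.tagging import ENTITY_TYPES, EntitySpan, spans_to_tags, tag_vocabulary


def sent(length, spans):
    tokens = tuple("A" * length)
    return lf.AnnotatedSentence(tokens, tuple(spans))


def test_perfect_predictions_score_one_everywhere():
    gold = [sent(8, [EntitySpan(0, 2, "Dis"), EntitySpan(4, 6, "Med")]),
            sent(5, [EntitySpan(1, 4, "Abn")])]
    pred = [list(s.tags()) for s in gold]
    rep = evaluate(gold, pred)
    assert rep.micro.precision == rep.micro.recall == rep.micro.f1 == 1.0
    for t in ("Dis", "Med", "Abn"):
        assert rep.per_type[t].f1 == 1.0


def test_no_predictions_zero_denominator_policy():
    gold = [sent(4, [EntitySpan(0, 2, "Dis")])]
    rep = evaluate(gold, [["O"] * 4])
    s = rep.micro
    assert (s.tp, s.fp, s.fn) == (0, 0, 1)
    assert s.precision == s.recall == s.f1 == 0.0  # reported 0, never NaN


def test_hand_counted_mixed_example():
    """Gold {(Dis,0,2),(Med,5,7)}, predicted {(Dis,0,2),(Dis,5,7)}:
    one hit, one type-confused span -> P = R = F1 = 0.5."""
    gold = [sent(8, [EntitySpan(0, 2, "Dis"), EntitySpan(5, 7, "Med")])]
    pred = [spans_to_tags([EntitySpan(0, 2, "Dis"), EntitySpan(5, 7, "Dis")], 8)]
    for fn in (evaluate, evaluate_bruteforce):
        rep = fn(gold, pred)
        s = rep.micro
        assert (s.tp, s.fp, s.fn) == (1, 1, 1)
        assert (s.precision, s.recall, s.f1) == (0.5, 0.5, 0.5)


def test_duplicate_gold_spans_cannot_double_count():
    gold = [lf.AnnotatedSentence(tuple("AAAA"), (EntitySpan(0, 2, "Dis"),))]
    pred = [["B-Dis", "I-Dis", "B-Dis", "I-Dis"]]
    # second predicted span (2,4) matches nothing
    for fn in (evaluate, evaluate_bruteforce):
        s = fn(gold, pred).micro
        assert (s.tp, s.fp, s.fn) == (1, 1, 0)


def test_micro_counts_are_sums_of_per_type_counts():
    gold = [sent(9, [EntitySpan(0, 2, "Dis"), EntitySpan(3, 5, "Med"),
                     EntitySpan(6, 8, "Abn")])]
    pred = [spans_to_tags([EntitySpan(0, 2, "Dis"), EntitySpan(3, 5, "Abn")], 9)]
    rep = evaluate(gold, pred)
    assert rep.micro.tp == sum(s.tp for s in rep.per_type.values())
    assert rep.micro.fp == sum(s.fp for s in rep.per_type.values())
    assert rep.micro.fn == sum(s.fn for s in rep.per_type.values())


def test_length_mismatch_names_sentence_index():
    gold = [sent(4, []), sent(5, [])]
    with pytest.raises(ValueError, match="sentence 1"):
        evaluate(gold, [["O"] * 4, ["O"] * 4])
    with pytest.raises(ValueError, match="2 sentences"):
        evaluate(gold, [["O"] * 4])


def _random_case(rng):
    """Random gold spans (possibly adjacent) and a random tag sequence."""
    length = int(rng.integers(1, 25))
    spans = []
    at = 0
    while at < length - 1:
        if rng.random() < 0.5:
            end = int(rng.integers(at + 1, min(length, at + 5) + 1))
            spans.append(EntitySpan(at, end, ENTITY_TYPES[rng.integers(6)]))
            at = end  # adjacent spans allowed: no forced gap
        else:
            at += int(rng.integers(1, 4))
    gold = sent(length, spans)
    vocab = tag_vocabulary()
    if rng.random() < 0.1:
        tags = ["O"] * length                      # degenerate all-O
    elif rng.random() < 0.2:
        tags = list(gold.tags())                   # perfect prediction
    else:
        tags = [vocab[rng.integers(13)] for _ in range(length)]
    return gold, tags


def test_oracle_equivalence_on_randomized_cases():
    """evaluate and its brute-force twin agree on 1000+ random pairs
    including empty, duplicated and boundary-touching spans."""
    rng = np.random.default_rng(42)
    golds, preds = [], []
    for _ in range(1100):
        g, p = _random_case(rng)
        golds.append(g)
        preds.append(p)
    fast = evaluate(golds, preds)
    slow = evaluate_bruteforce(golds, preds)
    assert fast.per_type == slow.per_type
    # and per-sentence too (catches cancellation across sentences)
    for g, p in zip(golds[:200], preds[:200]):
        assert evaluate([g], [p]).per_type == \
            evaluate_bruteforce([g], [p]).per_type


def test_symmetry_swapping_gold_and_predicted():
    """Swapping roles swaps P and R and preserves F1."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        g1, p1 = _random_case(rng)
        g2 = sent(len(g1.tokens),
                  lf.tags_to_spans(p1, repair="start-new"))
        p2 = list(g1.tags())
        a, b = evaluate([g1], [p1]).micro, evaluate([g2], [p2]).micro
        assert np.isclose(a.precision, b.recall)
        assert np.isclose(a.recall, b.precision)
        assert np.isclose(a.f1, b.f1)


def test_f1_bounded_by_arithmetic_mean():
    rng = np.random.default_rng(8)
    for _ in range(200):
        g, p = _random_case(rng)
        s = evaluate([g], [p]).micro
        assert 0.0 <= s.f1 <= 1.0
        assert s.f1 <= (s.precision + s.recall) / 2 + 1e-12


def test_adding_a_correct_prediction_never_hurts():
    """Filling in one unmatched gold span raises R and F1 (never lowers)."""
    rng = np.random.default_rng(9)
    tried = 0
    for _ in range(300):
        g, p = _random_case(rng)
        pred_spans = lf.tags_to_spans(p, repair="start-new")
        taken = set(pred_spans)
        missing = [s for s in g.entities
                   if s not in taken
                   and all(s.end <= t.start or t.end <= s.start for t in taken)]
        if not missing:
            continue
        tried += 1
        before = evaluate([g], [p]).micro
        better = spans_to_tags(sorted(set(pred_spans) | {missing[0]}),
                               len(g.tokens))
        after = evaluate([g], [better]).micro
        assert after.recall >= before.recall
        assert after.f1 >= before.f1
    assert tried > 20


def test_report_table_and_dict_shapes():
    gold = [sent(4, [EntitySpan(0, 2, "Dis")])]
    rep = evaluate(gold, [list(gold[0].tags())])
    d = rep.to_dict()
    assert set(d) == {"per_type", "micro", "macro"}
    table = rep.to_table()
    assert "micro" in table and "100.00" in table
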