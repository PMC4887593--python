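"""Event-, series- and subject-level similarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tsevents as tv
from conftest import mk_event
from test_evaluation import random_event_list

SCALING = tv.FeatureScaling(duration_range_ms=200.0, magnitude_range=100.0, anchor_range_ms=1000.0)


def oracle_max_weight(weights):
    n, m = weights.shape
    if n == 0 or m == 0:
        return 0.0
    if n > m:
        return oracle_max_weight(weights.T)
    best = 0.0
    for cols in itertools.permutations(range(m), n):
        best = max(best, sum(weights[i, c] for i, c in enumerate(cols)))
    return best


class TestEventSimilarity:
    def test_identical_events(self):
        e = mk_event("spike", 10, 5, 40.0)
        assert tv.event_similarity(e, e, SCALING) == 1.0

    def test_type_mismatch_is_zero(self):
        a = mk_event("spike", 10, 5, 40.0)
        b = mk_event("fall", 10, 5, 40.0)
        assert tv.event_similarity(a, b, SCALING) == 0.0

    def test_hand_evaluated_formula(self):
        # durations 100 vs 150 ms, range 200, other features equal, equal weights
        a = mk_event("w", 0, 10, 50.0, anchor=0)
        b = mk_event("w", 0, 15, 50.0, anchor=0)
        expected = 1.0 - (50.0 / 200.0) / 3.0
        assert tv.event_similarity(a, b, SCALING) == pytest.approx(expected)

    def test_scaling_validation(self):
        with pytest.raises(ValueError):
            tv.FeatureScaling(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            tv.FeatureScaling(1.0, 1.0, 1.0, weights=(-0.1, 0.6, 0.5))

    def test_weights_are_normalised(self):
        s = tv.FeatureScaling(1.0, 1.0, 1.0, weights=(2.0, 1.0, 1.0))
        assert sum(s.weights) == pytest.approx(1.0)


class TestSeriesSimilarity:
    def test_self_similarity_is_one(self):
        events = [mk_event("a", 10 * i, 5, float(i + 1)) for i in range(4)]
        assert tv.series_similarity(events, list(events), SCALING) == 1.0

    def test_one_empty_side_is_zero(self):
        events = [mk_event("a", 0, 5, 1.0)]
        assert tv.series_similarity(events, [], SCALING) == 0.0
        assert tv.series_similarity([], events, SCALING) == 0.0

    def test_both_empty_is_vacuously_one(self):
        assert tv.series_similarity([], [], SCALING) == 1.0

    @given(st.integers(0, 199))
    def test_agrees_with_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a = random_event_list(rng, int(rng.integers(1, 7)))
        b = random_event_list(rng, int(rng.integers(1, 7)))
        score = tv.series_similarity(a, b, SCALING)
        weights = np.array(
            [[tv.event_similarity(x, y, SCALING) for y in b] for x in a]
        )
        expected = 2.0 * oracle_max_weight(weights) / (len(a) + len(b))
        assert score == pytest.approx(expected)

    def test_reduces_to_agreement_metric_with_indicator_weights(self):
        """With 0/1 event similarities the score is exactly the Dice form."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            na, nb = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            # identical features within a type: similarity is 1 same-type, 0 otherwise
            a = [mk_event(str(rng.choice(["x", "y"])), 0, 5, 1.0) for _ in range(na)]
            b = [mk_event(str(rng.choice(["x", "y"])), 0, 5, 1.0) for _ in range(nb)]
            n_match = sum(
                min(sum(e.event_type == t for e in a), sum(e.event_type == t for e in b))
                for t in ("x", "y")
            )
            expected = tv.sim_exp_lang(tv.EvaluationCounts(na, nb, n_match))
            assert tv.series_similarity(a, b, SCALING) == pytest.approx(expected)

    @given(st.integers(0, 60))
    def test_symmetric_bounded_reflexive(self, seed):
        rng = np.random.default_rng(seed)
        a = random_event_list(rng, int(rng.integers(0, 6)))
        b = random_event_list(rng, int(rng.integers(0, 6)))
        sab = tv.series_similarity(a, b, SCALING)
        assert 0.0 <= sab <= 1.0
        assert sab == pytest.approx(tv.series_similarity(b, a, SCALING))
        assert tv.series_similarity(a, list(a), SCALING) == 1.0


def _leaf_subject(subject_id, events_by_leaf):
    leaves = [
        tv.SeriesLeaf(
            tv.TimeSeries(np.zeros(1000), series_id=name), events=list(events)
        )
        for name, events in events_by_leaf
    ]
    return tv.SubjectRecord(
        subject_id=subject_id,
        measurements=[tv.Measurement("m", [tv.Condition("c", leaves)])],
    )


class TestSubjectSimilarity:
    def test_self_comparison_scores_one_everywhere(self):
        p = _leaf_subject("p", [("s1", [mk_event("a", 5, 5, 2.0)])])
        rep = tv.subject_similarity(p, p, SCALING)
        assert rep.overall == 1.0
        assert set(rep.node_scores.values()) == {1.0}

    def test_single_leaf_aggregation_is_identity(self):
        a = _leaf_subject("a", [("s1", [mk_event("w", 0, 10, 50.0, anchor=0)])])
        b = _leaf_subject("b", [("s1", [mk_event("w", 0, 15, 50.0, anchor=0)])])
        rep = tv.subject_similarity(a, b, SCALING)
        leaf_score = tv.series_similarity(a.pooled_events(), b.pooled_events(), SCALING)
        assert rep.overall == pytest.approx(leaf_score)

    def test_two_leaves_average(self):
        shared = [mk_event("a", 5, 5, 2.0)]
        # leaf 1 identical (1.0); leaf 2: duration-only weight gives 0.5
        dur_scaling = tv.FeatureScaling(200.0, 1e6, 1e6, weights=(1.0, 0.0, 0.0))
        a = _leaf_subject("a", [("s1", shared), ("s2", [mk_event("w", 0, 10, 1.0, anchor=0)])])
        b = _leaf_subject("b", [("s1", shared), ("s2", [mk_event("w", 0, 20, 1.0, anchor=0)])])
        rep = tv.subject_similarity(a, b, dur_scaling)
        assert rep.overall == pytest.approx((1.0 + 0.5) / 2)

    def test_quantitative_and_qualitative_leaves(self):
        def subj(sid, age, sex):
            return tv.SubjectRecord(
                subject_id=sid,
                measurements=[
                    tv.Measurement(
                        "m",
                        [
                            tv.Condition(
                                "c",
                                [
                                    tv.ValueLeaf("age", age, "quantitative"),
                                    tv.ValueLeaf("sex", sex, "qualitative"),
                                ],
                            )
                        ],
                    )
                ],
            )

        rep = tv.subject_similarity(
            subj("a", 20, "m"), subj("b", 30, "f"), SCALING,
            quantitative_ranges={"age": 50.0},
        )
        # age: 1 - 10/50 = 0.8 ; sex mismatch: 0 ; mean = 0.4
        assert rep.overall == pytest.approx(0.4)

    def test_structural_mismatch_names_first_divergent_path(self):
        a = _leaf_subject("a", [("s1", [])])
        b = _leaf_subject("b", [("other", [])])
        with pytest.raises(ValueError, match=r"measurement\[m\]/condition\[c\]/series"):
            tv.subject_similarity(a, b, SCALING)

    def test_unannotated_leaf_is_an_error(self):
        a = _leaf_subject("a", [("s1", [])])
        b = _leaf_subject("b", [("s1", [])])
        b.measurements[0].conditions[0].leaves[0].events = None
        with pytest.raises(ValueError, match="no event annotations"):
            tv.subject_similarity(a, b, SCALING)
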