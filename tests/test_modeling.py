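"""Reference-model generation and similarity-matrix outlier screening."""

import numpy as np
import pytest

import tsevents as tv
from conftest import mk_event

SCALING = tv.FeatureScaling(200.0, 100.0, 10000.0, weights=(0.5, 0.5, 0.0))


def subject_with_events(sid, event_lists, n=1000):
    leaves = [
        tv.SeriesLeaf(tv.TimeSeries(np.zeros(n), series_id=f"s{i+1}"), events=list(ev))
        for i, ev in enumerate(event_lists)
    ]
    return tv.SubjectRecord(
        subject_id=sid, measurements=[tv.Measurement("m", [tv.Condition("c", leaves)])]
    )


class TestPairwiseSimilarityMatrix:
    def test_duplicate_subject_scores_one(self):
        s = subject_with_events("a", [[mk_event("x", 10, 5, 3.0)]])
        t = subject_with_events("b", [[mk_event("x", 10, 5, 3.0)]])
        u = subject_with_events("c", [[mk_event("x", 400, 15, 9.0)]])
        m = tv.pairwise_similarity_matrix([s, t, u], SCALING)
        assert m[0, 1] == 1.0

    def test_three_identical_subjects_give_all_ones(self):
        subs = [
            subject_with_events(f"s{i}", [[mk_event("x", 10, 5, 3.0)]]) for i in range(3)
        ]
        np.testing.assert_allclose(tv.pairwise_similarity_matrix(subs, SCALING), 1.0)

    def test_symmetric_unit_diagonal_on_random_cohort(self, eeg_cohort):
        subs = eeg_cohort.subjects[:6]
        ev = [e for s in subs for e in s.pooled_events()]
        m = tv.pairwise_similarity_matrix(subs, tv.FeatureScaling.from_events(ev))
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert ((m >= 0) & (m <= 1)).all()


class TestDetectOutliers:
    def test_isolated_subject_fires_all_four_criteria(self):
        n = 10
        m = np.full((n, n), 0.9)
        m[-1, :] = m[:, -1] = 0.2
        np.fill_diagonal(m, 1.0)
        verdicts = tv.detect_outliers(m)
        assert verdicts[-1].is_outlier
        assert verdicts[-1].criteria_hit == (True, True, True, True)
        assert not any(v.is_outlier for v in verdicts[:-1])

    def test_all_ones_matrix_has_no_outliers(self):
        assert not any(v.is_outlier for v in tv.detect_outliers(np.ones((5, 5))))

    def test_small_or_asymmetric_matrices_rejected(self):
        with pytest.raises(ValueError):
            tv.detect_outliers(np.ones((2, 2)))
        bad = np.ones((4, 4))
        bad[0, 1] = 0.2
        with pytest.raises(ValueError, match="symmetric"):
            tv.detect_outliers(bad)

    def test_injected_five_sigma_outliers_flagged_without_false_positives(self):
        """Two 5-sigma outliers per class, seeded: both flagged, no FPs."""
        cohort = tv.generate_cohort(
            [tv.eeg_epileptic_spec()], 20, outlier_fraction=0.1,
            outlier_shift_sd=5.0, seed=0,
        )
        members = cohort.subjects
        ev = [e for s in members for e in s.pooled_events()]
        scaling = tv.FeatureScaling.from_events(ev, anchor_weight=0.0)
        matrix = tv.pairwise_similarity_matrix(members, scaling)
        verdicts = tv.detect_outliers(matrix, subject_ids=[s.subject_id for s in members])
        flagged = {v.subject_id for v in verdicts if v.is_outlier}
        assert flagged == set(cohort.outlier_ids)


class TestBuildReferenceModel:
    def test_identical_event_everywhere_gives_that_event(self):
        subs = [
            subject_with_events(f"s{i}", [[mk_event("x", 50, 10, 30.0, anchor=55)]])
            for i in range(5)
        ]
        model = tv.build_reference_model(subs, "c", scaling=SCALING)
        (e,) = model.events
        assert (e.event_type, e.duration_ms, e.magnitude) == ("x", 100.0, 30.0)
        assert e.support == 1.0 and e.cluster_size == 5

    def test_support_threshold_separates_populations(self):
        # population A in 100% of series, B in 80%, C in 20%
        subs = []
        for i in range(10):
            events = [mk_event("x", 50, 10, 30.0)]
            if i < 8:
                events.append(mk_event("x", 400, 40, 90.0))
            if i < 2:
                events.append(mk_event("x", 800, 100, 200.0))
            subs.append(subject_with_events(f"s{i}", [events]))
        model = tv.build_reference_model(subs, "c", scaling=SCALING)
        feats = {(e.duration_ms, round(e.magnitude)) for e in model.events}
        assert feats == {(100.0, 30), (400.0, 90)}
        supports = sorted(e.support for e in model.events)
        assert supports == [0.8, 1.0]

    def test_degenerate_model_raises(self):
        # every series carries a unique, well separated event type
        subs = [
            subject_with_events(f"s{i}", [[mk_event(f"t{i}", 10, 5, 5.0)]])
            for i in range(4)
        ]
        with pytest.raises(tv.DegenerateModelError, match="degenerate"):
            tv.build_reference_model(subs, "c", scaling=SCALING)

    def test_model_events_lie_within_training_feature_hull(self, eeg_cohort):
        members = [s for s in eeg_cohort.subjects if s.class_label == "healthy"]
        ev = [e for s in members for e in s.pooled_events()]
        scaling = tv.FeatureScaling.from_events(ev)
        model = tv.build_reference_model(members, "healthy", scaling=scaling)
        durs = [e.duration_ms for e in ev]
        mags = [e.magnitude for e in ev]
        for me in model.events:
            assert min(durs) <= me.duration_ms <= max(durs)
            assert min(mags) <= me.magnitude <= max(mags)

    def test_parameter_recovery_from_generator_means(self, eeg_cohort):
        """Model-level duration/magnitude within 15% of the class means."""
        for label, dur, mag in [("epileptic", 195.0, 78.0), ("healthy", 56.0, 54.0)]:
            members = [s for s in eeg_cohort.subjects if s.class_label == label]
            ev = [e for s in members for e in s.pooled_events()]
            model = tv.build_reference_model(
                members, label, scaling=tv.FeatureScaling.from_events(ev)
            )
            t = model.as_table()
            assert abs(t["Duration (ms)"].mean() / dur - 1) < 0.15
            assert abs(t["Magnitude"].mean() / mag - 1) < 0.15

    def test_duplicate_subject_never_removes_a_model_event(self):
        subs = []
        for i in range(10):
            events = [mk_event("x", 50, 10, 30.0)]
            if i < 8:
                events.append(mk_event("x", 400, 40, 90.0))
            subs.append(subject_with_events(f"s{i}", [events]))
        before = tv.build_reference_model(subs, "c", scaling=SCALING)
        augmented = subs + [subject_with_events("dup", [[mk_event("x", 50, 10, 30.0)]])]
        after = tv.build_reference_model(augmented, "c", scaling=SCALING)
        kinds_before = {(e.event_type, e.duration_ms, e.magnitude) for e in before.events}
        kinds_after = {(e.event_type, e.duration_ms, e.magnitude) for e in after.events}
        assert kinds_before <= kinds_after

    def test_generation_is_deterministic(self, eeg_cohort):
        members = [s for s in eeg_cohort.subjects if s.class_label == "healthy"]
        ev = [e for s in members for e in s.pooled_events()]
        scaling = tv.FeatureScaling.from_events(ev)
        a = tv.build_reference_model(members, "healthy", scaling=scaling)
        b = tv.build_reference_model(members, "healthy", scaling=scaling)
        assert a.events == b.events

    def test_json_roundtrip(self, tmp_path, eeg_cohort):
        members = [s for s in eeg_cohort.subjects if s.class_label == "healthy"]
        ev = [e for s in members for e in s.pooled_events()]
        model = tv.build_reference_model(
            members, "healthy", scaling=tv.FeatureScaling.from_events(ev)
        )
        p = tmp_path / "model.json"
        model.to_json(p)
        back = tv.ReferenceModel.from_json(p)
        assert back.class_label == model.class_label
        assert back.events == model.events


class TestModelSimilarity:
    def _model_from(self, events):
        return tv.ReferenceModel(
            class_label="c",
            events=[
                tv.ModelEvent(e.event_type, e.duration_ms, e.magnitude, e.anchor_index, 1.0, 1)
                for e in events
            ],
        )

    def test_subject_matching_model_scores_one(self):
        events = [mk_event("x", 50, 10, 30.0, anchor=55)]
        s = subject_with_events("a", [events])
        assert tv.model_similarity(s, self._model_from(events), SCALING) == 1.0

    def test_eventless_subject_scores_zero(self):
        s = subject_with_events("a", [[]])
        m = self._model_from([mk_event("x", 50, 10, 30.0)])
        assert tv.model_similarity(s, m, SCALING) == 0.0

    def test_two_vs_three_equals_assignment_score(self):
        subj_events = [mk_event("x", 10, 10, 20.0), mk_event("x", 200, 30, 60.0)]
        model_events = [
            mk_event("x", 15, 12, 25.0),
            mk_event("x", 210, 28, 55.0),
            mk_event("x", 500, 50, 90.0),
        ]
        s = subject_with_events("a", [subj_events])
        m = self._model_from(model_events)
        score = tv.model_similarity(s, m, SCALING)
        expected = tv.series_similarity(subj_events, model_events, SCALING)
        assert score == pytest.approx(expected)
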