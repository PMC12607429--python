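import copy

import numpy as np
import pytest

import spinsense as ss
from spinsense.evaluation import (
    HeuristicPredictor,
    compute_metrics,
    confusion_counts,
    evaluate_events,
    train_predictor,
)
from spinsense.io import ValidationError, annotations_to_sample_mask
from spinsense.models import HeuristicModel
from spinsense.segmentation import WindowingParams, curate_events


class TestMetrics:
    def test_event_confusion_arithmetic(self):
        # TP=19, FN=4, FP=3, TN=102: sensitivity 19/23, accuracy 121/128
        conf = {"tp": 19, "fn": 4, "fp": 3, "tn": 102}
        m = compute_metrics(conf)
        assert m["sensitivity"] == pytest.approx(19 / 23)
        assert m["accuracy"] == pytest.approx(121 / 128)
        assert m["specificity"] == pytest.approx(102 / 105)
        assert m["f1"] == pytest.approx(2 * 19 / (2 * 19 + 3 + 4))

    def test_perfect_scores_give_auc_1(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(confusion_counts(labels, (scores > 0.5).astype(int)), scores, labels)
        assert m["roc_auc"] == 1.0

    def test_single_class_truth_reports_auc_absent(self):
        labels = np.zeros(4, dtype=int)
        m = compute_metrics(confusion_counts(labels, labels), np.ones(4), labels)
        assert m["roc_auc"] is None

    def test_random_scores_balanced_labels_auc_near_half(self, rng):
        labels = np.array([0, 1] * 1000)
        scores = rng.uniform(size=2000)
        m = compute_metrics(confusion_counts(labels, labels), scores, labels)
        assert m["roc_auc"] == pytest.approx(0.5, abs=0.05)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics({"tp": 0, "fp": 0, "fn": 0, "tn": 0})


class TestEventAggregation:
    def _setup(self, study):
        params = WindowingParams()
        recs = {}
        events = []
        for rec, ann in study:
            mask = annotations_to_sample_mask(rec, ann)
            recs[rec.subject_id] = (rec, mask)
            events.extend(curate_events(rec, ann, 7.8))
        return params, recs, events

    def test_single_positive_window_flips_event(self, small_study):
        """OR rule: window predictions (0,0,1,0,0) make the event a spin."""
        params, recs, events = self._setup(small_study)
        spin_events = [e for e in events if e.klass == "spin"]

        class OneWindowPredictor:
            def predict(self, segments):
                out = np.zeros(len(segments), dtype=int)
                out[len(segments) // 2] = 1
                return out

        conf, details = evaluate_events(OneWindowPredictor(), spin_events, recs, params)
        assert conf["tp"] == len(spin_events) and conf["fn"] == 0
        assert all(d["window_predictions"].count(1) == 1 for d in details)

    def test_all_negative_windows_give_non_spin(self, small_study):
        params, recs, events = self._setup(small_study)

        class NeverPredictor:
            def predict(self, segments):
                return np.zeros(len(segments), dtype=int)

        conf, _ = evaluate_events(NeverPredictor(), events, recs, params)
        assert conf["tp"] == 0 and conf["fp"] == 0
        assert conf["fn"] == sum(e.klass == "spin" for e in events)

    def test_impure_event_rejected(self, small_study):
        params, recs, events = self._setup(small_study)
        bad = copy.copy(events[0])
        bad.purity = False
        with pytest.raises(ValidationError, match="impure"):
            evaluate_events(HeuristicPredictor(HeuristicModel(threshold=50.0)), [bad], recs, params)

    def test_event_sensitivity_dominates_segment_sensitivity(self, rf_lodo_report):
        """OR aggregation can only add detections: an event is caught as
        soon as any of its windows is."""
        seg = rf_lodo_report.segment_metrics
        ev = rf_lodo_report.event_metrics
        assert ev["sensitivity"] >= seg["sensitivity"]


class TestProtocols:
    def test_lodo_full_cv_has_one_fold_per_subject(self, small_study):
        rep = ss.run_protocol(
            small_study, ss.SplitProtocol(kind="lodo_full_cv", seed=1), model="heuristic"
        )
        assert len(rep.folds) == len(small_study)
        for fold, (rec, _) in zip(rep.folds, small_study):
            assert fold.test_subjects == [rec.subject_id]
            assert rec.subject_id not in fold.train_subjects

    def test_unknown_holdout_subject_rejected(self, small_study):
        with pytest.raises(ValidationError, match="unknown holdout"):
            ss.run_protocol(
                small_study,
                ss.SplitProtocol(kind="lodo_single_holdout", holdout_subject="ghost_dog", seed=1),
                model="heuristic",
            )

    def test_lodo_needs_two_subjects(self, small_study):
        with pytest.raises(ValidationError, match="two subjects"):
            ss.run_protocol(small_study[:1], ss.SplitProtocol(kind="lodo_full_cv"), model="heuristic")

    def test_unknown_protocol_kind_rejected(self):
        with pytest.raises(ValidationError):
            ss.SplitProtocol(kind="k_fold")

    def test_within_subject_separable_fixture_is_perfect(self):
        """Rectangular spins aligned to a non-overlapping window grid:
        every window is purely spin or purely background, so the magnitude
        rule classifies all held-out windows correctly."""
        rate = 50.0
        studies = []
        for subject in ("dogA", "dogB"):
            data = np.zeros((3900, 6))
            intervals = []
            for k in (3, 9, 15, 21):  # window-aligned 2.6 s spins
                a = k * 130
                data[a : a + 130, 5] = 300.0
                intervals.append((a / rate, (a + 130) / rate, "spin"))
            rec = ss.ImuRecording(subject_id=subject, sampling_rate=rate, data=data)
            studies.append((rec, ss.AnnotationTrack(subject_id=subject, intervals=intervals)))
        rep = ss.run_protocol(
            studies,
            ss.SplitProtocol(kind="within_subject_random", seed=2),
            model="heuristic",
            windowing=WindowingParams(window_size=2.6, stride=2.6),
        )
        assert rep.segment_metrics["accuracy"] == 1.0

    def test_leakage_audit_clean_for_all_protocols(self, small_study):
        for kind, holdout in [
            ("lodo_full_cv", None),
            ("lodo_single_holdout", small_study[0][0].subject_id),
            ("within_subject_random", None),
            ("event_stratified_8020", None),
        ]:
            rep = ss.run_protocol(
                small_study,
                ss.SplitProtocol(kind=kind, holdout_subject=holdout, seed=4),
                model="heuristic",
            )
            assert rep.leakage_audit["clean"], kind
            assert rep.leakage_audit["event_overlap"] == 0
            assert rep.leakage_audit["subject_overlap"] == 0

    def test_metrics_recomputable_from_stored_confusion(self, rf_lodo_report):
        conf = rf_lodo_report.segment_confusion
        total = sum(conf.values())
        assert rf_lodo_report.segment_metrics["accuracy"] == pytest.approx(
            (conf["tp"] + conf["tn"]) / total
        )
        assert rf_lodo_report.segment_metrics["f1"] == pytest.approx(
            2 * conf["tp"] / (2 * conf["tp"] + conf["fp"] + conf["fn"])
        )
        ev = rf_lodo_report.event_confusion
        assert sum(ev.values()) > 0
        assert rf_lodo_report.event_metrics["accuracy"] == pytest.approx(
            (ev["tp"] + ev["tn"]) / sum(ev.values())
        )

    def test_report_json_is_deterministic(self, small_study):
        reps = [
            ss.run_protocol(
                small_study, ss.SplitProtocol(kind="lodo_full_cv", seed=6), model="heuristic"
            ).to_json()
            for _ in range(2)
        ]
        assert reps[0] == reps[1]


class TestPermutationNull:
    def test_random_labels_give_chance_level_auc(self, small_segments):
        """When window labels carry no information anywhere, held-out
        ROC-AUC averages to chance (0.5) across permutations."""
        subjects = list(small_segments)
        test = [copy.copy(s) for s in small_segments[subjects[-1]]]
        train_pool = [s for sid in subjects[:-1] for s in small_segments[sid]]
        rng = np.random.default_rng(13)
        from sklearn.metrics import roc_auc_score

        aucs = []
        for _ in range(8):
            train = [copy.copy(s) for s in train_pool]
            labels = [s.label for s in train]
            for s, i in zip(train, rng.permutation(len(labels))):
                s.label = labels[i]
            # labels random on the held-out side too: permute truth as well
            y_test = np.array([1 if s.is_spin else 0 for s in test])
            y_test = y_test[rng.permutation(len(y_test))]
            predictor = train_predictor("random_forest", train, 50.0)
            aucs.append(roc_auc_score(y_test, predictor.score(test)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)
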