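import numpy as np
import pytest

from echopipe.curation import (BackendContractError, ExclusionReason,
                               NoisyBackend, OracleModalityBackend,
                               OracleViewBackend, aggregate_image_quality,
                               classify_modality, classify_view, curate_exam,
                               gate_view_confidence, get_backend,
                               select_views_for_lavi, select_views_for_lvef)
from echopipe.exam_model import (ExamRecord, Modality, PatientInfo, Recording,
                                 Sex, View)
from echopipe.synthetic import CorruptionSpec, PhantomSpec, generate_exam

PAT = PatientInfo("p", Sex.MALE, 175, 75)


def _bmode(rid, view, confidence=1.0):
    return Recording(recording_id=rid, modality=Modality.B2D, view=view,
                     view_confidence=confidence, frame_rate=50.0)


class TestGate:
    @pytest.mark.parametrize("confidence,expected", [
        (0.85, True),   # inclusive boundary
        (0.849, False),
        (1.0, True),
        (0.0, False),
    ])
    def test_boundary(self, confidence, expected):
        assert gate_view_confidence(confidence) is expected

    def test_custom_threshold(self):
        assert gate_view_confidence(0.6, threshold=0.5)


class TestQualityAggregation:
    @pytest.mark.parametrize("scores,expected", [
        ([3, 3, 3, 3], 3),
        ([2.4, 2.4], 2),     # mean 2.4 rounds down
        ([2.5, 2.5], 3),     # half rounds up
        ([5, 5, 5], 5),
        ([0.2, 0.2], 0),
    ])
    def test_mean_rounded_half_up(self, scores, expected):
        assert aggregate_image_quality(scores) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_image_quality([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            aggregate_image_quality([6.0])


class TestClassification:
    def test_oracle_modality_on_synthetic_exam(self, pristine):
        exam, _ = pristine
        backend = OracleModalityBackend()
        labels = {}
        for rec in exam.recordings:
            label, conf = classify_modality(rec, backend)
            labels[rec.recording_id] = (label, conf)
            assert conf == 1.0
        values = [l.value for l, _ in labels.values()]
        assert values.count("B2D") == 4
        assert values.count("pw_doppler") == 1

    def test_view_requires_b2d(self):
        rec = Recording(recording_id="r", modality=Modality.PW_DOPPLER)
        with pytest.raises(ValueError, match="B2D"):
            classify_view(rec, OracleViewBackend())

    def test_probability_contract_enforced(self):
        class BadBackend:
            taxonomy = OracleViewBackend.taxonomy

            def classify(self, recording):
                probs = np.zeros(len(self.taxonomy))
                probs[0] = 0.9  # sums to 0.9, violates contract
                return self.taxonomy[0], probs

        rec = Recording(recording_id="r", modality=Modality.B2D)
        with pytest.raises(BackendContractError, match="sum"):
            classify_view(rec, BadBackend())

    def test_confidence_override_propagates(self):
        exam, _ = generate_exam(
            PhantomSpec(seed=0),
            CorruptionSpec(confidence_override={View.A2C: 0.5}))
        backend = OracleViewBackend()
        rec = next(r for r in exam.recordings
                   if (r.annotations or {}).get("true_view") == "A2C")
        rec.modality = Modality.B2D
        view, conf = classify_view(rec, backend)
        assert view is View.A2C
        assert conf == pytest.approx(0.5)

    def test_noisy_backend_accuracy_within_binomial_ci(self):
        """A 5% label-flip backend is ~95% accurate over 200 recordings."""
        backend = NoisyBackend(OracleModalityBackend(), flip_rate=0.05, seed=42)
        n, correct = 200, 0
        for i in range(n):
            rec = Recording(recording_id=f"r{i}",
                            annotations={"true_modality": "B2D"})
            label, _ = backend.classify(rec)
            correct += label == "B2D"
        p = 0.95
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(correct - n * p) < 4 * sigma

    def test_unknown_backend_name(self):
        with pytest.raises(KeyError):
            get_backend("modality", "resnet")


class TestViewSelection:
    def test_focused_preferred_standard_fallback(self):
        exam = ExamRecord("s", PAT, [
            _bmode("r1", View.A4C_LV_FOCUSED),
            _bmode("r2", View.A4C),
            _bmode("r3", View.A2C),
        ])
        sel = select_views_for_lvef(exam)
        assert sel.ok
        assert sel.representatives == {"a4c": "r1", "a2c": "r3"}

    def test_low_confidence_slot_excludes(self):
        exam = ExamRecord("s", PAT, [
            _bmode("r1", View.A4C),
            _bmode("r2", View.A2C, confidence=0.5),
        ])
        sel = select_views_for_lvef(exam)
        assert not sel.ok
        assert sel.exclusion_reason is ExclusionReason.LOW_VIEW_CONFIDENCE

    def test_missing_a2c(self):
        exam = ExamRecord("s", PAT, [_bmode("r1", View.A4C)])
        sel = select_views_for_lvef(exam)
        assert sel.exclusion_reason is ExclusionReason.MISSING_A2C

    def test_doppler_only_is_no_bmode(self):
        exam = ExamRecord("s", PAT, [
            Recording(recording_id="r1", modality=Modality.PW_DOPPLER),
            Recording(recording_id="r2", modality=Modality.CW_DOPPLER),
        ])
        assert select_views_for_lvef(exam).exclusion_reason is \
            ExclusionReason.NO_BMODE

    def test_multiple_clips_all_kept_best_first(self):
        exam = ExamRecord("s", PAT, [
            _bmode("r1", View.A4C, 0.9),
            _bmode("r2", View.A4C, 0.95),
            _bmode("r3", View.A2C),
        ])
        sel = select_views_for_lvef(exam)
        assert sel.candidates["a4c"] == ["r2", "r1"]

    def test_lavi_ignores_focused_views(self):
        exam = ExamRecord("s", PAT, [
            _bmode("r1", View.A4C_LV_FOCUSED),
            _bmode("r2", View.A2C_LV_FOCUSED),
        ])
        sel = select_views_for_lavi(exam)
        assert not sel.ok
        assert sel.exclusion_reason is ExclusionReason.MISSING_A4C_FOR_LA

    def test_lavi_standard_pair(self):
        exam = ExamRecord("s", PAT, [
            _bmode("r1", View.A4C),
            _bmode("r2", View.A2C),
        ])
        sel = select_views_for_lavi(exam)
        assert sel.ok and sel.representatives == {"a4c": "r1", "a2c": "r2"}

    def test_gate_monotonicity(self):
        """Raising the confidence threshold never includes more exams."""
        rng = np.random.default_rng(0)
        exams = []
        for i in range(30):
            exams.append(ExamRecord(f"s{i}", PAT, [
                _bmode("r1", View.A4C, float(rng.uniform(0.5, 1.0))),
                _bmode("r2", View.A2C, float(rng.uniform(0.5, 1.0))),
            ]))
        counts = [sum(select_views_for_lvef(e, threshold=t).ok for e in exams)
                  for t in (0.5, 0.7, 0.85, 0.95)]
        assert counts == sorted(counts, reverse=True)


class TestCurateExam:
    def test_pristine_exam_included(self, pristine):
        exam, _ = pristine
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        assert outcome.included and outcome.la_included
        assert set(outcome.selected_lv_views) == {"a4c", "a2c"}
        assert "A4C_LV_focused" in outcome.selected_lv_views["a4c"]
        assert outcome.exclusion_reason is ExclusionReason.NONE

    def test_tee_only_excluded(self):
        exam = ExamRecord("s", PAT, [
            Recording(recording_id="r1", modality=Modality.B2D,
                      annotations={"true_modality": "B2D", "true_view": "TEE"}),
        ])
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        assert not outcome.included
        assert outcome.exclusion_reason is ExclusionReason.TEE_ONLY

    def test_quality_class_from_regional_scores(self):
        exam, _ = generate_exam(PhantomSpec(seed=0),
                                CorruptionSpec(quality_scores=[3.6, 3.6, 3.6]))
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        assert outcome.quality_class == 4

    def test_injected_exclusions_match_outcomes(self):
        """The curation verdict reproduces each corruption's expected
        exclusion reason exactly."""
        cases = [
            (CorruptionSpec(), None),
            (CorruptionSpec(drop_views={View.A2C, View.A2C_LV_FOCUSED}),
             ExclusionReason.MISSING_A2C),
            (CorruptionSpec(drop_views={View.A4C, View.A4C_LV_FOCUSED}),
             ExclusionReason.MISSING_A4C),
            (CorruptionSpec(confidence_override={View.A4C: 0.3,
                                                 View.A4C_LV_FOCUSED: 0.3}),
             ExclusionReason.LOW_VIEW_CONFIDENCE),
        ]
        for corruption, expected in cases:
            exam, truth = generate_exam(PhantomSpec(seed=8), corruption)
            outcome = curate_exam(exam, OracleModalityBackend(),
                                  OracleViewBackend())
            if expected is None:
                assert outcome.included
                assert truth.expected_exclusion is None
            else:
                assert not outcome.included
                assert outcome.exclusion_reason is expected
                assert truth.expected_exclusion == expected.value
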