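import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echopipe.curation import OracleModalityBackend, OracleViewBackend, curate_exam
from echopipe.measurement import (InvalidSegmentationError, MeasurementExclusion,
                                  MeasurementResult, biplane_simpson,
                                  body_surface_area, dice, disc_diameters,
                                  ejection_fraction, extract_long_axis, lavi,
                                  measure_exam, segmentation_qc)
from echopipe.synthetic import CorruptionSpec, PhantomSpec, generate_exam
from echopipe.timing import OracleTimingBackend, resolve_events
from tests.conftest import make_ellipse


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = b[7, 7] = True
        assert dice(a, b) == 0.0

    def test_shifted_block_by_hand(self):
        # 2x2 block vs the same block shifted one column: overlap 2 px
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True
        assert dice(a, b) == 0.5

    def test_both_empty_is_one(self):
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**16 - 1))
    def test_symmetric_and_bounded(self, bits):
        a = np.array([(bits >> i) & 1 for i in range(8)], bool).reshape(2, 4)
        b = np.array([(bits >> (i + 8)) & 1 for i in range(8)], bool).reshape(2, 4)
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestSegmentationQc:
    def test_threshold_inclusive(self):
        # 4/5 overlap on equal-size masks -> dice > 0.8; construct exact 0.8
        a = np.zeros((1, 10), bool)
        b = np.zeros((1, 10), bool)
        a[0, :5] = True
        b[0, 1:6] = True  # overlap 4, dice 8/10 = 0.8 exactly
        ok, d = segmentation_qc(a, b)
        assert d == pytest.approx(0.8)
        assert ok

    def test_below_threshold_fails(self):
        a = np.zeros((1, 100), bool)
        b = np.zeros((1, 100), bool)
        a[0, :50] = True
        b[0, 11:61] = True  # overlap 39, dice 78/100 = 0.78
        ok, d = segmentation_qc(a, b)
        assert d < 0.8 and not ok


class TestScalarFormulas:
    @pytest.mark.parametrize("edv,esv,expected", [
        (100.0, 50.0, 50.0),
        (150.0, 150.0, 0.0),
        (120.0, 40.0, 200.0 / 3.0),
    ])
    def test_ejection_fraction(self, edv, esv, expected):
        assert ejection_fraction(edv, esv) == pytest.approx(expected)

    def test_ef_requires_positive_edv(self):
        with pytest.raises(ValueError):
            ejection_fraction(0.0, 10.0)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(50, 250), st.floats(0.1, 0.9), st.floats(0.01, 0.1))
    def test_ef_monotone_decreasing_in_esv(self, edv, frac, d):
        esv = edv * frac
        assert ejection_fraction(edv, esv) > ejection_fraction(edv, esv + d * edv)

    @pytest.mark.parametrize("w,h,expected", [
        (100.0, 36.0, 1.0),                      # sqrt(3600)/60
        (72.0, 180.0, math.sqrt(12960) / 60.0),  # ~1.897
    ])
    def test_bsa_mosteller(self, w, h, expected):
        assert body_surface_area(w, h) == pytest.approx(expected)

    def test_bsa_dubois_alternative(self):
        # DuBois and Mosteller agree within a few percent for average adults
        m = body_surface_area(72, 180, "mosteller")
        d = body_surface_area(72, 180, "dubois")
        assert abs(m - d) / m < 0.05

    def test_bsa_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            body_surface_area(0.0, 180.0)

    @pytest.mark.parametrize("la,bsa,expected", [
        (68.0, 2.0, 34.0),
        (0.0, 1.5, 0.0),
    ])
    def test_lavi(self, la, bsa, expected):
        assert lavi(la, bsa) == pytest.approx(expected)

    def test_lavi_rejects_nonpositive_bsa(self):
        with pytest.raises(ValueError):
            lavi(60.0, 0.0)


class TestLongAxis:
    def test_axis_aligned_ellipse_length(self):
        # semi-axes 40x20 px at 0.5 mm/px -> long axis 40 mm
        mask = make_ellipse(20.0, 10.0, 0.5)
        axis = extract_long_axis(mask, 0.5)
        assert axis.length_mm == pytest.approx(40.0, abs=0.5)

    @pytest.mark.parametrize("angle", [30.0, 65.0])
    def test_rotation_invariant_length(self, angle):
        sp = 0.5
        straight = extract_long_axis(make_ellipse(20.0, 10.0, sp), sp)
        rotated = extract_long_axis(make_ellipse(20.0, 10.0, sp, angle), sp)
        assert rotated.length_mm == pytest.approx(straight.length_mm, abs=0.5)

    def test_tiny_mask_invalid(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4:6] = True
        with pytest.raises(InvalidSegmentationError, match="px"):
            extract_long_axis(mask, 0.5)

    def test_disconnected_mask_invalid(self):
        mask = np.zeros((40, 40), bool)
        mask[2:12, 2:12] = True
        mask[25:35, 25:35] = True
        with pytest.raises(InvalidSegmentationError, match="components"):
            extract_long_axis(mask, 0.5)


class TestDiscDiameters:
    def test_circle_middle_disc_is_diameter(self):
        sp, r = 0.5, 15.0
        mask = make_ellipse(r, r, sp)
        axis = extract_long_axis(mask, sp)
        d = disc_diameters(mask, axis, sp, n_discs=21)
        assert d[10] == pytest.approx(2 * r, abs=0.6)

    def test_ellipse_chords_match_analytic(self):
        sp, a, b = 0.5, 25.0, 12.0
        mask = make_ellipse(a, b, sp)
        center = (mask.shape[0] - 1) / 2.0
        axis = extract_long_axis(mask, sp)
        n = 20
        diameters = disc_diameters(mask, axis, sp, n_discs=n)
        apex = np.array(axis.apex_point)
        base = np.array(axis.base_midpoint)
        for i, d in enumerate(diameters):
            # slab center in mm, measured from the ellipse center along
            # the extracted axis (which overhangs the tip by half a pixel)
            pos = apex + (i + 0.5) / n * (base - apex)
            x = (pos[0] - center) * sp
            expected = 2 * b * math.sqrt(max(0.0, 1 - min(abs(x) / a, 1.0) ** 2))
            assert d == pytest.approx(expected, abs=0.6)

    def test_slab_beyond_mask_is_zero(self):
        from echopipe.measurement import LongAxis

        sp = 0.5
        mask = make_ellipse(10.0, 5.0, sp)
        center = (mask.shape[0] - 1) / 2.0
        # axis deliberately extends far past the apex
        axis = LongAxis(apex_point=(0.0, center),
                        base_midpoint=(2 * center, center),
                        length_mm=2 * center * sp)
        d = disc_diameters(mask, axis, sp, n_discs=20)
        assert d[0] == 0.0 and d[-1] == 0.0
        assert max(d) > 0


class TestBiplaneSimpson:
    def test_sphere_closed_form(self):
        sp, r = 0.5, 30.0
        mask = make_ellipse(r, r, sp)
        truth = 4.0 / 3.0 * math.pi * r**3 / 1000.0  # 113.1 mL
        vol = biplane_simpson(mask, mask, sp, sp)
        assert abs(vol.volume_ml - truth) / truth < 0.02

    def test_prolate_ellipsoid_closed_form(self):
        sp = 0.5
        mask = make_ellipse(40.0, 20.0, sp)  # L=80, D=40
        truth = math.pi / 6.0 * 80 * 40 * 40 / 1000.0  # 67.0 mL
        vol = biplane_simpson(mask, mask, sp, sp)
        assert abs(vol.volume_ml - truth) / truth < 0.02

    def test_error_decreases_with_finer_spacing(self):
        truth = math.pi / 6.0 * 80 * 40 * 40 / 1000.0
        errs = []
        for sp in (0.5, 0.25):
            mask = make_ellipse(40.0, 20.0, sp)
            errs.append(abs(biplane_simpson(mask, mask, sp, sp).volume_ml - truth))
        assert errs[1] < errs[0]

    def test_rotation_invariance(self):
        sp = 0.5
        v0 = biplane_simpson(make_ellipse(40.0, 20.0, sp),
                             make_ellipse(40.0, 20.0, sp), sp, sp).volume_ml
        m = make_ellipse(40.0, 20.0, sp, angle_deg=30.0)
        v30 = biplane_simpson(m, m, sp, sp).volume_ml
        assert abs(v30 - v0) / v0 < 0.02

    def test_scale_equivariance(self):
        # halving the spacing while doubling pixel extent is the same object
        v_coarse = biplane_simpson(make_ellipse(40.0, 20.0, 0.5),
                                   make_ellipse(40.0, 20.0, 0.5), 0.5, 0.5)
        v_fine = biplane_simpson(make_ellipse(40.0, 20.0, 0.25),
                                 make_ellipse(40.0, 20.0, 0.25), 0.25, 0.25)
        assert abs(v_fine.volume_ml - v_coarse.volume_ml) / v_coarse.volume_ml < 0.01

    def test_empty_mask_invalid(self):
        mask = make_ellipse(20.0, 10.0, 0.5)
        with pytest.raises(InvalidSegmentationError):
            biplane_simpson(np.zeros_like(mask), mask, 0.5, 0.5)

    def test_foreshortening_flagged_on_length_discrepancy(self):
        sp = 0.5
        full = make_ellipse(40.0, 20.0, sp)
        short = make_ellipse(28.0, 20.0, sp)  # 30% shorter long axis
        assert biplane_simpson(full, short, sp, sp).foreshortening_suspected
        assert not biplane_simpson(full, full, sp, sp).foreshortening_suspected


def _measure(exam, curation_outcome, dice_threshold=0.8):
    backend = OracleTimingBackend()
    events = {}
    for ids in list(curation_outcome.lv_candidates.values()) + \
            list(curation_outcome.la_candidates.values()):
        for rid in ids:
            rec = exam.get_recording(rid)
            events[rid] = resolve_events(rec, exam.patient, backend)
    return measure_exam(exam, curation_outcome, events,
                        dice_threshold=dice_threshold)


class TestMeasureExam:
    def test_pristine_phantom_recovers_ef(self, pristine):
        exam, truth = pristine
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        result = _measure(exam, outcome)
        assert isinstance(result, MeasurementResult)
        assert result.ef_pct == pytest.approx(truth.ef_pct, abs=2.0)
        assert result.edv_ml == pytest.approx(truth.edv_ml, rel=0.02)
        assert result.lavi_ml_m2 == pytest.approx(truth.lavi_ml_m2, abs=2.0)
        assert result.timing_source == "network"
        assert result.dice_ed == 1.0 and result.dice_es == 1.0

    def test_degraded_dice_excluded(self):
        exam, truth = generate_exam(PhantomSpec(seed=5),
                                    CorruptionSpec(dice_degradation=0.4))
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        result = _measure(exam, outcome)
        assert isinstance(result, MeasurementExclusion)
        assert result.reason == "low_dice"
        assert truth.achieved_dice < 0.8

    def test_duplicate_clips_average_without_change(self, pristine):
        import copy

        exam, truth = pristine
        exam = copy.deepcopy(exam)
        extra = copy.deepcopy(next(
            r for r in exam.recordings
            if (r.annotations or {}).get("true_view") == "A4C_LV_focused"))
        extra.recording_id += "-dup"
        exam.recordings.append(extra)
        outcome = curate_exam(exam, OracleModalityBackend(), OracleViewBackend())
        result = _measure(exam, outcome)
        assert result.n_clips_averaged == 2
        single = _measure(exam, curate_exam(
            generate_exam(PhantomSpec(edv_ml=150.0, esv_ml=75.0,
                                      la_esv_ml=60.0, seed=1))[0],
            OracleModalityBackend(), OracleViewBackend()))
        assert result.ef_pct == pytest.approx(single.ef_pct, abs=1e-9)
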