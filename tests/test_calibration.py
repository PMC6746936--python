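"""Gray-to-BMD calibration: two-anchor line, averaging, pixel mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxafem.calibration import (
    CalibrationLine,
    GrayImage,
    RoiMeasurement,
    apply_calibration,
    calibrate_single_roi,
    combine_rois,
)
from dxafem.phantom import generate_femur_image


def _toy_image(grays, spacing=0.5):
    return GrayImage(pixels=np.asarray(grays, dtype=float), spacing_mm=spacing)


class TestSingleRoi:
    def test_two_anchor_line(self):
        img = _toy_image(np.full((4, 4), 100.0))
        roi = RoiMeasurement("neck", np.ones((4, 4), bool), 1.0)
        line = calibrate_single_roi(img, roi, 0.20)
        assert line.intercept_b == pytest.approx(0.20)
        assert line.slope_m == pytest.approx(0.008)
        assert line(100.0) == pytest.approx(1.0)

    def test_zero_fraction_limit(self):
        img = _toy_image(np.full((2, 2), 50.0))
        roi = RoiMeasurement("neck", np.ones((2, 2), bool), 0.8)
        line = calibrate_single_roi(img, roi, 0.0)
        assert line.intercept_b == 0.0
        assert line.slope_m == pytest.approx(0.8 / 50.0)

    def test_hand_example_3x3(self):
        # grays {50, 100, 150}, zeros elsewhere; non-zero mean is 100
        pix = np.zeros((3, 3))
        pix[0, 0], pix[1, 1], pix[2, 2] = 50, 100, 150
        img = _toy_image(pix)
        roi = RoiMeasurement("trochanter", np.ones((3, 3), bool), 0.9)
        line = calibrate_single_roi(img, roi, 0.10)
        assert line.intercept_b == pytest.approx(0.09)
        assert line.slope_m == pytest.approx(0.0081)
        assert line(100.0) == pytest.approx(0.9000, abs=1e-12)

    def test_all_zero_grays_error(self):
        img = _toy_image(np.zeros((3, 3)))
        roi = RoiMeasurement("neck", np.ones((3, 3), bool), 0.9)
        with pytest.raises(ValueError, match="slope undefined"):
            calibrate_single_roi(img, roi, 0.2)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_gray_rescaling(self, scale):
        """gray -> a*gray (a > 0) leaves the mapped BMD values unchanged."""
        pix = np.array([[10.0, 20.0], [30.0, 0.0]])
        mask = pix > 0
        roi = RoiMeasurement("neck", mask, 0.7)
        line1 = calibrate_single_roi(_toy_image(pix), roi, 0.15)
        line2 = calibrate_single_roi(_toy_image(pix * scale), roi, 0.15)
        np.testing.assert_allclose(
            line1(pix[mask]), line2(pix[mask] * scale), rtol=1e-12
        )


class TestCombine:
    def _line(self, b, m, f=0.2):
        return CalibrationLine(b, m, f)

    def test_idempotent_on_identical_lines(self):
        line = self._line(0.1, 0.005)
        combined = combine_rois([line, line, line])
        assert combined.intercept_b == pytest.approx(line.intercept_b, rel=1e-15)
        assert combined.slope_m == pytest.approx(line.slope_m, rel=1e-15)
        assert combined.fraction_f == line.fraction_f

    def test_arithmetic_mean(self):
        lines = [self._line(0.1, 0.004), self._line(0.2, 0.006), self._line(0.3, 0.008)]
        combined = combine_rois(lines)
        assert combined.intercept_b == pytest.approx(0.2)
        assert combined.slope_m == pytest.approx(0.006)

    def test_mixed_fractions_rejected(self):
        lines = [self._line(0.1, 0.004, 0.2), self._line(0.1, 0.004, 0.2),
                 self._line(0.1, 0.004, 0.3)]
        with pytest.raises(ValueError, match="different fractions"):
            combine_rois(lines)


class TestApply:
    def test_gray_zero_maps_to_intercept_and_line_evaluation(self):
        pix = np.array([[0.0, 100.0]])
        mask = np.array([[True, True]])
        line = CalibrationLine(0.2, 0.008, 0.2)
        abmd = apply_calibration(_toy_image(pix), line, mask)
        assert abmd[0, 0] == pytest.approx(0.2)
        assert abmd[0, 1] == pytest.approx(1.0)

    def test_background_excluded_and_monotone(self):
        pix = np.array([[0.0, 10.0, 20.0]])
        mask = np.array([[False, True, True]])
        line = CalibrationLine(0.1, 0.01, 0.1)
        abmd = apply_calibration(_toy_image(pix), line, mask)
        assert np.isnan(abmd[0, 0])
        assert abmd[0, 1] < abmd[0, 2]


def test_phantom_roundtrip_recovers_synthesis_line_exactly():
    """Whole-femur single-ROI calibration on a noiseless phantom recovers the
    synthesis line and the truth BMD map to machine precision."""
    image, masks, truth = generate_femur_image(seed=4, noise_sd=0.0)
    b, m, f = truth.gray_to_bmd_line
    fg = masks["femur"]
    roi = RoiMeasurement("neck", fg, float(np.nanmean(truth.true_bmd_map[fg])))
    line = calibrate_single_roi(image, roi, f)
    assert line.intercept_b == pytest.approx(b, rel=1e-14)
    assert line.slope_m == pytest.approx(m, rel=1e-14)
    abmd = apply_calibration(image, line, fg)
    err = np.abs(abmd[fg] - truth.true_bmd_map[fg])
    assert err.max() < 1e-12
    # mapped ROI mean equals the sidecar mean exactly (by construction)
    assert float(abmd[fg].mean()) == pytest.approx(roi.mean_abmd, abs=1e-13)
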