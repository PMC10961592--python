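"""Calibration, detection limits, QC and matrix-effect arithmetic."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdpkpd import (CalibrationPoint, detection_limits, fit_calibration,
                    invert_calibration, matrix_effect, precision_accuracy,
                    qc_levels)
from mdpkpd.calibration import qc_report
from mdpkpd.errors import (CalibrationUnderdeterminedError, InvalidSlopeError,
                           UndefinedRsdError)


def _points(pairs):
    return [CalibrationPoint(c, a) for c, a in pairs]


class TestFitCalibration:
    def test_perfect_line(self):
        curve = fit_calibration(_points([(1, 10), (2, 20), (4, 40)]))
        r = curve.ranges[0]
        assert r.slope == pytest.approx(10.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        # closed-form OLS of {(1,11),(2,19),(3,31),(4,39)}:
        # Sxy/Sxx = 48/5 = 9.6, intercept = 25 - 9.6*2.5 = 1.0,
        # R^2 = 1 - 3.2/464
        curve = fit_calibration(_points([(1, 11), (2, 19), (3, 31), (4, 39)]))
        r = curve.ranges[0]
        assert r.slope == pytest.approx(9.6)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0 - 3.2 / 464.0)

    def test_dual_range_layout(self):
        # two overlapping ranges as used for schisandrol A (1-100, 10-1000)
        low = [(c, 63.0 * c - 60.0) for c in (1, 2, 5, 10, 50, 100)]
        high = [(c, 63.0 * c + 140.0) for c in (10, 100, 250, 500, 1000)]
        curve = fit_calibration(_points(low + high),
                                [(1.0, 100.0), (10.0, 1000.0)])
        assert [(r.conc_low, r.conc_high) for r in curve.ranges] \
            == [(1.0, 100.0), (10.0, 1000.0)]
        assert all(r.slope > 0 for r in curve.ranges)

    def test_underdetermined_range_raises(self):
        with pytest.raises(CalibrationUnderdeterminedError):
            fit_calibration(_points([(1, 10), (2, 20)]))

    @settings(derandomize=True, max_examples=30)
    @given(slope=st.floats(0.5, 500), intercept=st.floats(-50, 50),
           noise=st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_ols_residuals_orthogonal_to_design(self, slope, intercept, noise):
        conc = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
        area = slope * conc + intercept + np.array(noise)
        curve = fit_calibration([CalibrationPoint(c, a)
                                 for c, a in zip(conc, area)])
        r = curve.ranges[0]
        resid = area - r.predict_area(conc)
        scale = max(np.abs(area).max(), 1.0)
        assert abs(resid.sum()) < 1e-9 * scale
        assert abs((conc * resid).sum()) < 1e-9 * scale * conc.max()


class TestInvertCalibration:
    def test_inverse_of_line(self):
        curve = fit_calibration(_points([(1, 10), (50, 500), (100, 1000)]),
                                [(1.0, 100.0)])
        out = invert_calibration(curve, 50.0)
        assert out.value == pytest.approx(5.0)
        assert not out.clamped

    def test_area_at_intercept_is_zero_and_flagged(self):
        curve = fit_calibration(_points([(1, 15), (50, 505), (100, 1005)]),
                                [(1.0, 100.0)])
        out = invert_calibration(curve, curve.ranges[0].intercept)
        assert out.value == pytest.approx(0.0, abs=1e-12)
        assert out.below_loq

    def test_overlap_resolves_to_lower_range(self):
        low = [(c, 10.0 * c) for c in (1, 2, 5, 10, 50, 100)]
        high = [(c, 10.0 * c) for c in (10, 100, 250, 500, 1000)]
        curve = fit_calibration(_points(low + high),
                                [(1.0, 100.0), (10.0, 1000.0)])
        out = invert_calibration(curve, 500.0)  # 50 ng/mL: inside both ranges
        assert out.range_index == 0
        assert out.overlap

    @settings(derandomize=True, max_examples=30)
    @given(conc=st.floats(1.5, 95.0))
    def test_roundtrip_identity_in_range(self, conc):
        curve = fit_calibration(_points([(1, 17), (50, 710), (100, 1400)]),
                                [(1.0, 100.0)])
        area = float(curve.ranges[0].predict_area(conc))
        out = invert_calibration(curve, area)
        assert out.value == pytest.approx(conc, rel=1e-9)


class TestDetectionLimits:
    def test_worked_example(self):
        assert detection_limits(10.0, 1.0) == pytest.approx((0.3, 1.0))

    def test_noiseless_limit(self):
        assert detection_limits(10.0, 0.0) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(slope=st.floats(0.1, 1e4), noise=st.floats(1e-6, 1e3),
           c=st.floats(0.1, 100))
    def test_homogeneity(self, slope, noise, c):
        lod, loq = detection_limits(slope, noise)
        lod_c, loq_c = detection_limits(slope, c * noise)
        assert lod_c == pytest.approx(c * lod, rel=1e-12)
        assert loq_c == pytest.approx(c * loq, rel=1e-12)
        lod_s, _ = detection_limits(c * slope, noise)
        assert lod_s == pytest.approx(lod / c, rel=1e-12)

    def test_invalid_slope(self):
        with pytest.raises(InvalidSlopeError):
            detection_limits(0.0, 1.0)


class TestQcLevels:
    @pytest.mark.parametrize("lloq, uloq, expected, flagged", [
        (1.0, 100.0, (3.0, 40.0, 80.0), False),
        (0.1, 50.0, (0.3, 20.0, 40.0), False),
        (10.0, 40.0, (30.0, 16.0, 32.0), True),
    ])
    def test_levels(self, lloq, uloq, expected, flagged):
        levels, overlap = qc_levels(lloq, uloq)
        assert levels == pytest.approx(expected)
        assert overlap is flagged


class TestPrecisionAccuracy:
    @pytest.mark.parametrize("measured, nominal, rsd, re", [
        ((9, 10, 11), 10.0, 10.0, 0.0),
        ((10, 10, 10), 8.0, 0.0, 25.0),
        ((8, 8, 8), 10.0, 0.0, -20.0),
    ])
    def test_worked_examples(self, measured, nominal, rsd, re):
        got_rsd, got_re = precision_accuracy(measured, nominal)
        assert got_rsd == pytest.approx(rsd)
        assert got_re == pytest.approx(re)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 1e4))
    def test_rsd_scale_invariant(self, scale):
        base = np.array([8.0, 9.5, 10.0, 11.5])
        rsd1, _ = precision_accuracy(base, 10.0)
        rsd2, _ = precision_accuracy(base * scale, 10.0 * scale)
        assert rsd2 == pytest.approx(rsd1, rel=1e-9)

    def test_zero_mean_raises(self):
        with pytest.raises(UndefinedRsdError):
            precision_accuracy([0.0, 0.0, 0.0], 10.0)


class TestMatrixEffect:
    def test_ratio_of_constants(self):
        me, _ = matrix_effect([95, 95, 95], [100, 100, 100])
        assert me == pytest.approx(95.0)

    def test_identity(self):
        me, sd = matrix_effect([70, 80, 90], [70, 80, 90])
        assert me == pytest.approx(100.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_typical_dialysate_suppression(self):
        # mean ratio near 98.6% sits inside the routinely acceptable
        # 85-115% bioanalytical window
        me, _ = matrix_effect([98.0, 98.6, 99.2], [99.4, 100.0, 100.6])
        assert me == pytest.approx(98.6, rel=1e-3)
        assert 85.0 < me < 115.0


def test_qc_report_aggregates_by_level_and_day():
    import pandas as pd
    df = pd.DataFrame({
        "analyte": ["a"] * 6, "level": ["low"] * 3 + ["high"] * 3,
        "day": [1] * 6, "nominal_conc_ng_ml": [3.0] * 3 + [80.0] * 3,
        "measured_conc_ng_ml": [2.7, 3.0, 3.3, 80.0, 80.0, 80.0],
    })
    rep = qc_report(df)
    assert len(rep) == 2
    low = rep[rep["level"] == "low"].iloc[0]
    assert low["re_percent"] == pytest.approx(0.0)
    assert low["rsd_percent"] == pytest.approx(10.0)
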