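import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agiwear.qc import (QcRuleSet, acc_magnitude, acc_window_series,
                        hr_window_verdict, impute_hr_window, st_window_verdict)
from agiwear.streams import FeatureWindow


def make_window(values, rate, modality="hr"):
    values = np.asarray(values, dtype=float)
    return FeatureWindow(survey_id="s", patient_id="P", modality=modality,
                         t_center=180.0, sampling_rate=rate,
                         times=np.arange(values.shape[0]) / rate,
                         values=values)


class TestAccMagnitude:
    @pytest.mark.parametrize("xyz,expected", [
        ((1.0, 0.0, 0.0), 1.0),
        ((0.6, 0.8, 0.0), 1.0),
        ((1.0, 2.0, 2.0), 3.0),
    ])
    def test_pythagorean_fixtures(self, xyz, expected):
        assert acc_magnitude(*xyz) == pytest.approx(expected, abs=1e-15)

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError):
            acc_magnitude(np.inf, 0.0, 0.0)

    def test_nan_propagates_as_missing(self):
        out = acc_magnitude(np.array([1.0, np.nan]), np.zeros(2), np.zeros(2))
        assert out[0] == 1.0 and np.isnan(out[1])


class TestHrImputation:
    def test_short_gap_filled_with_rolling_median(self):
        # 0.5 Hz: one missing sample, gap 2 s < 10 s.  The centered 10 s
        # window around slot 2 holds valid values {1, 2, 4, 5}: median 3.
        w = make_window([1, 2, np.nan, 4, 5, 6, 7], rate=0.5)
        out = impute_hr_window(w)
        assert out.values[2] == pytest.approx(3.0)
        assert np.array_equal(out.values[[0, 1, 3, 4, 5, 6]],
                              [1, 2, 4, 5, 6, 7])

    def test_long_gap_filled_with_cubic_spline_exact_on_cubic(self):
        # interior gap of 12 s (6 samples at 0.5 Hz) >= rolling window length
        idx = np.arange(40, dtype=float)
        poly = 0.01 * idx**3 - 0.3 * idx**2 + 2.0 * idx + 50.0
        vals = poly.copy()
        vals[15:21] = np.nan
        out = impute_hr_window(make_window(vals, rate=0.5))
        assert np.allclose(out.values[15:21], poly[15:21], atol=1e-8)

    def test_trailing_gap_stays_missing(self):
        vals = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan])
        # gap runs to the window end: no surrounding data on the right,
        # so neither median fill nor spline extrapolation applies
        out = impute_hr_window(make_window(vals, rate=0.5))
        assert np.isnan(out.values[3:]).all()

    def test_imputation_never_alters_valid_samples(self, rng):
        vals = rng.normal(70, 5, 180)
        vals[rng.choice(180, 40, replace=False)] = np.nan
        w = make_window(vals, rate=0.5)
        out = impute_hr_window(w)
        valid = np.isfinite(vals)
        assert np.array_equal(out.values[valid], vals[valid])

    def test_accounting_identity(self, rng):
        vals = rng.normal(70, 5, 180)
        vals[rng.choice(180, 60, replace=False)] = np.nan
        out = impute_hr_window(make_window(vals, rate=0.5))
        n_valid = int(np.isfinite(vals).sum())
        n_imputed = int((np.isfinite(out.values) & ~np.isfinite(vals)).sum())
        n_still = int((~np.isfinite(out.values)).sum())
        assert n_valid + n_imputed + n_still == 180


class TestVerdicts:
    def test_hr_drop_at_exactly_half_missing(self):
        vals = np.full(180, 70.0)
        vals[:90] = np.nan
        assert hr_window_verdict(make_window(vals, 0.5)).quality_verdict == "dropped"

    def test_hr_kept_just_below_half(self):
        vals = np.full(180, 70.0)
        vals[:89] = np.nan
        assert hr_window_verdict(make_window(vals, 0.5)).quality_verdict == "kept"

    def test_hr_verdict_uses_pre_imputation_missingness(self):
        vals = np.full(180, 70.0)
        vals[:90] = np.nan
        w = impute_hr_window(make_window(vals, 0.5))
        # imputation fills some slots, but the drop rule still sees >= 50%
        assert hr_window_verdict(w).quality_verdict == "dropped"

    def test_st_drop_at_exactly_half_valid(self):
        vals = np.full(360, 33.0)
        vals[:180] = 45.0  # out of range
        assert st_window_verdict(make_window(vals, 1.0, "st")).quality_verdict == "dropped"

    def test_st_kept_just_above_half_valid(self):
        vals = np.full(360, 33.0)
        vals[:179] = 45.0
        assert st_window_verdict(make_window(vals, 1.0, "st")).quality_verdict == "kept"

    def test_st_range_boundaries_inclusive(self):
        ok = np.full(360, 20.0)
        ok[::2] = 40.0
        assert st_window_verdict(make_window(ok, 1.0, "st")).quality_verdict == "kept"
        bad = np.full(360, 40.001)
        assert st_window_verdict(make_window(bad, 1.0, "st")).quality_verdict == "dropped"

    @settings(max_examples=25, deadline=None)
    @given(n_missing=st.integers(0, 180), extra=st.integers(0, 30))
    def test_hr_verdict_monotone_in_missingness(self, n_missing, extra):
        vals = np.full(180, 70.0)
        vals[:n_missing] = np.nan
        v1 = hr_window_verdict(make_window(vals, 0.5)).quality_verdict
        vals2 = vals.copy()
        vals2[:min(180, n_missing + extra)] = np.nan
        v2 = hr_window_verdict(make_window(vals2, 0.5)).quality_verdict
        assert not (v1 == "dropped" and v2 == "kept")


class TestAccWindow:
    def test_at_rest_gives_unit_magnitude(self):
        xyz = np.zeros((100, 3))
        xyz[:, 2] = 1.0
        out = acc_window_series(make_window(xyz, 32.0, "acc"))
        assert out.quality_verdict == "kept"
        assert np.allclose(out.values, 1.0)

    def test_shaking_raises_magnitude_sd(self):
        xyz = np.zeros((100, 3))
        xyz[:, 2] = 1.0
        xyz[::2, 0] = 0.5
        xyz[1::2, 0] = -0.5
        out = acc_window_series(make_window(xyz, 32.0, "acc"))
        assert np.std(out.values) > 0

    def test_empty_window_dropped_no_data(self):
        xyz = np.full((100, 3), np.nan)
        out = acc_window_series(make_window(xyz, 32.0, "acc"))
        assert out.quality_verdict == "dropped"
        assert out.drop_reason == "no_data"
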