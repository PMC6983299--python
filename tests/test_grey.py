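import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vegtrend as vt
from vegtrend.grey import (
    ago,
    class_ratio_check,
    diagnose,
    inverse_ago,
    percent_change,
    posterior_ratio,
    relational_grade,
    residual_table,
)

from conftest import make_series

# five (measured, predicted) pairs of the worked accuracy example
ACCURACY_ROWS = [
    (1981, 0.2876, 0.2854, -0.0022, 99.24),
    (1990, 0.3134, 0.3030, -0.0104, 96.68),
    (2000, 0.2996, 0.3010, 0.0014, 99.53),
    (2010, 0.3092, 0.3183, 0.0091, 97.06),
    (2018, 0.3174, 0.3209, 0.0035, 98.90),
]


class TestAGO:
    def test_small_example(self):
        np.testing.assert_array_equal(ago([1, 2, 3]), [1, 3, 6])

    def test_single_element_identity(self):
        np.testing.assert_array_equal(ago([4.2]), [4.2])
        np.testing.assert_array_equal(inverse_ago([4.2]), [4.2])

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False, width=32), min_size=1,
                    max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_round_trip(self, values):
        x = np.array(values)
        np.testing.assert_allclose(inverse_ago(ago(x)), x, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(vt.ValidationError, match="empty"):
            ago([])


class TestFitGM11:
    def geometric(self, q=1.01, A=0.3, n=20):
        return make_series(A * q ** np.arange(n))

    def test_geometric_series_alpha_near_log_ratio(self):
        m = vt.fit_gm11(self.geometric())
        # least squares on the trapezoid mean sequence gives the bilinear
        # approximant -2(q-1)/(q+1) of -ln q
        assert m.alpha == pytest.approx(-2 * 0.01 / 2.01, abs=1e-12)
        assert m.alpha == pytest.approx(-np.log(1.01), rel=1e-4)

    def test_geometric_series_reproduced(self):
        s = self.geometric()
        m = vt.fit_gm11(s)
        f = vt.forecast(m, 0)
        np.testing.assert_allclose(f.values, s.values, rtol=2e-5)

    def test_geometric_forecast_continues_the_law(self):
        m = vt.fit_gm11(self.geometric())
        f = vt.forecast(m, 3).values
        ratios = f[-3:] / f[-4:-1]
        np.testing.assert_allclose(ratios, 1.01, rtol=1e-6)

    def test_constant_series_flat_limit(self):
        s = make_series([0.4] * 12)
        m = vt.fit_gm11(s, check_admissibility=False)
        assert m.alpha == pytest.approx(0.0, abs=1e-10)
        assert m.beta == pytest.approx(0.4, abs=1e-10)
        np.testing.assert_allclose(vt.forecast(m, 4).values, 0.4, atol=1e-8)

    def test_scale_equivariance(self, rng):
        x = 0.3 + 0.01 * rng.random(15)
        a = vt.fit_gm11(make_series(x))
        b = vt.fit_gm11(make_series(10.0 * x))
        assert b.alpha == pytest.approx(a.alpha, abs=1e-12)
        assert b.beta == pytest.approx(10.0 * a.beta, rel=1e-12)
        np.testing.assert_allclose(
            vt.forecast(b, 2).values, 10.0 * vt.forecast(a, 2).values, rtol=1e-10
        )

    def test_closed_form_constants_sum_to_first_value(self):
        m = vt.fit_gm11(self.geometric())
        assert m.c_exp + m.c_const == pytest.approx(m.x0_1, rel=1e-9)

    def test_nonpositive_or_short_rejected(self):
        with pytest.raises(vt.ValidationError, match="positive"):
            vt.fit_gm11(make_series([0.3, -0.1, 0.2, 0.4]))
        with pytest.raises(vt.ValidationError, match="n >= 4"):
            vt.fit_gm11(make_series([0.3, 0.4, 0.5]))

    def test_class_ratio_warning(self):
        # wildly varying series violates the admissibility band
        x = np.array([0.3, 3.0, 0.2, 5.0, 0.1, 4.0])
        with pytest.warns(UserWarning, match="class-ratio"):
            vt.fit_gm11(make_series(x))
        assert class_ratio_check(np.array([0.3, 0.301, 0.302, 0.303]))

    def test_horizon_zero_in_sample_only(self):
        s = self.geometric(n=10)
        f = vt.forecast(vt.fit_gm11(s), 0)
        assert len(f) == 10
        assert np.array_equal(f.years, s.years)
        assert f.values[0] == s.values[0]

    def test_rolling_refit_tracks_regime_change(self):
        # rolling one-step forecasts adapt to a growth-rate change
        x = np.concatenate([0.3 * 1.01 ** np.arange(12),
                            0.3 * 1.01**11 * 1.03 ** np.arange(1, 9)])
        s = make_series(x)
        roll = vt.rolling_gm11(s, window=6)
        assert roll.years[0] == s.years[6]
        # late predictions reflect the ~3% growth, not the initial 1%
        assert roll.values[-1] / x[-2] == pytest.approx(1.03, abs=5e-3)


class TestDiagnostics:
    def test_accuracy_rows_reproduced(self):
        measured = vt.AnnualSeries(np.arange(5) + 1981,
                                   [r[1] for r in ACCURACY_ROWS])
        predicted = vt.AnnualSeries(np.arange(5) + 1981,
                                    [r[2] for r in ACCURACY_ROWS])
        table = residual_table(measured, predicted)
        for row, (_, m, p, diff, sim) in zip(table.itertuples(), ACCURACY_ROWS):
            assert row.difference == pytest.approx(p - m, abs=1e-12)
            assert abs(row.difference) == pytest.approx(abs(diff), abs=1e-12)
            assert row.similarity_pct == pytest.approx(sim, abs=0.011)

    def test_identical_series_full_similarity(self):
        s = make_series([0.3, 0.31, 0.32, 0.33])
        table = residual_table(s, s)
        assert (table["difference"] == 0).all()
        assert (table["similarity_pct"] == 100.0).all()

    def test_year_mismatch_rejected(self):
        a = make_series([0.3, 0.31], start_year=1981)
        b = make_series([0.3, 0.31], start_year=1982)
        with pytest.raises(vt.ValidationError, match="different years"):
            residual_table(a, b)

    def test_relational_grade_hand_computed(self):
        measured = np.array([r[1] for r in ACCURACY_ROWS])
        predicted = np.array([r[2] for r in ACCURACY_ROWS])
        xi, R = relational_grade(measured, predicted, rho=0.5)
        np.testing.assert_allclose(
            xi, [0.8919, 0.4231, 1.0000, 0.4615, 0.7586], atol=1e-4
        )
        assert R == pytest.approx(0.7070, abs=1e-4)
        assert R > 0.5

    def test_relational_grade_identical_series(self):
        x = np.array([0.3, 0.31, 0.32])
        xi, R = relational_grade(x, x)
        np.testing.assert_array_equal(xi, 1.0)
        assert R == 1.0

    def test_relational_grade_constant_gap(self):
        x = np.arange(5.0)
        xi, R = relational_grade(x, x + 0.2)
        assert np.allclose(xi, xi[0])
        assert R == pytest.approx(xi[0])

    def test_posterior_ratio_extremes(self, rng):
        x = rng.normal(10, 1, 30)
        c, label = posterior_ratio(x, x + 0.5)  # constant offset: sd resid 0
        assert c == 0.0 and label == "excellent"
        c, label = posterior_ratio(x, np.full(30, x.mean()))
        assert c == pytest.approx(1.0, abs=0.01)
        assert label == "unqualified"

    def test_posterior_ratio_near_one_without_signal(self, rng):
        # GM(1,1) fitted to positive white noise explains almost nothing
        cs = []
        for _ in range(50):
            x = rng.normal(10, 1, 20)
            x = np.abs(x)
            s = make_series(x)
            m = vt.fit_gm11(s, check_admissibility=False)
            f = vt.forecast(m, 0)
            cs.append(posterior_ratio(s.values, f.values)[0])
        assert 0.8 < np.median(cs) < 1.2

    def test_percent_change(self):
        assert percent_change(0.3174, 0.3174 + 0.0196) == pytest.approx(
            6.18, abs=0.005
        )
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(100.0, 150.0) == 50.0
        with pytest.raises(vt.ValidationError, match="baseline"):
            percent_change(0.0, 1.0)

    def test_diagnose_bundle(self):
        measured = make_series([0.30, 0.31, 0.32, 0.33, 0.34])
        predicted = make_series([0.30, 0.312, 0.318, 0.331, 0.34])
        d = diagnose(measured, predicted)
        assert d.pass_50pct == (d.relational_grade > 0.5)
        assert 0 < d.relational_grade <= 1
        assert d.posterior_grade == "excellent"
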