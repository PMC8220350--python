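"""Survey-table reading and the linear prevalence-temperature fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raynaud import (
    CalendarWindow,
    LinearPrevalenceFit,
    StudyRecord,
    TemperatureGrid,
    assign_winter_temps,
    fit_prevalence,
    latitude_fallback_fit,
    predict_prevalence,
    read_study_table,
    zero_crossing,
)
from raynaud.exceptions import (
    DegenerateDesignError,
    LinkageError,
    NoCrossingError,
    ValidationError,
)

from conftest import make_grid

WINTER = CalendarWindow((11, 1), (3, 31))


def records_from(temps, prevalences, sizes=None):
    sizes = sizes if sizes is not None else [100] * len(temps)
    return [
        StudyRecord(
            study=f"s{i}",
            year=1999,
            country="X",
            city=f"c{i}",
            latitude=45.0,
            longitude=5.0,
            sample_size=int(n),
            prevalence=float(p),
            winter_temp=float(t),
        )
        for i, (t, p, n) in enumerate(zip(temps, prevalences, sizes))
    ]


def ols_oracle(x, y, w=None):
    """Closed-form (weighted) normal equations, independent of the fit path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ (X * w[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ beta
    dof = len(x) - 2
    scale = (w * resid**2).sum() / dof if dof > 0 else np.nan
    cov = scale * np.linalg.inv(XtWX)
    return beta, np.sqrt(np.diag(cov))


class TestReadStudyTable:
    def test_bundled_table_has_twenty_studies(self):
        records = read_study_table()
        assert len(records) == 20
        first = records[0]
        assert (first.study, first.year, first.city) == ("Brand", 1997, "Boston")
        assert first.latitude == pytest.approx(42.36)
        assert first.sample_size == 4182
        assert first.prevalence == pytest.approx(7.20)

    def test_copenhagen_prevalence_parsed(self):
        records = {r.city: r for r in read_study_table()}
        olsen = records["Copenhagen"]
        assert olsen.study == "Olsen"
        assert olsen.prevalence == pytest.approx(15.51)
        assert olsen.sample_size == 67

    def test_gazetteer_fills_longitudes(self):
        records = {r.city: r for r in read_study_table()}
        assert records["Grenoble"].longitude == pytest.approx(5.72)
        assert records["Boston"].longitude == pytest.approx(-71.06)

    def test_explicit_longitude_column_overrides_gazetteer(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "study": ["A"],
                "year": [1999],
                "country": ["FR"],
                "city": ["Grenoble"],
                "latitude": [45.19],
                "longitude": [99.0],
                "sample_size": [100],
                "prevalence": [5.0],
            }
        ).to_csv(path, index=False)
        assert read_study_table(path)[0].longitude == 99.0

    def test_out_of_range_prevalence_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "study": ["A", "B"],
                "year": [1999, 1999],
                "country": ["FR", "FR"],
                "city": ["Grenoble", "Milan"],
                "latitude": [45.19, 45.46],
                "sample_size": [100, 100],
                "prevalence": [5.0, -1.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 1"):
            read_study_table(path)

    def test_unknown_city_without_longitude_raises(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "study": ["A"],
                "year": [1999],
                "country": ["??"],
                "city": ["Atlantis"],
                "latitude": [0.0],
                "sample_size": [100],
                "prevalence": [5.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(LinkageError, match="Atlantis"):
            read_study_table(path)


class TestAssignWinterTemps:
    def test_constant_grid_assigns_constant(self):
        grid = make_grid(fill=5.0)
        records = records_from([np.nan], [5.0])
        out = assign_winter_temps(records, grid, WINTER)
        assert out[0].winter_temp == pytest.approx(5.0)

    def test_uniform_warming_between_years(self):
        """+1 degC/yr uniform trend puts 2 degC between 1997 and 1999 studies."""
        time = pd.date_range("1995-11-01", "1999-03-31", freq="D")
        years = time.year.to_numpy(dtype=float)
        values = np.broadcast_to(
            (years - 1995.0)[:, None, None], (time.size, 2, 2)
        ).copy()
        grid = TemperatureGrid([40.0, 50.0], [0.0, 10.0], time, values)
        recs = records_from([np.nan, np.nan], [5.0, 5.0])
        recs[0].year, recs[1].year = 1997, 1999
        out = assign_winter_temps(recs, grid, WINTER)
        # trend is a step at New Year; the step position is identical in both
        # windows, so the window means differ by exactly the 2-year offset
        assert out[1].winter_temp - out[0].winter_temp == pytest.approx(2.0)

    def test_gradient_grid_reproduces_gradient_at_sites(self):
        lat = np.arange(35.0, 56.0, 1.0)
        lon = np.array([0.0, 10.0])
        time = WINTER.dates(1999)
        base = (30.0 - 0.5 * lat)[:, None]
        values = np.broadcast_to(base, (time.size, lat.size, lon.size)).copy()
        grid = TemperatureGrid(lat, lon, time, values)
        recs = records_from([np.nan, np.nan, np.nan], [5, 5, 5])
        for r, la in zip(recs, (37.0, 45.0, 53.0)):
            r.latitude = la
        out = assign_winter_temps(recs, grid, WINTER)
        for r in out:
            assert r.winter_temp == pytest.approx(30.0 - 0.5 * r.latitude)

    def test_errors_carry_study_label(self):
        grid = make_grid(start="1999-01-01", end="1999-03-31")  # November missing
        with pytest.raises(Exception, match="s0"):
            assign_winter_temps(records_from([np.nan], [5.0]), grid, WINTER)


class TestFitPrevalence:
    def test_exact_line_through_collinear_points(self):
        recs = records_from([0, 5, 10], [10, 7.5, 5])
        fit = fit_prevalence(recs)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-7)

    def test_two_point_line_and_zero_crossing(self):
        fit = fit_prevalence(records_from([0, 13], [6.5, 0]))
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert zero_crossing(fit) == pytest.approx(13.0, abs=1e-10)

    def test_recovers_simulated_slope_within_two_se(self):
        rng = np.random.default_rng(1)
        temps = rng.uniform(-10, 10, size=20)
        prev = np.clip(10.0 - 0.5 * temps + rng.normal(0, 1, 20), 0, 100)
        fit = fit_prevalence(records_from(temps, prev))
        assert abs(fit.slope - (-0.5)) < 2 * fit.slope_se
        # frozen closed-form oracle agrees
        beta, se = ols_oracle(temps, prev)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(se[1], rel=1e-10)

    def test_sample_size_weighting_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(2)
        temps = rng.uniform(-5, 10, 15)
        prev = np.clip(8 - 0.5 * temps + rng.normal(0, 1, 15), 0, 100)
        sizes = rng.integers(67, 4182, 15)
        fit = fit_prevalence(records_from(temps, prev, sizes), weighting="sample_size")
        beta, se = ols_oracle(temps, prev, w=sizes)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.weighting == "sample_size"

    def test_identical_temperatures_are_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_prevalence(records_from([5, 5, 5], [1, 2, 3]))

    def test_refit_on_own_predictions_is_idempotent(self):
        rng = np.random.default_rng(3)
        temps = rng.uniform(-10, 10, 12)
        prev = np.clip(9 - 0.4 * temps + rng.normal(0, 1, 12), 0, 100)
        fit = fit_prevalence(records_from(temps, prev))
        refit = fit_prevalence(
            records_from(temps, fit.intercept + fit.slope * temps)
        )
        assert refit.slope == pytest.approx(fit.slope, abs=1e-10)
        assert refit.intercept == pytest.approx(fit.intercept, abs=1e-10)

    @given(shift=st.floats(-20, 20))
    @settings(max_examples=25, deadline=None)
    def test_temperature_shift_property(self, shift):
        """Adding c to all temps: slope unchanged, intercept drops by slope*c."""
        temps = np.array([-8.0, -3.0, 1.0, 4.0, 9.0])
        prev = np.array([11.0, 8.2, 6.1, 4.9, 2.0])
        f0 = fit_prevalence(records_from(temps, prev))
        f1 = fit_prevalence(records_from(temps + shift, prev))
        assert f1.slope == pytest.approx(f0.slope, abs=1e-8)
        assert f1.intercept == pytest.approx(f0.intercept - f0.slope * shift, abs=1e-7)

    def test_json_round_trip(self, tmp_path):
        fit = fit_prevalence(records_from([0, 5, 10], [10, 7.5, 5]))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = LinearPrevalenceFit.from_json(path)
        assert back == fit


class TestPredictAndCrossing:
    @pytest.mark.parametrize(
        "temp,expected", [(0.0, 10.0), (4.0, 8.0), (25.0, 0.0), (-200.0, 100.0)]
    )
    def test_prediction_is_clamped_line(self, temp, expected):
        fit = LinearPrevalenceFit(-0.5, 10.0, 0.1, 0.1, 0.5, 20, 0.001)
        assert predict_prevalence(fit, temp) == pytest.approx(expected)

    @given(t1=st.floats(-50, 50), t2=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_and_bounded(self, t1, t2):
        fit = LinearPrevalenceFit(-0.5, 10.0, 0.1, 0.1, 0.5, 20, 0.001)
        p1, p2 = predict_prevalence(fit, t1), predict_prevalence(fit, t2)
        assert 0.0 <= p1 <= 100.0
        if t1 <= t2:
            assert p1 >= p2

    def test_zero_crossing_values(self):
        fit = LinearPrevalenceFit(-0.5, 6.5, 0.1, 0.1, 0.5, 20, 0.001)
        assert zero_crossing(fit) == pytest.approx(13.0)
        fit = LinearPrevalenceFit(-1.0, 0.0, 0.1, 0.1, 0.5, 20, 0.001)
        assert zero_crossing(fit) == pytest.approx(0.0)

    def test_positive_slope_has_no_crossing(self):
        fit = LinearPrevalenceFit(0.1, 5.0, 0.1, 0.1, 0.5, 20, 0.5)
        with pytest.raises(NoCrossingError):
            zero_crossing(fit)


def test_latitude_fallback_regression():
    """Sensitivity path: prevalence against |latitude| instead of temperature."""
    records = read_study_table()
    fit = latitude_fallback_fit(records)
    # published surveys show prevalence increasing toward the poles
    assert fit.slope > 0
    lats = np.abs([r.latitude for r in records])
    prevs = [r.prevalence for r in records]
    beta, _ = ols_oracle(lats, prevs)
    assert fit.slope == pytest.approx(beta[1], rel=1e-10)
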