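"""Domain types, I/O round trips and curve utilities."""

import numpy as np
import pandas as pd
import pytest

import glucoroute as gr
from glucoroute.data_model import (
    SamplingSeries,
    UnitError,
    ValidationError,
    auc,
    read_session,
    smooth_and_differentiate,
    write_session,
)


def series(times, values, analyte="glucose", unit="mmol/l"):
    return SamplingSeries(analyte, unit, np.asarray(times, float),
                          np.asarray(values, float))


class TestSessionIO:
    def test_round_trip_is_lossless(self, oral_session, tmp_path):
        session, _ = oral_session
        p1 = tmp_path / "s1.csv"
        write_session(session, p1)
        back = read_session(p1)
        p2 = tmp_path / "s2.csv"
        write_session(back, p2)
        assert p1.read_text() == p2.read_text()
        assert p1.with_suffix(".yaml").read_text() == p2.with_suffix(".yaml").read_text()
        np.testing.assert_array_equal(back.glucose.values, session.glucose.values)
        np.testing.assert_array_equal(back.tracers["C13"].ttr,
                                      session.tracers["C13"].ttr)

    def test_glucose_grid_has_37_points_on_test_window(self, oral_session, tmp_path):
        session, _ = oral_session
        path = tmp_path / "s.csv"
        write_session(session, path)
        back = read_session(path)
        on_test = (back.glucose.times >= 0) & (back.glucose.times <= 360)
        assert on_test.sum() == 37
        assert np.allclose(np.diff(back.glucose.times[on_test]), 10.0)

    def test_duplicated_time_row_rejected(self, oral_session, tmp_path):
        session, _ = oral_session
        path = tmp_path / "s.csv"
        write_session(session, path)
        df = pd.read_csv(path)
        dup = df[df["analyte"] == "glucose"].iloc[[5]]
        pd.concat([df, dup]).sort_values(["analyte", "time_min"]).to_csv(
            path, index=False)
        with pytest.raises(ValidationError, match="non-monotone"):
            read_session(path)

    def test_unit_mismatch_names_the_analyte(self, oral_session, tmp_path):
        session, _ = oral_session
        path = tmp_path / "s.csv"
        write_session(session, path)
        df = pd.read_csv(path)
        df.loc[df["analyte"] == "insulin", "unit"] = "mU/l"
        df.to_csv(path, index=False)
        with pytest.raises(UnitError, match="insulin"):
            read_session(path)

    def test_missing_basal_samples_rejected(self, oral_session, tmp_path):
        session, _ = oral_session
        path = tmp_path / "s.csv"
        write_session(session, path)
        df = pd.read_csv(path)
        df = df[~((df["analyte"] == "cpeptide") & (df["time_min"] <= 0))]
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_session(path)


class TestAuc:
    @pytest.mark.parametrize("times,values,window,expected", [
        (np.arange(0, 101, 10), np.full(11, 5.0), (0, 100), 500.0),
        ([0, 10, 20], [0, 10, 0], (0, 20), 100.0),  # triangle
        ([0, 50, 100], [2, 2, 2], (25, 75), 100.0),  # interpolated endpoints
    ])
    def test_trapezoid_values(self, times, values, window, expected):
        assert auc(series(times, values), window) == pytest.approx(expected)

    def test_incremental_of_constant_at_basal_is_zero(self):
        s = series([-20, -10, 0, 10, 20], [5, 5, 5, 5, 5])
        assert auc(s, (0, 20), incremental=True) == pytest.approx(0.0)

    def test_incremental_may_be_negative_unless_floored(self):
        s = series([-10, 0, 10, 20], [5, 5, 4, 4])
        assert auc(s, (0, 20), incremental=True) < 0
        assert auc(s, (0, 20), incremental=True, floor=True) == 0.0

    def test_additive_over_adjacent_windows(self, oral_session):
        session, _ = oral_session
        g = session.glucose
        whole = auc(g, (0, 360))
        parts = auc(g, (0, 117.5)) + auc(g, (117.5, 360))
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            auc(series([0, 10], [1, 1]), (50, 50))


class TestSmoothing:
    def test_linear_series_has_constant_derivative(self):
        t = np.arange(0, 361, 10.0)
        s = series(t, 4 + 0.01 * t)
        _, _, deriv = smooth_and_differentiate(s, lam=0.0)
        np.testing.assert_allclose(deriv, 0.01, atol=1e-10)

    def test_sine_derivative_matches_closed_form(self):
        # amplitude 1, period 240 min, sampled every 10 min
        omega = 2 * np.pi / 240.0
        t = np.arange(0, 361, 10.0)
        s = series(t, 2 + np.sin(omega * t), analyte="toy")
        grid, _, deriv = smooth_and_differentiate(s, lam=0.0)
        true = omega * np.cos(omega * grid)
        interior = (grid > 20) & (grid < 340)
        assert np.abs(deriv - true)[interior].max() < 0.02 * omega

    def test_constant_series_derivative_zero(self):
        s = series(np.arange(0, 61, 10.0), np.full(7, 3.3))
        _, _, deriv = smooth_and_differentiate(s, lam=5.0)
        np.testing.assert_allclose(deriv, 0.0, atol=1e-10)

    def test_interpolating_spline_passes_through_data(self, oral_session):
        session, _ = oral_session
        g = session.glucose
        grid, vals, _ = smooth_and_differentiate(g, lam=0.0)
        at_samples = np.interp(g.times, grid, vals)
        np.testing.assert_allclose(at_samples, g.values, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            smooth_and_differentiate(series([0, 10, 20, 30], [1, 2, 3, 4]))


class TestInfusionSchedule:
    def test_oral_and_dextrose_are_mutually_exclusive(self):
        with pytest.raises(ValidationError):
            gr.InfusionSchedule(oral_loads=((0.0, 25.0, 0.9),),
                                dextrose_times=np.array([0.0]),
                                dextrose_rates=np.array([10.0]))

    def test_default_drink_enrichments(self):
        inf = gr.InfusionSchedule.default_oral()
        assert inf.drink_enrichment(60) == pytest.approx(0.9 / 25)
        assert inf.drink_enrichment(130) == pytest.approx(0.9 / 75)
        assert inf.drink_enrichment(300) == pytest.approx(0.9 / 100)

    def test_igivi_label_rate_includes_enriched_dextrose(self):
        inf = gr.InfusionSchedule(dextrose_times=np.array([0.0, 10.0]),
                                  dextrose_rates=np.array([20.0, 40.0]))
        assert inf.label_infusion_rate(5.0) == pytest.approx(0.22 + 0.025 * 20)
        assert inf.label_infusion_rate(15.0) == pytest.approx(0.22 + 0.025 * 40)
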