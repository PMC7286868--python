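"""Metabolite decay fits, Z tests and feature-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from glucoroute.data_model import SamplingSeries, ValidationError
from glucoroute.metabolites import (
    fit_decay,
    heatmap_matrix,
    normalize_beta,
    percent_delta,
    ztest_betas,
)


def decay_series(beta, c0=2.0, t=None, noise=None, rng=None, name="lactate"):
    t = t if t is not None else np.arange(0.0, 361.0, 20.0)
    c = c0 * np.exp(-beta * t)
    if noise and rng is not None:
        c = np.maximum(c * (1 + noise * rng.standard_normal(t.size)), 1e-9)
    return SamplingSeries(name, "mmol/l", t, c)


class TestFitDecay:
    def test_exact_exponential_recovered(self):
        fit = fit_decay(decay_series(0.001, c0=2.0))
        assert fit.beta == pytest.approx(0.001, abs=1e-10)
        assert fit.c0 == pytest.approx(2.0, abs=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_constant_series_beta_zero_within_se(self):
        fit = fit_decay(decay_series(0.0, c0=1.5))
        assert abs(fit.beta) <= max(fit.beta_se, 1e-10)

    def test_matches_loglinear_slope_on_exact_data(self):
        s = decay_series(0.0014)
        fit = fit_decay(s)
        slope = -np.polyfit(s.times, np.log(s.values), 1)[0]
        assert fit.beta == pytest.approx(slope, abs=1e-8)

    def test_noisy_recovery_median_within_10pct(self):
        # generator truth anchored at the intravenous lactate decay rate
        beta_true = 0.0014
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fit = fit_decay(decay_series(beta_true, noise=0.08, rng=rng))
            errs.append(fit.beta)
        assert abs(np.median(errs) - beta_true) < 0.10 * beta_true

    def test_nonpositive_values_rejected(self):
        t = np.arange(0.0, 81.0, 20.0)
        s = SamplingSeries("x", "mmol/l", t, np.array([1.0, 0.5, 0.0, 0.2, 0.1]))
        with pytest.raises(ValidationError):
            fit_decay(s)

    def test_too_few_points_rejected(self):
        s = SamplingSeries("x", "mmol/l", np.array([0.0, 20, 40.0]),
                           np.array([1.0, 0.9, 0.8]))
        with pytest.raises(ValidationError):
            fit_decay(s)


class TestNormalise:
    def test_division_by_mean_insulin(self):
        fit = fit_decay(decay_series(0.002))
        t = np.arange(-40.0, 361.0, 20.0)
        ins = SamplingSeries("insulin", "pmol/l", t, np.full(t.size, 400.0))
        assert normalize_beta(fit, ins) == pytest.approx(5e-6)

    def test_doubling_insulin_halves_normalised_beta(self):
        fit = fit_decay(decay_series(0.002))
        t = np.arange(-40.0, 361.0, 20.0)
        i1 = SamplingSeries("insulin", "pmol/l", t, np.full(t.size, 200.0))
        i2 = SamplingSeries("insulin", "pmol/l", t, np.full(t.size, 400.0))
        assert normalize_beta(fit, i1) == pytest.approx(2 * normalize_beta(fit, i2))

    def test_equal_raw_beta_higher_insulin_widens_normalised_gap(self):
        fit = fit_decay(decay_series(0.002))
        t = np.arange(-40.0, 361.0, 20.0)
        oral_i = SamplingSeries("insulin", "pmol/l", t, np.full(t.size, 600.0))
        iv_i = SamplingSeries("insulin", "pmol/l", t, np.full(t.size, 300.0))
        assert normalize_beta(fit, iv_i) > normalize_beta(fit, oral_i)


class TestZTest:
    def test_identical_fits_give_zero(self):
        rng = np.random.default_rng(3)
        f = fit_decay(decay_series(0.0014, noise=0.05, rng=rng))
        z, p = ztest_betas(f, f)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_quantile_anchoring_at_nominal_level(self):
        from glucoroute.metabolites import DecayFit
        se = 3e-4
        a = DecayFit(1.0, 0.002 + 1.959963985 * np.sqrt(2) * se, se, (0, 360), 0)
        b = DecayFit(1.0, 0.002, se, (0, 360), 0)
        _, p = ztest_betas(a, b)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_antisymmetric(self):
        rng = np.random.default_rng(4)
        f1 = fit_decay(decay_series(0.001, noise=0.05, rng=rng))
        f2 = fit_decay(decay_series(0.002, noise=0.05, rng=rng))
        assert ztest_betas(f1, f2)[0] == pytest.approx(-ztest_betas(f2, f1)[0])


class TestPercentDelta:
    @pytest.mark.parametrize("start,end,expected", [
        (2.0, 1.5, -25.0),
        (1.0, 1.0, 0.0),
        (2.0, 1.0, -50.0),
    ])
    def test_examples(self, start, end, expected):
        t = np.array([-20.0, 0.0, 180.0, 360.0])
        s = SamplingSeries("x", "mmol/l", t,
                           np.array([start, start, (start + end) / 2, end]))
        assert percent_delta(s) == pytest.approx(expected)


class TestHeatmap:
    def frame(self, values):
        rows = []
        for (met, grp, proc, seg), v in values.items():
            rows.append({"metabolite": met, "group": grp, "procedure": proc,
                         "segment": seg, "value": v})
        return pd.DataFrame(rows)

    def test_uniform_metabolite_z_scores_zero(self):
        cells = {("x", g, p, s): 3.0 for g in ("NGT", "IGT", "T2D")
                 for p in ("oral", "igivi") for s in (1, 2, 3)}
        fm = heatmap_matrix(self.frame(cells), cluster_rows=False)
        assert fm.frame.shape == (1, 18)
        np.testing.assert_allclose(fm.frame.to_numpy(), 0.0)

    def test_two_cell_toy_follows_sd_convention(self):
        cells = {("x", "NGT", "oral", 1): 1.0, ("x", "NGT", "igivi", 1): 3.0}
        fm = heatmap_matrix(self.frame(cells), cluster_rows=False)
        np.testing.assert_allclose(sorted(fm.frame.to_numpy().ravel()),
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        fm_pop = heatmap_matrix(self.frame(cells), convention="population",
                                cluster_rows=False)
        np.testing.assert_allclose(sorted(fm_pop.frame.to_numpy().ravel()),
                                   [-1.0, 1.0])

    def test_rows_are_standardised(self):
        rng = np.random.default_rng(0)
        cells = {}
        for met in ("a", "b", "c", "d"):
            for g in ("NGT", "IGT", "T2D"):
                for p in ("oral", "igivi"):
                    for s in (1, 2, 3):
                        cells[(met, g, p, s)] = float(rng.uniform(0.5, 2.0))
        fm = heatmap_matrix(self.frame(cells))
        vals = fm.frame.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(vals.std(axis=1, ddof=0), np.sqrt(17 / 18),
                                   atol=1e-9)

    def test_significance_filter_drops_rows(self):
        cells = {}
        for met in ("keep", "drop"):
            for g in ("NGT",):
                for p in ("oral", "igivi"):
                    for s in (1, 2, 3):
                        cells[(met, g, p, s)] = 1.0 + (s if met == "keep" else 0)
        fm = heatmap_matrix(self.frame(cells),
                            significant={"keep": True, "drop": False},
                            cluster_rows=False)
        assert list(fm.frame.index) == ["keep"]

    def test_subject_order_invariance(self):
        """Assembly from cell means is invariant to input row order."""
        rng = np.random.default_rng(1)
        cells = {}
        for met in ("a", "b", "c"):
            for g in ("NGT", "IGT"):
                for p in ("oral", "igivi"):
                    for s in (1, 2, 3):
                        cells[(met, g, p, s)] = float(rng.uniform(1, 2))
        df = self.frame(cells)
        fm1 = heatmap_matrix(df)
        fm2 = heatmap_matrix(df.sample(frac=1.0, random_state=7))
        pd.testing.assert_frame_equal(fm1.frame, fm2.frame)
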