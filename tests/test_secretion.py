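"""C-peptide kinetics and ISR deconvolution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import glucoroute as gr
from glucoroute.data_model import SamplingSeries, SEGMENTS
from glucoroute.secretion import (
    CPeptideKinetics,
    cpeptide_from_isr,
    deconvolve_isr,
    population_kinetics,
    total_isr,
)


@pytest.fixture(scope="module")
def kin(subject):
    return population_kinetics(subject)


def staircase_cpeptide(kin, cp_b=1000.0, rng=None, cv=0.0):
    """C-peptide observations generated from a known 20-min ISR staircase."""
    isr_b = kin.basal_isr(cp_b)
    steps = isr_b + np.array([0, 100, 400, 300, 200, 150, 500, 600, 400,
                              300, 250, 200, 700, 800, 600, 400, 300, 200.0])
    edges = np.arange(0.0, 361.0, 20.0)
    grid = np.arange(0.0, 360.5, 1.0)
    idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, 17)
    isr = steps[idx]
    cp = cpeptide_from_isr(isr, kin, 1.0, cp_b)
    t_obs = np.arange(-40.0, 361.0, 20.0)
    obs = np.interp(t_obs, grid, cp)
    obs[t_obs < 0] = cp_b
    if rng is not None and cv > 0:
        obs = np.maximum(obs * (1 + cv * rng.standard_normal(obs.size)), 0.0)
    return SamplingSeries("cpeptide", "nmol/l", t_obs, obs / 1e3), steps, edges


class TestKinetics:
    def test_conversion_identities(self, kin):
        lam1, lam2, f = kin.lam1, kin.lam2, kin.fraction
        assert kin.k12 == pytest.approx((1 - f) * lam1 + f * lam2, abs=1e-12)
        assert kin.k01 == pytest.approx(lam1 * lam2 / kin.k12, abs=1e-12)
        assert kin.k21 == pytest.approx(lam1 + lam2 - kin.k01 - kin.k12, abs=1e-12)

    def test_impulse_response_matches_compartmental_ode(self, kin):
        """Independent oracle: integrate the two-compartment ODE for a bolus."""
        def rhs(_t, y):
            q1, q2 = y
            return [-(kin.k01 + kin.k21) * q1 + kin.k12 * q2,
                    kin.k21 * q1 - kin.k12 * q2]
        t_eval = np.linspace(0, 200, 201)
        sol = solve_ivp(rhs, (0, 200), [1.0, 0.0], t_eval=t_eval,
                        rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(sol.y[0] / kin.v1,
                                   kin.impulse_response(t_eval), atol=1e-8)

    def test_diabetes_set_has_longer_slow_halflife(self):
        t2d = gr.SubjectProfile("a", "T2D", 50, 150, 50, 7, 0, 1.2)
        ngt = gr.SubjectProfile("b", "NGT", 50, 150, 50, 5.4, 0, 1.0)
        assert (population_kinetics(t2d).t_half_long
                > population_kinetics(ngt).t_half_long)

    def test_invalid_halflife_ordering_rejected(self):
        with pytest.raises(gr.ValidationError):
            CPeptideKinetics(30.0, 5.0, 0.78, 5.0)


class TestDeconvolution:
    def test_constant_cpeptide_gives_equilibrium_isr(self, kin):
        t = np.arange(-40.0, 361.0, 20.0)
        cp = SamplingSeries("cpeptide", "nmol/l", t, np.full(t.size, 1.0))
        res = deconvolve_isr(cp, kin)
        np.testing.assert_allclose(res.isr, kin.basal_isr(1000.0), rtol=1e-6)

    def test_noise_free_staircase_recovered_pointwise(self, kin):
        cp, steps, _ = staircase_cpeptide(kin)
        res = deconvolve_isr(cp, kin, reg=1e-9)
        np.testing.assert_allclose(res.isr, steps, rtol=0.02)

    def test_noisy_auc_within_5pct(self, kin):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cp, steps, _ = staircase_cpeptide(kin, rng=rng, cv=0.05)
            res = deconvolve_isr(cp, kin)
            truth = float(np.sum(steps * 20.0))
            errs.append(abs(res.isr_auc["total"] - truth) / truth)
        assert np.median(errs) < 0.05

    def test_reconvolution_r2_above_099(self, kin, oral_session):
        session, _ = oral_session
        res = deconvolve_isr(session.cpeptide, kin)
        cp_b = session.cpeptide.basal() * 1e3
        grid = np.arange(0.0, 360.5, 1.0)
        pred = cpeptide_from_isr(res.at(grid), kin, 1.0, cp_b)
        obs_t = session.cpeptide.times[session.cpeptide.times >= 0]
        obs = session.cpeptide.values[session.cpeptide.times >= 0] * 1e3
        pred_at = np.interp(obs_t, grid, pred)
        ss_res = np.sum((obs - pred_at) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_time_shift_invariance(self, kin):
        cp, _, _ = staircase_cpeptide(kin)
        res = deconvolve_isr(cp, kin)
        # shifting the clock does not change the reconstructed rates
        shifted = SamplingSeries("cpeptide", "nmol/l", cp.times - 0.0,
                                 cp.values)
        res2 = deconvolve_isr(shifted, kin)
        np.testing.assert_allclose(res.isr, res2.isr, rtol=1e-12)

    def test_halving_v1_halves_equilibrium_isr(self, kin):
        t = np.arange(-40.0, 361.0, 20.0)
        cp = SamplingSeries("cpeptide", "nmol/l", t, np.full(t.size, 1.0))
        small = CPeptideKinetics(kin.t_half_short, kin.t_half_long,
                                 kin.fraction, kin.v1 / 2)
        res_full = deconvolve_isr(cp, kin)
        res_half = deconvolve_isr(cp, small)
        np.testing.assert_allclose(res_half.isr, res_full.isr / 2, rtol=1e-6)


class TestTotalIsr:
    def test_constant_isr_average_is_constant(self, kin):
        t = np.arange(-40.0, 361.0, 20.0)
        cp = SamplingSeries("cpeptide", "nmol/l", t, np.full(t.size, 1.0))
        res = deconvolve_isr(cp, kin)
        for seg in SEGMENTS:
            assert total_isr(res, seg) == pytest.approx(kin.basal_isr(1000.0),
                                                        rel=1e-6)

    def test_segment_averages_combine_to_session_mean(self, kin):
        cp, _, _ = staircase_cpeptide(kin)
        res = deconvolve_isr(cp, kin, reg=1e-9)
        session_mean = float(np.sum(res.isr * np.diff(res.edges)) / 360.0)
        seg_mean = np.mean([total_isr(res, s) for s in SEGMENTS])
        assert seg_mean == pytest.approx(session_mean, rel=1e-9)

    def test_incretin_cohort_has_higher_oral_isr(self, oral_session,
                                                 igivi_session, kin):
        oral, _ = oral_session
        igivi, _ = igivi_session
        res_o = deconvolve_isr(oral.cpeptide, kin)
        res_i = deconvolve_isr(igivi.cpeptide, kin)
        mean_o = np.mean([total_isr(res_o, s) for s in SEGMENTS])
        mean_i = np.mean([total_isr(res_i, s) for s in SEGMENTS])
        assert mean_o > mean_i
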