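"""Index panel: unit arithmetic, closed forms, invariances."""

import numpy as np
import pytest

import glucoroute as gr
from glucoroute.data_model import SamplingSeries, SEGMENTS, Segment, ValidationError
from glucoroute.indices import (
    adipo_ir,
    disposition_index,
    hepatic_ir,
    insulin_clearance,
    insulinogenic_index,
    mcr_i,
    required_sample_size,
)
from glucoroute.secretion import SecretionResult, CPeptideKinetics
from glucoroute.tracer import FluxResult, PoolModel


def flat_series(analyte, unit, value, step=10.0):
    t = np.arange(-40.0, 361.0, step)
    return SamplingSeries(analyte, unit, t, np.full(t.size, float(value)))


def flat_flux(rd=20.0, egp=10.0):
    grid = np.arange(0.0, 360.5, 1.0)
    return FluxResult(times=grid, ra_total=np.full(grid.size, rd),
                      ra_oral=np.zeros(grid.size), rd=np.full(grid.size, rd),
                      egp=np.full(grid.size, egp), pool=PoolModel())


def flat_secretion(isr=500.0):
    kin = CPeptideKinetics(4.55, 33.1, 0.78, 5.0)
    edges = np.arange(0.0, 361.0, 20.0)
    return SecretionResult(edges=edges, isr=np.full(edges.size - 1, isr),
                           isr_basal=isr, kinetics=kin, reg=0.0,
                           residual_rms=0.0)


class TestMcrI:
    def test_unit_arithmetic(self):
        flux = flat_flux(rd=20.0)
        g = flat_series("glucose", "mmol/l", 5.0)
        i = flat_series("insulin", "pmol/l", 500.0, step=20.0)
        assert mcr_i(flux, g, i) == pytest.approx(8.0)

    def test_doubling_insulin_halves_index(self):
        flux = flat_flux()
        g = flat_series("glucose", "mmol/l", 5.0)
        i1 = flat_series("insulin", "pmol/l", 300.0, step=20.0)
        i2 = flat_series("insulin", "pmol/l", 600.0, step=20.0)
        assert mcr_i(flux, g, i1) == pytest.approx(2 * mcr_i(flux, g, i2))

    def test_nonpositive_insulin_rejected(self):
        flux = flat_flux()
        g = flat_series("glucose", "mmol/l", 5.0)
        i = flat_series("insulin", "pmol/l", 0.0, step=20.0)
        with pytest.raises(ValidationError):
            mcr_i(flux, g, i)

    def test_route_resistance_recovered_in_index_ratio(
            self, oral_session, igivi_session, generator_pool, physiology):
        """kappa=0.6 shows up as a proportionally lower oral index."""
        oral, _ = oral_session
        igivi, _ = igivi_session
        kin = gr.population_kinetics(oral.subject)
        fo = gr.analyze_session(oral, generator_pool)
        fi = gr.analyze_session(igivi, generator_pool)
        r = (mcr_i(fo, oral.glucose, oral.insulin)
             / mcr_i(fi, igivi.glucose, igivi.insulin))
        # insulin action is kappa-scaled but basal disposal is not, so the
        # index ratio sits between kappa and 1, well below unity
        assert r < 0.85
        assert r > physiology.kappa * 0.85


class TestSimpleIndices:
    def test_hepatic_ir_product(self):
        flux = flat_flux(egp=10.0)
        i = flat_series("insulin", "pmol/l", 100.0, step=20.0)
        assert hepatic_ir(flux, i) == pytest.approx(1000.0)

    def test_hepatic_ir_zero_when_egp_zero(self):
        flux = flat_flux(egp=0.0)
        i = flat_series("insulin", "pmol/l", 100.0, step=20.0)
        assert hepatic_ir(flux, i) == 0.0

    def test_insulinogenic_ratio(self):
        t = np.array([-20.0, 0.0, 120.0, 240.0, 360.0])
        ins = SamplingSeries("insulin", "pmol/l", t,
                             np.array([100.0, 100, 102.5, 102.5, 102.5]))
        glu = SamplingSeries("glucose", "mmol/l", t,
                             np.array([5.0, 5, 5.025, 5.025, 5.025]))
        # incremental AUCs: insulin 2.5*300+150=900-ish vs glucose ~9-ish
        val = insulinogenic_index(ins, glu)
        assert val == pytest.approx(100.0, rel=1e-9)

    def test_insulinogenic_basal_insulin_gives_zero(self):
        ins = flat_series("insulin", "pmol/l", 100.0, step=20.0)
        t = np.array([-20.0, 0.0, 180.0, 360.0])
        glu = SamplingSeries("glucose", "mmol/l", t, np.array([5.0, 5, 8, 6]))
        assert insulinogenic_index(ins, glu) == pytest.approx(0.0)

    def test_insulinogenic_flat_glucose_rejected(self):
        ins = flat_series("insulin", "pmol/l", 100.0, step=20.0)
        glu = flat_series("glucose", "mmol/l", 5.0)
        with pytest.raises(ValidationError):
            insulinogenic_index(ins, glu)

    def test_adipo_ir_product_and_empty_list(self):
        mets = {"palmitic_acid": flat_series("palmitic_acid", "mmol/l", 0.5,
                                             step=20.0)}
        ins = flat_series("insulin", "pmol/l", 200.0, step=20.0)
        assert adipo_ir(mets, ins, ("palmitic_acid",)) == pytest.approx(100.0)
        with pytest.raises(ValidationError):
            adipo_ir(mets, ins, fatty_acids=())


class TestClearance:
    def test_steady_state_collapses_to_isr_over_insulin(self):
        sec = flat_secretion(isr=600.0)
        ins = flat_series("insulin", "pmol/l", 300.0, step=20.0)
        cl = insulin_clearance(sec, ins, weight=150.0)
        assert cl == pytest.approx(600.0 / 300.0, rel=1e-10)

    def test_equal_endpoint_insulin_drops_volume_term(self):
        sec = flat_secretion(isr=600.0)
        t = np.arange(-40.0, 361.0, 20.0)
        wave = 300.0 + 50.0 * np.sin(2 * np.pi * t / 360.0)
        wave[t <= 0] = 300.0
        wave[-1] = 300.0  # I_end == I_0
        ins = SamplingSeries("insulin", "pmol/l", t, wave)
        auc_i = gr.auc(ins, (0, 360))
        assert insulin_clearance(sec, ins, 150.0) == pytest.approx(
            600.0 * 360.0 / auc_i, rel=1e-10)

    def test_simulator_clearance_matches_generator_ratio(
            self, oral_session, oral_secretion, physiology):
        """Measured CL approximates peripheral clearance / (1 - extraction)."""
        session, _ = oral_session
        cl = insulin_clearance(oral_secretion, session.insulin,
                               session.subject.weight)
        expected = (physiology.peripheral_clearance
                    / (1 - physiology.hepatic_extraction_oral))
        assert abs(cl - expected) < 0.10 * expected


class TestDispositionIndex:
    def test_product_form(self):
        sec = flat_secretion(isr=500.0)
        flux = flat_flux(rd=20.0)
        g = flat_series("glucose", "mmol/l", 5.0)
        i = flat_series("insulin", "pmol/l", 500.0, step=20.0)
        assert disposition_index(sec, flux, g, i) == pytest.approx(500.0 * 8.0)

    def test_zero_secretion_gives_zero_di(self):
        sec = flat_secretion(isr=0.0)
        flux = flat_flux()
        g = flat_series("glucose", "mmol/l", 5.0)
        i = flat_series("insulin", "pmol/l", 500.0, step=20.0)
        assert disposition_index(sec, flux, g, i) == 0.0


class TestSampleSize:
    def test_study_design_number(self):
        assert required_sample_size(4.6, 5.98, 0.9, 0.05, 0.90, 0.25) == 24

    def test_without_attrition(self):
        assert required_sample_size(4.6, 5.98, 0.9, 0.05, 0.90, 0.0) == 18

    def test_huge_effect_floors_at_two_inflated(self):
        assert required_sample_size(1.0, 1e9, 0.9, 0.05, 0.90, 0.25) == 3
        assert required_sample_size(1.0, 1e9, 0.9, 0.05, 0.90, 0.0) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ValidationError):
            required_sample_size(5.0, 5.0, 0.9)


class TestGridInvariance:
    def test_indices_stable_under_grid_refinement(self, oral_session,
                                                  oral_flux, oral_secretion):
        """Linear interpolation refinement leaves segment indices unchanged."""
        session, _ = oral_session

        def refine(s, factor=4):
            t = np.linspace(s.times[0], s.times[-1],
                            (s.times.size - 1) * factor + 1)
            return SamplingSeries(s.analyte, s.unit, t, s.interp(t))

        g2 = refine(session.glucose)
        i2 = refine(session.insulin)
        for seg in SEGMENTS:
            a = mcr_i(oral_flux, session.glucose, session.insulin, seg)
            b = mcr_i(oral_flux, g2, i2, seg)
            assert b == pytest.approx(a, rel=1e-6)
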