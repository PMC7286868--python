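"""Shared fixtures: one canonical simulated subject reused across modules.

Session-scoped because the forward simulation and controller runs are
the expensive part; tests must not mutate the returned objects.
"""

import warnings

import numpy as np
import pytest

import glucoroute as gr

warnings.filterwarnings("ignore", message="segment .*oral Ra integral")


@pytest.fixture(scope="session")
def subject():
    return gr.SubjectProfile(
        subject_id="NGT01", group="NGT", age=46.0, weight=150.0, bmi=52.0,
        basal_glucose=5.35, basal_insulin=0.0, basal_cpeptide=1.0,
    )


@pytest.fixture(scope="session")
def physiology():
    return gr.default_physiology("NGT")


@pytest.fixture(scope="session")
def noise_free_cfg():
    return gr.CohortConfig(rng_seed=1).noise_free()


@pytest.fixture(scope="session")
def oral_session(subject, physiology, noise_free_cfg):
    session, truth = gr.simulate_oral_session(subject, physiology, noise_free_cfg)
    return session, truth


@pytest.fixture(scope="session")
def igivi_session(subject, physiology, noise_free_cfg, oral_session):
    _, oral_truth = oral_session
    session, truth = gr.simulate_igivi_session(subject, physiology,
                                               noise_free_cfg, oral_truth)
    return session, truth


@pytest.fixture(scope="session")
def generator_pool():
    """Pool model whose effective volume equals the generator's V_g."""
    return gr.PoolModel()  # 160 ml/kg x 0.65 = 104 = generator default


@pytest.fixture(scope="session")
def oral_flux(oral_session, generator_pool):
    session, _ = oral_session
    return gr.analyze_session(session, generator_pool)


@pytest.fixture(scope="session")
def oral_secretion(oral_session):
    session, _ = oral_session
    kin = gr.population_kinetics(session.subject)
    return gr.deconvolve_isr(session.cpeptide, kin)
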