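"""Forward simulation of paired oral / IGIVI sessions with known truth.

The generator exists so that every downstream estimator (Steele fluxes,
C-peptide deconvolution, the three-load beta-cell model, the index
panel) can be tested by parameter recovery. Its glucose side is the
single-pool oral minimal model, deliberately the same structural family
the analysis assumes, so noise-free recovery is a true oracle; realism
beyond that family is explicitly sacrificed.

Model (1-min fixed-step RK4, t in [-150, 360] min):

    dG/dt  = (EGP + Ra_oral + GIR - Rd) / V_g
    Rd     = max(0, EGP_b + V_g * [S_G (G - G_b) + X G])
    dX/dt  = -p2 (X - kappa * S_I * (I - I_b))
    EGP    = max(0, EGP_b - k_egp_I (I - I_b) - k_egp_G (G - G_b))
    tau dSR_s/dt = -SR_s + beta_seg (G - h)+
    SR_d   = K_d,seg * max(dG/dt, 0)
    ISR    = ISR_b + gain * (SR_s + SR_d)
    dI/dt  = (-CL_p I + (1 - E) ISR) / V_I,   V_I = 0.14 * weight

Basal disposal is anchored at EGP_b so the system is at equilibrium at
(G_b, I_b) — insulin action, secretion and production all reduce to
their basal values there. Route dependence enters through exactly one
knob per claim under test: kappa (<1: oral insulin resistance),
incretin_gain (>1: amplified oral secretion), hepatic extraction
(route-specific insulin clearance) and a metabolic blunting factor on
insulin-driven metabolite disappearance under oral dosing.

Both labeled species are carried as separate single-pool mass balances
cleared at the tracee's fractional clearance, yielding the
tracer-to-tracee ratio series the Steele analysis consumes. The IGIVI
dextrose schedule is produced by a proportional-integral tracking
controller with model feedforward, updated on the 10-min measurement
grid, so the intravenous glycaemic profile replicates the oral one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    GLUCOSE_MW,
    InfusionSchedule,
    NumericsError,
    SamplingSeries,
    SEGMENTS,
    SessionRecord,
    SubjectProfile,
    TracerSeries,
    ValidationError,
)
from .secretion import CPeptideKinetics, cpeptide_from_isr, population_kinetics

__all__ = [
    "TruePhysiology",
    "CohortConfig",
    "GroundTruth",
    "SubjectData",
    "default_physiology",
    "simulate_oral_session",
    "simulate_igivi_session",
    "derive_igivi_infusion",
    "simulate_cohort",
]

T_START = -150.0  # tracer equilibration begins 2.5 h before the first load
T_END = 360.0
DT = 1.0

#: default NEFA species tracked by the simulator (mmol/l basal levels)
DEFAULT_METABOLITES = {
    "lactate": 1.0,
    "alanine": 0.35,
    "leucine": 0.13,
    "isoleucine": 0.065,
    "valine": 0.22,
    "palmitic_acid": 0.15,
    "oleic_acid": 0.18,
    "stearic_acid": 0.05,
    "linoleic_acid": 0.10,
    "myristic_acid": 0.02,
}

#: insulin-driven disappearance constants, 1/min per pmol/l of insulin
DEFAULT_KM = {
    "lactate": 1.75e-5,
    "alanine": 1.8e-5,
    "leucine": 1.65e-5,
    "isoleucine": 1.95e-5,
    "valine": 1.5e-5,
    "palmitic_acid": 3.9e-5,
    "oleic_acid": 3.9e-5,
    "stearic_acid": 3.3e-5,
    "linoleic_acid": 3.6e-5,
    "myristic_acid": 4.2e-5,
}


@dataclass
class TruePhysiology:
    """Ground-truth parameters of one simulated participant.

    Units: S_I per pmol/l per min; S_G, p2 1/min; V_g ml/kg; beta
    pmol/min per mmol/l; kd pmol per mmol/l; h mmol/l (None anchors the
    secretion threshold at basal glucose); tau min; EGP_b
    umol kg-1 min-1; peripheral_clearance l/min.
    """

    s_i_iv: float = 1.2e-4
    kappa: float = 0.6
    s_g: float = 0.035
    p2: float = 0.08
    v_g: float = 104.0
    beta_true: tuple[float, float, float] = (120.0, 120.0, 120.0)
    kd_true: tuple[float, float, float] = (600.0, 600.0, 600.0)
    h: float | None = None
    tau: float = 15.0
    hepatic_extraction_iv: float = 0.50
    hepatic_extraction_oral: float = 0.42
    incretin_gain: float = 1.8
    egp_b: float = 11.0
    k_egp_i: float = 0.004
    k_egp_g: float = 0.5
    peripheral_clearance: float = 1.25
    absorption_shape: float = 3.0
    absorption_scale: float = 16.0
    metabolite_basal: dict = field(default_factory=lambda: dict(DEFAULT_METABOLITES))
    k_m: dict = field(default_factory=lambda: dict(DEFAULT_KM))
    metabolic_blunting: float = 0.25  # oral multiplier on k_m
    glp1_basal: float = 8.0  # ng/l
    glp1_amplitude: float = 25.0  # ng/l peak increment per 75 g
    glucagon_basal: float = 70.0  # ng/l
    glucagon_suppression: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.kappa <= 1:
            raise ValidationError("kappa must lie in (0, 1]")
        for name in ("s_i_iv", "s_g", "p2", "v_g", "tau", "egp_b",
                     "peripheral_clearance"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for e in (self.hepatic_extraction_iv, self.hepatic_extraction_oral):
            if not 0 <= e < 0.9:
                raise ValidationError("hepatic extraction must lie in [0, 0.9)")


@dataclass
class CohortConfig:
    """Cohort composition, noise levels and the mandatory seed."""

    rng_seed: int
    n_per_group: tuple[int, int, int] = (9, 7, 7)  # NGT, IGT, T2D
    cv_glucose: float = 0.015
    cv_insulin: float = 0.05
    cv_cpeptide: float = 0.05
    sd_ttr: float = 3.0e-4  # additive
    cv_metabolite: float = 0.08
    between_subject_cv: float = 0.12  # lognormal CV on physiology parameters
    glucose_step: float = 10.0
    hormone_step: float = 20.0

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValidationError("rng_seed is mandatory")
        for name in ("cv_glucose", "cv_insulin", "cv_cpeptide", "sd_ttr",
                     "cv_metabolite", "between_subject_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def noise_free(self) -> "CohortConfig":
        return replace(self, cv_glucose=0.0, cv_insulin=0.0, cv_cpeptide=0.0,
                       sd_ttr=0.0, cv_metabolite=0.0)


@dataclass
class GroundTruth:
    """Latent noise-free trajectories on the 1-min simulation grid."""

    times: np.ndarray
    glucose: np.ndarray  # mmol/l
    insulin: np.ndarray  # pmol/l
    cpeptide: np.ndarray  # nmol/l
    isr: np.ndarray  # pmol/min
    ra_oral: np.ndarray  # umol kg-1 min-1
    egp: np.ndarray
    gir: np.ndarray
    rd: np.ndarray
    ttr_d2: np.ndarray
    ttr_c13: np.ndarray
    metabolites: dict[str, np.ndarray]
    phys: TruePhysiology
    kinetics: CPeptideKinetics
    basal_insulin: float

    @property
    def ra_total(self) -> np.ndarray:
        return self.ra_oral + self.egp + self.gir

    def mean_isr(self, segment) -> float:
        m = (self.times >= segment.start) & (self.times <= segment.end)
        return float(np.trapezoid(self.isr[m], self.times[m]) / (segment.end - segment.start))


@dataclass
class SubjectData:
    """One participant's paired sessions with their ground truths."""

    subject: SubjectProfile
    phys: TruePhysiology
    oral: SessionRecord
    oral_truth: GroundTruth
    igivi: SessionRecord
    igivi_truth: GroundTruth


# ---------------------------------------------------------------------------
# Oral absorption
# ---------------------------------------------------------------------------

def _gamma_density(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma pdf, shape>=1, vectorised; 0 for t<0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    from scipy.special import gammaln
    x = t[pos] / scale
    out[pos] = np.exp((shape - 1) * np.log(x) - x - gammaln(shape)) / scale
    return out


def oral_appearance(times: np.ndarray, infusions: InfusionSchedule,
                    phys: TruePhysiology, weight: float) -> tuple[np.ndarray, np.ndarray]:
    """(total Ra_oral, labeled C13 input) in umol kg-1 min-1 on ``times``.

    Each load appears as a gamma-density pulse (shape/scale from the
    physiology; defaults put ~99% of the dose inside its own 120-min segment). The labeled input carries each load's own enrichment.
    """
    total = np.zeros_like(times, dtype=float)
    labeled = np.zeros_like(times, dtype=float)
    for t0, dose_g, tracer_g in infusions.oral_loads:
        pulse = _gamma_density(times - t0, phys.absorption_shape, phys.absorption_scale)
        dose_umol_kg = dose_g * 1e6 / GLUCOSE_MW / weight
        total += dose_umol_kg * pulse
        labeled += (tracer_g / dose_g) * dose_umol_kg * pulse
    return total, labeled


# ---------------------------------------------------------------------------
# Core forward simulation
# ---------------------------------------------------------------------------

def _segment_index(t: float) -> int:
    if t < 120.0:
        return 0
    if t < 240.0:
        return 1
    return 2


def _simulate(subject: SubjectProfile, phys: TruePhysiology, route: str,
              infusions: InfusionSchedule,
              gir_fn=None, controller=None) -> GroundTruth:
    """Run the forward model; optionally let a controller set GIR blocks.

    ``gir_fn(t)`` supplies the dextrose rate for a fixed schedule;
    ``controller`` (IGIVI derivation) is called at every 10-min
    boundary with (t, state, history) and returns the next block rate.
    """
    kin = population_kinetics(subject)
    g_b = subject.basal_glucose
    cp_b_pmol = subject.basal_cpeptide * 1e3
    isr_b = kin.basal_isr(cp_b_pmol)
    extraction = (phys.hepatic_extraction_oral if route == "oral"
                  else phys.hepatic_extraction_iv)
    kappa = phys.kappa if route == "oral" else 1.0
    gain = phys.incretin_gain if route == "oral" else 1.0
    v_i = 0.14 * subject.weight  # insulin distribution volume, litres
    i_b = (1 - extraction) * isr_b / phys.peripheral_clearance
    h = phys.h if phys.h is not None else g_b

    n = int(round((T_END - T_START) / DT))
    times = T_START + DT * np.arange(n + 1)

    # precompute oral inputs on the half-step grid used by RK4
    half = T_START + 0.5 * DT * np.arange(2 * n + 1)
    if route == "oral":
        ra_oral_half, label_oral_half = oral_appearance(half, infusions, phys,
                                                        subject.weight)
    else:
        ra_oral_half = np.zeros_like(half)
        label_oral_half = np.zeros_like(half)

    gir_current = [0.0]

    def gir_at(t: float) -> float:
        if controller is not None:
            return gir_current[0] if t >= 0 else 0.0
        if gir_fn is not None:
            return float(gir_fn(t))
        return 0.0

    beta = phys.beta_true
    kd = phys.kd_true

    def rhs(t: float, y: np.ndarray, k_half: int) -> tuple[np.ndarray, float, float, float]:
        G, X, srs, I, g_d2, g_c13 = y
        seg = _segment_index(t) if t >= 0 else 0
        ra_o = ra_oral_half[k_half]
        lab_o = label_oral_half[k_half]
        gir = gir_at(t)
        egp = max(0.0, phys.egp_b - phys.k_egp_i * (I - i_b) - phys.k_egp_g * (G - g_b))
        rd = max(0.0, phys.egp_b + phys.v_g * (phys.s_g * (G - g_b) + X * G))
        dG = (egp + ra_o + gir - rd) / phys.v_g
        dX = -phys.p2 * (X - kappa * phys.s_i_iv * (I - i_b))
        u = beta[seg] * max(G - h, 0.0) if t >= 0 else 0.0
        dsrs = (-srs + u) / phys.tau
        sr_d = kd[seg] * max(dG, 0.0) if t >= 0 else 0.0
        isr = isr_b + gain * (srs + sr_d)
        dI = (-phys.peripheral_clearance * I + (1 - extraction) * isr) / v_i
        frac = rd / (phys.v_g * G) if G > 0 else 0.0
        label_iv = infusions.tracer_rate + infusions.dextrose_enrichment * gir \
            if route == "igivi" and t >= 0 else infusions.tracer_rate
        d_d2 = label_iv / phys.v_g - frac * g_d2
        d_c13 = lab_o / phys.v_g - frac * g_c13
        return np.array([dG, dX, dsrs, dI, d_d2, d_c13]), isr, egp, rd

    # initial state: basal equilibrium + tracer prime
    y = np.array([g_b, 0.0, 0.0, i_b, infusions.tracer_prime / phys.v_g, 0.0])
    traj = np.empty((n + 1, 6))
    isr_t = np.empty(n + 1)
    egp_t = np.empty(n + 1)
    rd_t = np.empty(n + 1)
    gir_t = np.empty(n + 1)
    gir_blocks: list[tuple[float, float]] = []
    err_hist: list[float] = []

    traj[0] = y
    d0, isr_t[0], egp_t[0], rd_t[0] = rhs(times[0], y, 0)
    gir_t[0] = gir_at(times[0])

    for k in range(n):
        t = times[k]
        if controller is not None and t >= 0 and abs(t % 10.0) < 1e-9:
            gir_current[0] = controller(t, y, err_hist)
            gir_blocks.append((t, gir_current[0]))
        gir_t[k] = gir_at(t)
        k1, isr_k, egp_k, rd_k = rhs(t, y, 2 * k)
        isr_t[k], egp_t[k], rd_t[k] = isr_k, egp_k, rd_k
        k2, *_ = rhs(t + 0.5 * DT, y + 0.5 * DT * k1, 2 * k + 1)
        k3, *_ = rhs(t + 0.5 * DT, y + 0.5 * DT * k2, 2 * k + 1)
        k4, *_ = rhs(t + DT, y + DT * k3, 2 * k + 2)
        y = y + (DT / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if y[0] <= 0 or not np.all(np.isfinite(y)):
            raise NumericsError(
                f"simulation diverged at t={t + DT:.0f} min; state={y}, phys={phys}"
            )
        y[1] = max(y[1], -kappa * phys.s_i_iv * i_b)  # X bounded below
        y[4] = max(y[4], 0.0)
        y[5] = max(y[5], 0.0)
        traj[k + 1] = y
    d_end, isr_t[n], egp_t[n], rd_t[n] = rhs(times[n], y, 2 * n)
    gir_t[n] = gir_at(times[n])

    G = traj[:, 0]
    I = traj[:, 3]
    ttr_d2 = traj[:, 4] / G
    ttr_c13 = traj[:, 5] / G
    cp = cpeptide_from_isr(isr_t, kin, DT, cp_b_pmol) / 1e3  # nmol/l

    # insulin-driven metabolite disappearance, production balanced at basal
    blunt = phys.metabolic_blunting if route == "oral" else 1.0
    mets = {}
    i_int = np.concatenate(([0.0], np.cumsum(0.5 * (I[1:] + I[:-1]) * DT)))
    for name, c0 in phys.metabolite_basal.items():
        k_eff = blunt * phys.k_m[name]
        # dC/dt = -k_eff I C + k_eff I_b C0  (flat at basal, decays when I > I_b);
        # integrating-factor solution on the grid, trapezoid for the source term
        big_m = np.exp(k_eff * i_int)
        source = k_eff * i_b * c0 * big_m
        src_int = np.concatenate(([0.0], np.cumsum(0.5 * (source[1:] + source[:-1]) * DT)))
        mets[name] = (c0 + src_int) / big_m

    truth = GroundTruth(
        times=times, glucose=G, insulin=I, cpeptide=cp, isr=isr_t,
        ra_oral=ra_oral_half[::2] if route == "oral" else np.zeros(n + 1),
        egp=egp_t, gir=gir_t, rd=rd_t, ttr_d2=ttr_d2, ttr_c13=ttr_c13,
        metabolites=mets, phys=phys, kinetics=kin, basal_insulin=i_b,
    )
    if controller is not None:
        truth._gir_blocks = gir_blocks  # type: ignore[attr-defined]
    return truth


def _descriptive_hormones(times: np.ndarray, route: str, phys: TruePhysiology,
                          infusions: InfusionSchedule,
                          insulin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLP-1 and glucagon shapes (ng/l): descriptive, not causal drivers."""
    glp1 = np.full_like(times, phys.glp1_basal, dtype=float)
    if route == "oral":
        for t0, dose_g, _ in infusions.oral_loads:
            pulse = _gamma_density(times - t0, 2.0, 25.0)
            peak = _gamma_density(np.array([25.0]), 2.0, 25.0)[0]
            glp1 += phys.glp1_amplitude * (dose_g / 75.0) * pulse / peak
    i_b = insulin[times <= 0].mean()
    supra = np.maximum(insulin - i_b, 0.0)
    denom = supra.max() if supra.max() > 0 else 1.0
    glucagon = phys.glucagon_basal * (1.0 - phys.glucagon_suppression * supra / denom)
    return glp1, glucagon


def _sample_session(truth: GroundTruth, subject: SubjectProfile, route: str,
                    infusions: InfusionSchedule, cfg: CohortConfig,
                    rng: np.random.Generator) -> SessionRecord:
    """Sample the latent trajectories on the protocol grids with noise."""
    t, G = truth.times, truth.glucose

    def at(series: np.ndarray, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, t, series)

    g_grid = np.arange(-30.0, T_END + 0.5, cfg.glucose_step)
    h_grid = np.arange(-40.0, T_END + 0.5, cfg.hormone_step)

    def noisy(values: np.ndarray, cv: float) -> np.ndarray:
        if cv == 0:
            return values.copy()
        return np.maximum(values * (1.0 + cv * rng.standard_normal(values.size)), 0.0)

    glucose = SamplingSeries("glucose", "mmol/l", g_grid, noisy(at(G, g_grid), cfg.cv_glucose))
    insulin = SamplingSeries("insulin", "pmol/l", h_grid,
                             noisy(at(truth.insulin, h_grid), cfg.cv_insulin))
    cpeptide = SamplingSeries("cpeptide", "nmol/l", h_grid,
                              noisy(at(truth.cpeptide, h_grid), cfg.cv_cpeptide))
    glp1_v, glucagon_v = _descriptive_hormones(t, route, truth.phys, infusions,
                                               truth.insulin)
    glp1 = SamplingSeries("glp1", "ng/l", h_grid, noisy(at(glp1_v, h_grid), cfg.cv_insulin))
    glucagon = SamplingSeries("glucagon", "ng/l", h_grid,
                              noisy(at(glucagon_v, h_grid), cfg.cv_insulin))
    mets = {
        name: SamplingSeries(name, "mmol/l", h_grid,
                             noisy(at(series, h_grid), cfg.cv_metabolite))
        for name, series in truth.metabolites.items()
    }

    def noisy_ttr(values: np.ndarray) -> np.ndarray:
        if cfg.sd_ttr == 0:
            return values.copy()
        return np.maximum(values + cfg.sd_ttr * rng.standard_normal(values.size), 0.0)

    tracers = {"D2": TracerSeries("D2", g_grid, noisy_ttr(at(truth.ttr_d2, g_grid)))}
    if route == "oral":
        tracers["C13"] = TracerSeries("C13", g_grid, noisy_ttr(at(truth.ttr_c13, g_grid)))

    return SessionRecord(subject=subject, route=route, glucose=glucose,
                         insulin=insulin, cpeptide=cpeptide, glp1=glp1,
                         glucagon=glucagon, metabolites=mets, tracers=tracers,
                         infusions=infusions)


def simulate_oral_session(
    subject: SubjectProfile, phys: TruePhysiology, cfg: CohortConfig,
    rng: np.random.Generator | None = None,
    infusions: InfusionSchedule | None = None,
) -> tuple[SessionRecord, GroundTruth]:
    """Simulate the triple-load oral session for one subject."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    infusions = infusions if infusions is not None else InfusionSchedule.default_oral()
    truth = _simulate(subject, phys, "oral", infusions)
    session = _sample_session(truth, subject, "oral", infusions, cfg, rng)
    return session, truth


def _make_controller(target_fn, phys: TruePhysiology, subject: SubjectProfile,
                     isr_b: float, i_b: float, g_b: float,
                     kp: float = 16.0, ki: float = 1.5):
    """PI tracking controller with model feedforward, 10-min update."""
    state = {"integral": 0.0}
    block = 10.0

    def controller(t: float, y: np.ndarray, err_hist: list[float]) -> float:
        G, X, srs, I, *_ = y
        tgt_now = target_fn(t)
        tgt_next = target_fn(min(t + block, T_END))
        err = tgt_now - G
        state["integral"] += err * block
        egp = max(0.0, phys.egp_b - phys.k_egp_i * (I - i_b) - phys.k_egp_g * (G - g_b))
        rd = max(0.0, phys.egp_b + phys.v_g * (phys.s_g * (G - g_b) + X * G))
        feedforward = phys.v_g * (tgt_next - tgt_now) / block + rd - egp
        u = feedforward + kp * err + ki * state["integral"]
        err_hist.append(err)
        return max(0.0, u)

    return controller


def derive_igivi_infusion(
    subject: SubjectProfile, phys: TruePhysiology, target: GroundTruth,
    rms_tolerance: float = 0.3,
) -> tuple[InfusionSchedule, GroundTruth]:
    """Derive the variable dextrose schedule matching an oral glycaemic profile.

    A proportional-integral controller with feedforward from the
    generator's own model updates the piecewise-constant 20% dextrose
    rate every 10 min (the protocol's measurement cadence) so the
    simulated intravenous glucose tracks the oral session's noise-free
    profile. The intravenous arm runs with kappa=1, incretin_gain=1 and
    the intravenous hepatic extraction.
    """
    kin = target.kinetics
    cp_b_pmol = subject.basal_cpeptide * 1e3
    isr_b = kin.basal_isr(cp_b_pmol)
    i_b = (1 - phys.hepatic_extraction_iv) * isr_b / phys.peripheral_clearance
    g_b = subject.basal_glucose

    def target_fn(t: float) -> float:
        return float(np.interp(t, target.times, target.glucose))

    controller = _make_controller(target_fn, phys, subject, isr_b, i_b, g_b)
    base = InfusionSchedule(dextrose_times=np.array([0.0]),
                           dextrose_rates=np.array([0.0]))
    truth = _simulate(subject, phys, "igivi", base, controller=controller)

    blocks = truth._gir_blocks  # type: ignore[attr-defined]
    schedule = InfusionSchedule(
        dextrose_times=np.array([b[0] for b in blocks]),
        dextrose_rates=np.array([b[1] for b in blocks]),
    )
    mask = truth.times >= 0
    rms = float(np.sqrt(np.mean(
        (truth.glucose[mask] - np.interp(truth.times[mask], target.times,
                                         target.glucose)) ** 2)))
    if rms > rms_tolerance:
        raise NumericsError(
            f"IGIVI controller failed to track the oral profile: RMS {rms:.3f} mmol/l"
        )
    return schedule, truth


def simulate_igivi_session(
    subject: SubjectProfile, phys: TruePhysiology, cfg: CohortConfig,
    target: GroundTruth, rng: np.random.Generator | None = None,
) -> tuple[SessionRecord, GroundTruth]:
    """Simulate the isoglycaemic intravenous session paired to ``target``."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    schedule, truth = derive_igivi_infusion(subject, phys, target)
    session = _sample_session(truth, subject, "igivi", schedule, cfg, rng)
    return session, truth


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

#: group-level means for profile and physiology draws
GROUP_DEFAULTS = {
    "NGT": dict(weight=152.4, bmi=53.7, age=46.0, basal_glucose=5.35,
                basal_cpeptide=1.0, s_i_iv=1.2e-4, beta=120.0, kd=600.0),
    "IGT": dict(weight=135.3, bmi=49.1, age=41.1, basal_glucose=4.9,
                basal_cpeptide=1.1, s_i_iv=7.5e-5, beta=90.0, kd=450.0),
    "T2D": dict(weight=153.6, bmi=53.0, age=46.7, basal_glucose=7.1,
                basal_cpeptide=1.2, s_i_iv=5.3e-5, beta=55.0, kd=280.0),
}


def default_physiology(group: str = "NGT", **overrides) -> TruePhysiology:
    """Group-typical physiology (means of the cohort draws)."""
    g = GROUP_DEFAULTS[group]
    params = dict(s_i_iv=g["s_i_iv"],
                  beta_true=(g["beta"],) * 3, kd_true=(g["kd"],) * 3)
    params.update(overrides)
    return TruePhysiology(**params)


def _draw_subject(group: str, idx: int, cfg: CohortConfig,
                  rng: np.random.Generator,
                  phys_overrides: dict) -> tuple[SubjectProfile, TruePhysiology]:
    g = GROUP_DEFAULTS[group]
    cv = cfg.between_subject_cv

    def ln(mean: float, cv_: float = cv) -> float:
        if cv_ == 0:
            return mean
        sigma = np.sqrt(np.log(1 + cv_**2))
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    weight = ln(g["weight"], 0.12)
    bmi = max(ln(g["bmi"], 0.08), 30.5)  # study inclusion: BMI > 30
    profile = SubjectProfile(
        subject_id=f"{group}{idx + 1:02d}", group=group,
        age=float(np.clip(rng.normal(g["age"], 8.0), 20, 64)),
        weight=weight, bmi=bmi,
        basal_glucose=ln(g["basal_glucose"], 0.05),
        basal_insulin=0.0,  # filled from equilibrium below
        basal_cpeptide=ln(g["basal_cpeptide"], 0.10),
    )
    phys = default_physiology(
        group,
        s_i_iv=ln(g["s_i_iv"]),
        beta_true=tuple(ln(g["beta"]) for _ in range(3)),
        kd_true=tuple(ln(g["kd"]) for _ in range(3)),
        tau=ln(15.0, 0.1),
        peripheral_clearance=ln(1.25, 0.1),
        **phys_overrides,
    )
    kin = population_kinetics(profile)
    isr_b = kin.basal_isr(profile.basal_cpeptide * 1e3)
    profile.basal_insulin = (1 - phys.hepatic_extraction_oral) * isr_b / phys.peripheral_clearance
    return profile, phys


def simulate_cohort(cfg: CohortConfig, **phys_overrides) -> list[SubjectData]:
    """Simulate the full paired cohort (default 9 NGT + 7 IGT + 7 T2D).

    Reproducible given ``cfg.rng_seed``; each subject draws from a
    counter-derived substream so cohort composition changes do not
    perturb other subjects.
    """
    out = []
    counter = 0
    for group, n in zip(("NGT", "IGT", "T2D"), cfg.n_per_group):
        for i in range(n):
            rng = np.random.default_rng([cfg.rng_seed, counter])
            subject, phys = _draw_subject(group, i, cfg, rng, phys_overrides)
            oral, oral_truth = simulate_oral_session(subject, phys, cfg, rng)
            igivi, igivi_truth = simulate_igivi_session(subject, phys, cfg,
                                                        oral_truth, rng)
            out.append(SubjectData(subject, phys, oral, oral_truth,
                                   igivi, igivi_truth))
            counter += 1
    return out
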