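"""Domain types, unit conventions, I/O and curve utilities.

The study design represented here is a paired two-session protocol in
severely obese participants: a triple sequential oral glucose tolerance
test (25 g at t=0, 75 g at t=120 min, 100 g at t=240 min, each spiked
with 0.9 g of [U-13C6]glucose) and, on a separate day, an isoglycaemic
intravenous glucose infusion (IGIVI) of 20% dextrose enriched ~2.5% with
[6,6-2H2]glucose that reproduces the oral session's glycaemic profile.
[6,6-2H2]glucose is infused in both sessions (22 umol/kg prime,
0.22 umol kg-1 min-1) after a 2.5 h basal equilibration.

Time conventions: t=0 is the first glucose load; the basal tracer
equilibration period occupies [-150, 0] min. Plasma glucose is sampled
every 10 min on [0, 360]; hormones and metabolites every 20 min. The
session splits into three 120-min segments ("Time 1/2/3"), one per load.

Units are carried as strings and validated, never silently converted:
glucose mmol/l, insulin pmol/l, C-peptide nmol/l, GLP-1 ng/l, fluxes
umol kg-1 min-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GLUCOSE_MW",
    "CANONICAL_UNITS",
    "SEGMENTS",
    "GlucorouteError",
    "ValidationError",
    "UnitError",
    "NumericsError",
    "SubjectProfile",
    "SamplingSeries",
    "TracerSeries",
    "InfusionSchedule",
    "SessionRecord",
    "Segment",
    "read_session",
    "write_session",
    "auc",
    "smooth_and_differentiate",
    "smoothing_spline",
]

#: molar mass of glucose, g/mol
GLUCOSE_MW = 180.156

#: canonical unit string per analyte; I/O rejects anything else
CANONICAL_UNITS = {
    "glucose": "mmol/l",
    "insulin": "pmol/l",
    "cpeptide": "nmol/l",
    "glp1": "ng/l",
    "glucagon": "ng/l",
    "ttr_d2": "ratio",
    "ttr_c13": "ratio",
}

#: default unit attached to metabolite series
METABOLITE_UNIT = "mmol/l"


class GlucorouteError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GlucorouteError):
    """Input data violates a structural invariant."""


class UnitError(ValidationError):
    """An analyte arrived with a non-canonical unit string."""


class NumericsError(GlucorouteError):
    """A numerical procedure failed (ODE, optimiser, controller)."""


@dataclass(frozen=True)
class Segment:
    """One of the three 120-min sub-experiments (Time 1/2/3)."""

    index: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValidationError(f"segment index must be 1..3, got {self.index}")

    @property
    def start(self) -> float:
        return self.window[0]

    @property
    def end(self) -> float:
        return self.window[1]


#: the fixed segment boundaries of the protocol
SEGMENTS: tuple[Segment, Segment, Segment] = (
    Segment(1, (0.0, 120.0)),
    Segment(2, (120.0, 240.0)),
    Segment(3, (240.0, 360.0)),
)


@dataclass
class SubjectProfile:
    """Anthropometrics and fasting (basal) levels for one participant.

    ``group`` is the glycaemic status: normal glucose tolerance (NGT),
    impaired glucose tolerance (IGT) or type 2 diabetes (T2D). Basal
    values are the fasting concentrations the analysis anchors to.
    """

    subject_id: str
    group: str
    age: float
    weight: float  # kg
    bmi: float  # kg/m^2
    basal_glucose: float  # mmol/l
    basal_insulin: float  # pmol/l
    basal_cpeptide: float  # nmol/l

    def __post_init__(self) -> None:
        if self.group not in ("NGT", "IGT", "T2D"):
            raise ValidationError(f"unknown glycaemic group {self.group!r}")
        if self.weight <= 0:
            raise ValidationError("weight must be positive")
        if self.bmi <= 0:
            raise ValidationError("bmi must be positive")
        for name in ("basal_glucose", "basal_insulin", "basal_cpeptide"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def height_m(self) -> float:
        """Height implied by weight and BMI."""
        return float(np.sqrt(self.weight / self.bmi))

    @property
    def bsa(self) -> float:
        """Body surface area (m^2), Du Bois formula."""
        h_cm = self.height_m * 100.0
        return 0.007184 * self.weight**0.425 * h_cm**0.725

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": float(self.age),
            "weight": float(self.weight),
            "bmi": float(self.bmi),
            "basal_glucose": float(self.basal_glucose),
            "basal_insulin": float(self.basal_insulin),
            "basal_cpeptide": float(self.basal_cpeptide),
        }


@dataclass
class SamplingSeries:
    """A sampled concentration time course for one analyte.

    Times are minutes relative to the first glucose load; basal samples
    sit at t <= 0. Values must be non-negative and times strictly
    increasing.
    """

    analyte: str
    unit: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError(f"{self.analyte}: times/values shape mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.analyte}: non-monotone times")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.analyte}: negative concentration")

    def basal(self) -> float:
        """Basal level: mean of all samples at t <= 0."""
        mask = self.times <= 0
        if not mask.any():
            raise ValidationError(f"{self.analyte}: no basal (t<=0) samples")
        return float(self.values[mask].mean())

    def interp(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation onto arbitrary times (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < self.times[0] or t.max() > self.times[-1]):
            raise ValidationError(
                f"{self.analyte}: interpolation outside sampled range"
            )
        return np.interp(t, self.times, self.values)

    def window(self, t0: float, t1: float) -> "SamplingSeries":
        """Sub-series on [t0, t1] with linearly interpolated endpoints."""
        inside = (self.times > t0) & (self.times < t1)
        t = np.concatenate(([t0], self.times[inside], [t1]))
        v = np.concatenate(([self.interp(t0)], self.values[inside], [self.interp(t1)]))
        return SamplingSeries(self.analyte, self.unit, t, v)


@dataclass
class TracerSeries:
    """Tracer-to-tracee ratio (TTR) time course for one labeled species.

    ``species`` is "D2" ([6,6-2H2]glucose, m/z 202/200) or "C13"
    ([U-13C6]glucose, m/z 205/200). A mean plateau TTR below 1% marks
    the series low-quality (the assay's enrichment floor), without
    rejecting it.
    """

    species: str
    times: np.ndarray
    ttr: np.ndarray

    def __post_init__(self) -> None:
        if self.species not in ("D2", "C13"):
            raise ValidationError(f"unknown tracer species {self.species!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.ttr = np.asarray(self.ttr, dtype=float)
        if self.times.shape != self.ttr.shape or self.times.ndim != 1:
            raise ValidationError("tracer times/ttr shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"ttr_{self.species.lower()}: non-monotone times")
        if np.any(self.ttr < 0):
            raise ValidationError("negative TTR")
        if np.any(self.ttr >= 0.2):
            raise ValidationError("TTR >= 0.2: outside tracer assumption")

    @property
    def low_enrichment(self) -> bool:
        """True when the mean TTR over t>=0 falls below the 1% gate."""
        mask = self.times >= 0
        return bool(self.ttr[mask].mean() < 0.01)

    def as_series(self) -> SamplingSeries:
        return SamplingSeries(
            f"ttr_{self.species.lower()}", "ratio", self.times, self.ttr
        )


@dataclass
class InfusionSchedule:
    """Everything infused or ingested during one session.

    ``tracer_prime`` / ``tracer_rate`` describe the primed-constant
    [6,6-2H2]glucose infusion common to both sessions. Oral sessions
    carry ``oral_loads`` (time min, dose g, tracer g); IGIVI sessions
    carry the piecewise-constant variable dextrose infusion
    (``dextrose_times`` breakpoints every 10 min, ``dextrose_rates`` in
    umol kg-1 min-1) whose label enrichment is ``dextrose_enrichment``.
    """

    tracer_prime: float = 22.0  # umol/kg
    tracer_rate: float = 0.22  # umol kg-1 min-1
    oral_loads: tuple[tuple[float, float, float], ...] = ()
    dextrose_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    dextrose_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    dextrose_enrichment: float = 0.025

    def __post_init__(self) -> None:
        self.dextrose_times = np.asarray(self.dextrose_times, dtype=float)
        self.dextrose_rates = np.asarray(self.dextrose_rates, dtype=float)
        self.oral_loads = tuple(tuple(float(x) for x in load) for load in self.oral_loads)
        if self.dextrose_times.size != self.dextrose_rates.size:
            raise ValidationError("dextrose breakpoints/rates length mismatch")
        if len(self.oral_loads) and self.dextrose_rates.size:
            raise ValidationError("a session is oral or intravenous, not both")
        if np.any(self.dextrose_rates < 0):
            raise ValidationError("negative dextrose rate")
        for t, dose, tracer in self.oral_loads:
            if dose <= 0 or tracer < 0 or tracer > dose:
                raise ValidationError(f"invalid oral load ({t}, {dose}, {tracer})")

    @classmethod
    def default_oral(cls) -> "InfusionSchedule":
        """The protocol's triple load: 25/75/100 g at 0/120/240 min, 0.9 g label each."""
        return cls(oral_loads=((0.0, 25.0, 0.9), (120.0, 75.0, 0.9), (240.0, 100.0, 0.9)))

    @property
    def route(self) -> str:
        return "oral" if self.oral_loads else "igivi"

    def gir(self, t: np.ndarray | float) -> np.ndarray:
        """Glucose infusion rate (umol kg-1 min-1) at times t (0 before start)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if not self.dextrose_times.size:
            return np.zeros_like(t)
        idx = np.searchsorted(self.dextrose_times, t, side="right") - 1
        out = np.where(idx >= 0, self.dextrose_rates[np.clip(idx, 0, None)], 0.0)
        return out

    def label_infusion_rate(self, t: np.ndarray | float) -> np.ndarray:
        """[6,6-2H2] label delivery per kg: constant infusion plus enriched dextrose."""
        return self.tracer_rate + self.dextrose_enrichment * self.gir(t)

    def drink_enrichment(self, t: float) -> float:
        """Oral-label enrichment z_drink = tracer_g/dose_g of the load covering t."""
        for start, dose, tracer in reversed(sorted(self.oral_loads)):
            if t >= start:
                return tracer / dose
        raise ValidationError(f"no oral load covers t={t}")

    def to_dict(self) -> dict:
        return {
            "tracer_prime": float(self.tracer_prime),
            "tracer_rate": float(self.tracer_rate),
            "oral_loads": [[float(x) for x in l] for l in self.oral_loads],
            "dextrose_times": [float(x) for x in self.dextrose_times],
            "dextrose_rates": [float(x) for x in self.dextrose_rates],
            "dextrose_enrichment": float(self.dextrose_enrichment),
        }


@dataclass
class SessionRecord:
    """One subject-session: concentrations, tracers, infusions.

    ``route`` is "oral" or "igivi"; oral sessions must carry the
    [U-13C6] tracer series and loads, intravenous ones the dextrose
    schedule and no oral tracer.
    """

    subject: SubjectProfile
    route: str
    glucose: SamplingSeries
    insulin: SamplingSeries
    cpeptide: SamplingSeries
    glp1: SamplingSeries | None
    glucagon: SamplingSeries | None
    metabolites: dict[str, SamplingSeries]
    tracers: dict[str, TracerSeries]
    infusions: InfusionSchedule

    def __post_init__(self) -> None:
        if self.route not in ("oral", "igivi"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.route == "oral":
            if not self.infusions.oral_loads:
                raise ValidationError("oral session without oral loads")
            if "C13" not in self.tracers:
                raise ValidationError("oral session without [U-13C6] tracer series")
        else:
            if not self.infusions.dextrose_rates.size:
                raise ValidationError("IGIVI session without dextrose schedule")
            if "C13" in self.tracers:
                raise ValidationError("IGIVI session must not carry a C13 series")
        for name, series in (("glucose", self.glucose), ("insulin", self.insulin),
                             ("cpeptide", self.cpeptide)):
            expected = CANONICAL_UNITS[name]
            if series.unit != expected:
                raise UnitError(f"{name}: expected unit {expected!r}, got {series.unit!r}")
            if not (series.times <= 0).any():
                raise ValidationError(f"{name}: missing basal samples")


# ---------------------------------------------------------------------------
# I/O: long-format CSV (time_min, analyte, value, unit) + sidecar YAML
# ---------------------------------------------------------------------------

_CORE_ANALYTES = ("glucose", "insulin", "cpeptide", "glp1", "glucagon")


def _series_from_frame(df: pd.DataFrame, analyte: str, unit: str) -> SamplingSeries:
    sub = df[df["analyte"] == analyte]
    bad = sub[sub["unit"] != unit]
    if len(bad):
        raise UnitError(
            f"{analyte}: expected unit {unit!r}, got {bad['unit'].iloc[0]!r}"
        )
    return SamplingSeries(analyte, unit, sub["time_min"].to_numpy(),
                          sub["value"].to_numpy())


def read_session(path: str | Path, sidecar: str | Path | None = None) -> SessionRecord:
    """Read one session from a long-format CSV and its sidecar YAML.

    The CSV has columns ``time_min, analyte, value, unit``; rows with
    analyte ``ttr_d2`` / ``ttr_c13`` are the tracer enrichments, the
    core analytes are ``glucose, insulin, cpeptide, glp1, glucagon``,
    and every other analyte name is treated as a metabolite. The
    sidecar (default: same stem with ``.yaml``) holds the subject
    profile, route and infusion schedule.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_min", "analyte", "value", "unit"}
    if not required.issubset(df.columns):
        raise ValidationError(f"session CSV must have columns {sorted(required)}")

    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    subject = SubjectProfile(**meta["subject"])
    inf = meta.get("infusions", {})
    infusions = InfusionSchedule(
        tracer_prime=inf.get("tracer_prime", 22.0),
        tracer_rate=inf.get("tracer_rate", 0.22),
        oral_loads=tuple(tuple(l) for l in inf.get("oral_loads", [])),
        dextrose_times=np.asarray(inf.get("dextrose_times", []), dtype=float),
        dextrose_rates=np.asarray(inf.get("dextrose_rates", []), dtype=float),
        dextrose_enrichment=inf.get("dextrose_enrichment", 0.025),
    )

    core = {}
    for name in _CORE_ANALYTES:
        if (df["analyte"] == name).any():
            core[name] = _series_from_frame(df, name, CANONICAL_UNITS[name])
        else:
            core[name] = None
    for name in ("glucose", "insulin", "cpeptide"):
        if core[name] is None:
            raise ValidationError(f"session file lacks {name} rows")

    tracers = {}
    for species, col in (("D2", "ttr_d2"), ("C13", "ttr_c13")):
        sub = df[df["analyte"] == col]
        if len(sub):
            tracers[species] = TracerSeries(species, sub["time_min"].to_numpy(),
                                            sub["value"].to_numpy())

    known = set(_CORE_ANALYTES) | {"ttr_d2", "ttr_c13"}
    metabolites = {}
    for name in df.loc[~df["analyte"].isin(known), "analyte"].unique():
        unit = df.loc[df["analyte"] == name, "unit"].iloc[0]
        metabolites[name] = _series_from_frame(df, name, unit)

    return SessionRecord(
        subject=subject,
        route=meta["route"],
        glucose=core["glucose"],
        insulin=core["insulin"],
        cpeptide=core["cpeptide"],
        glp1=core["glp1"],
        glucagon=core["glucagon"],
        metabolites=metabolites,
        tracers=tracers,
        infusions=infusions,
    )


def write_session(session: SessionRecord, path: str | Path,
                  sidecar: str | Path | None = None) -> None:
    """Write a session to long-format CSV + sidecar YAML (see read_session)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    rows = []

    def emit(series: SamplingSeries | None) -> None:
        if series is None:
            return
        for t, v in zip(series.times, series.values):
            rows.append((t, series.analyte, repr(float(v)), series.unit))

    emit(session.glucose)
    emit(session.insulin)
    emit(session.cpeptide)
    emit(session.glp1)
    emit(session.glucagon)
    for tr in session.tracers.values():
        emit(tr.as_series())
    for series in session.metabolites.values():
        emit(series)
    df = pd.DataFrame(rows, columns=["time_min", "analyte", "value", "unit"])
    df.to_csv(path, index=False)

    meta = {
        "subject": session.subject.to_dict(),
        "route": session.route,
        "infusions": session.infusions.to_dict(),
    }
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Curve utilities
# ---------------------------------------------------------------------------

def auc(series: SamplingSeries, window: tuple[float, float],
        incremental: bool = False, floor: bool = False) -> float:
    """Trapezoidal area under a sampled curve over ``window``.

    Endpoints not on the sampling grid are linearly interpolated. The
    incremental variant subtracts basal x window-length and may be
    negative unless ``floor`` is set.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("empty AUC window")
    sub = series.window(t0, t1)
    if sub.times.size < 2:
        raise ValidationError("fewer than 2 samples in AUC window")
    total = float(np.trapezoid(sub.values, sub.times))
    if incremental:
        total -= series.basal() * (t1 - t0)
        if floor:
            total = max(total, 0.0)
    return total


def smoothing_spline(times: np.ndarray, values: np.ndarray, lam: float = 0.0):
    """Cubic smoothing spline (scipy); lam=0 interpolates the data."""
    return make_smoothing_spline(np.asarray(times, float),
                                 np.asarray(values, float), lam=lam)


def smooth_and_differentiate(
    series: SamplingSeries, lam: float = 0.0, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth a sampled series and return (grid, values, d/dt) on a fine grid.

    A cubic smoothing spline with penalty weight ``lam`` is fitted and
    evaluated, with its analytic first derivative, on a uniform grid
    (default 1 min) spanning the sampled range. ``lam=0`` reproduces an
    interpolating spline.
    """
    if series.times.size < 5:
        raise ValidationError(
            f"{series.analyte}: need >=5 samples to smooth, got {series.times.size}"
        )
    spl = smoothing_spline(series.times, series.values, lam)
    grid = np.arange(series.times[0], series.times[-1] + 0.5 * grid_step, grid_step)
    grid = np.clip(grid, series.times[0], series.times[-1])
    return grid, spl(grid), spl.derivative()(grid)
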