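"""Insulin-driven metabolite disappearance and cohort feature assembly.

During sustained hyperinsulinaemia, circulating amino acids, lactate
and non-esterified fatty acids fall roughly exponentially; the decay
coefficient beta of C(t) = C0 exp(-beta t) summarises how effectively
insulin clears each metabolite, and dividing beta by the session-mean
insulin gives a per-unit-insulin efficacy that can be compared between
routes at unequal insulin exposure. Coefficients from independent fits
are compared with a Z test on their standard errors. For cohort-level
views, per-metabolite percentage changes (final vs baseline) and a
row-z-scored matrix over (group x procedure x segment) cells feed the
heat-map / classifier stages, which run through standard library
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit

from .data_model import SamplingSeries, ValidationError, auc

__all__ = ["DecayFit", "FeatureMatrix", "fit_decay", "normalize_beta",
           "ztest_betas", "percent_delta", "heatmap_matrix"]


@dataclass
class DecayFit:
    """Exponential-disappearance fit C(t) = C0 exp(-beta (t - t0))."""

    c0: float
    beta: float  # 1/min
    beta_se: float
    window: tuple[float, float]
    residual_rms: float

    def normalized(self, mean_insulin: float) -> float:
        """beta per pmol/l of insulin exposure."""
        return self.beta / mean_insulin


@dataclass
class FeatureMatrix:
    """Row-z-scored metabolite matrix over (group x procedure x segment)."""

    frame: pd.DataFrame  # rows metabolites, 18 columns group_procedure_segment
    raw: pd.DataFrame
    convention: str  # "sample" (ddof=1) or "population" (ddof=0)
    linkage: np.ndarray | None


def fit_decay(series: SamplingSeries, window: tuple[float, float] = (0.0, 360.0),
              from_peak: bool = False, sigma: float | None = None) -> DecayFit:
    """Fit a decaying exponential to one metabolite time course.

    The default window is the full 0-360 min record; ``from_peak``
    starts the fit at the series maximum inside the window instead.
    Requires at least 4 strictly positive samples. When the
    measurement SD is known, pass it as ``sigma`` so the coefficient
    standard error is exact rather than estimated from the residuals.
    """
    t0, t1 = window
    m = (series.times >= t0) & (series.times <= t1)
    t = series.times[m]
    c = series.values[m]
    if from_peak and c.size:
        k = int(np.argmax(c))
        t, c = t[k:], c[k:]
        t0 = float(t[0]) if t.size else t0
    if t.size < 4:
        raise ValidationError(f"{series.analyte}: need >=4 samples to fit decay")
    if np.any(c <= 0):
        raise ValidationError(f"{series.analyte}: non-positive values in decay window")

    # log-linear start, then proper nonlinear fit with SE from the Jacobian
    slope, intercept = np.polyfit(t - t0, np.log(c), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))

    def model(tt, c0, beta):
        return c0 * np.exp(-beta * (tt - t0))

    if sigma is not None:
        popt, pcov = curve_fit(model, t, c, p0=p0, maxfev=10000,
                               sigma=np.full_like(c, sigma), absolute_sigma=True)
    else:
        popt, pcov = curve_fit(model, t, c, p0=p0, maxfev=10000)
    resid = c - model(t, *popt)
    return DecayFit(
        c0=float(popt[0]), beta=float(popt[1]),
        beta_se=float(np.sqrt(max(pcov[1, 1], 0.0))),
        window=(float(t0), float(t1)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def normalize_beta(fit: DecayFit, insulin: SamplingSeries) -> float:
    """Decay coefficient per unit insulin: beta / mean insulin over the window."""
    t0, t1 = fit.window
    mean_i = auc(insulin, (t0, t1)) / (t1 - t0)
    if mean_i <= 0:
        raise ValidationError("non-positive mean insulin")
    return fit.beta / mean_i


def ztest_betas(fit_a: DecayFit, fit_b: DecayFit) -> tuple[float, float]:
    """Two-sided Z test comparing two independent decay coefficients."""
    se = np.sqrt(fit_a.beta_se**2 + fit_b.beta_se**2)
    if se == 0:
        raise ValidationError("zero standard errors: Z test undefined")
    z = (fit_a.beta - fit_b.beta) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def percent_delta(series: SamplingSeries) -> float:
    """Percentage change: 100 (C_final - C_baseline) / C_baseline.

    C_final is the last sample, C_baseline the basal (t <= 0) mean.
    """
    base = series.basal()
    if base == 0:
        raise ValidationError(f"{series.analyte}: zero baseline")
    return 100.0 * (series.values[-1] - base) / base


def heatmap_matrix(cell_means: pd.DataFrame,
                   significant: dict[str, bool] | None = None,
                   convention: str = "sample",
                   cluster_rows: bool = True) -> FeatureMatrix:
    """Assemble the row-z-scored (group x procedure x segment) matrix.

    ``cell_means`` is long format with columns ``metabolite, group,
    procedure, segment, value`` (per-cell means over subjects);
    ``significant`` filters rows to metabolites flagged by the external
    mixed-effects stage (flags arrive as input, the model itself is out
    of the assembly's hands). Rows are z-scored across the 18 columns
    with sample SD by default and ordered by hierarchical clustering
    (average linkage on Euclidean distance).
    """
    required = {"metabolite", "group", "procedure", "segment", "value"}
    if not required.issubset(cell_means.columns):
        raise ValidationError(f"cell_means must have columns {sorted(required)}")
    df = cell_means.copy()
    if significant is not None:
        keep = [m for m, flag in significant.items() if flag]
        df = df[df["metabolite"].isin(keep)]
    if df.empty:
        raise ValidationError("no metabolites left to assemble")
    df["column"] = (df["group"].astype(str) + "_" + df["procedure"].astype(str)
                    + "_segment" + df["segment"].astype(str))
    wide = df.pivot_table(index="metabolite", columns="column", values="value")
    ddof = 1 if convention == "sample" else 0
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=ddof)
    z = wide.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)

    link = None
    if cluster_rows and len(z) > 2:
        link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
        z = z.iloc[order]
        wide = wide.iloc[order]
    return FeatureMatrix(frame=z, raw=wide, convention=convention, linkage=link)
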