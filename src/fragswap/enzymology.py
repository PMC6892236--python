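"""Quantitative characterization of wild-type and hybrid xylanases.

Covers the full bench-side math for a fragment-swap campaign: reducing
sugar assay units, Michaelis–Menten fitting by double-reciprocal
(Lineweaver–Burk) regression or direct nonlinear least squares, kcat and
catalytic-efficiency derivation, thermal T50 (logistic residual-activity
curve) and first-order inactivation half-life fits, fold-change summaries
against a reference enzyme, and degree-of-synergy analysis of
xylanase + cellulase co-hydrolysis timecourses.

Units follow polysaccharide-substrate convention throughout: substrate in
mg/mL (xylan has no molarity), Vmax in umol/min/mg, kcat in /s,
kcat/Km in mL/s/mg, specific activity in U/mg where
1 U = 1 umol xylose equivalents released per minute.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError, InputError
from .formats_io import AssayTable

AVERAGE_RESIDUE_MASS_DA = 110.0  # rule-of-thumb average amino-acid residue mass


# ---------------------------------------------------------------------------
# units and arithmetic


def activity_units(released_umol: float, minutes: float, enzyme_mg: float) -> float:
    """Specific activity in U/mg: umol xylose equivalents / min / mg enzyme."""
    if released_umol <= 0 or minutes <= 0 or enzyme_mg <= 0:
        raise DomainError("activity_units needs strictly positive inputs")
    return released_umol / minutes / enzyme_mg


def kcat_from_vmax(vmax: float, mw_kda: float) -> float:
    """Turnover number (/s) from Vmax (umol/min/mg) and protein mass (kDa).

    umol/min/mg x kDa = umol substrate / min / umol enzyme; divide by 60
    for per-second.
    """
    if vmax <= 0 or mw_kda <= 0:
        raise DomainError("kcat_from_vmax needs strictly positive inputs")
    return vmax * mw_kda / 60.0


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km in mL/s/mg for mass-concentration substrates."""
    if km <= 0:
        raise DomainError("Km must be positive")
    if kcat < 0:
        raise DomainError("kcat must be non-negative")
    return kcat / km


def percent_change(treated: float, reference: float) -> float:
    """(treated - reference) / reference x 100."""
    if reference <= 0:
        raise DomainError("reference must be positive")
    return (treated - reference) / reference * 100.0


def molecular_weight_kda(protein_seq: str) -> float:
    """Rough mature-protein mass from average residue masses (+ water)."""
    if not protein_seq:
        raise InputError("empty sequence")
    return (len(protein_seq) * AVERAGE_RESIDUE_MASS_DA + 18.0) / 1000.0


# ---------------------------------------------------------------------------
# Michaelis-Menten


@dataclass
class KineticsFit:
    """One characterization-table row with fit diagnostics."""

    km: float  # mg/mL
    vmax: float  # umol/min/mg
    method: Literal["lineweaver_burk", "nonlinear"]
    r_squared: float
    se: dict[str, float] = field(default_factory=dict)
    kcat: float | None = None  # /s
    kcat_over_km: float | None = None  # mL/s/mg
    specific_activity: float | None = None  # U/mg
    name: str = ""

    def with_derived(self, mw_kda: float, specific_activity: float | None = None) -> "KineticsFit":
        """Fill kcat and kcat/Km from a molecular weight (kDa)."""
        self.kcat = kcat_from_vmax(self.vmax, mw_kda)
        self.kcat_over_km = catalytic_efficiency(self.kcat, self.km)
        if specific_activity is not None:
            self.specific_activity = specific_activity
        return self


def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    data: AssayTable,
    method: Literal["lineweaver_burk", "nonlinear"] = "lineweaver_burk",
) -> KineticsFit:
    """Estimate (Km, Vmax) from a substrate-vs-rate table.

    ``lineweaver_burk`` regresses 1/v on 1/[S] by ordinary least squares
    (Km = slope/intercept, Vmax = 1/intercept); ``nonlinear`` fits
    v = Vmax [S] / (Km + [S]) directly, initialized from the LB estimate.
    """
    if data.kind != "kinetics":
        raise InputError("expected a kinetics assay table")
    s = data.column("substrate_mg_per_mL")
    v = data.column("rate")
    if len(np.unique(s)) < 4:
        raise FitError("need >= 4 distinct substrate concentrations")
    if np.any(v <= 0):
        raise DomainError("non-positive rate: cannot fit (reciprocal undefined)")
    lb = stats.linregress(1.0 / s, 1.0 / v)
    if lb.intercept <= 0:
        raise FitError("Lineweaver-Burk intercept <= 0: data inconsistent with saturation kinetics")
    vmax_lb = 1.0 / lb.intercept
    km_lb = lb.slope / lb.intercept
    if km_lb <= 0 or math.isclose(km_lb, 0.0, abs_tol=1e-12):
        warnings.warn("fitted Km at/below zero: rates look saturated at all [S]", stacklevel=2)
        km_lb = max(km_lb, 0.0)

    if method == "lineweaver_burk":
        n = len(s)
        resid = 1.0 / v - (lb.intercept + lb.slope / s)
        se = {
            "slope": float(lb.stderr),
            "intercept": float(lb.intercept_stderr),
        }
        r2 = float(lb.rvalue**2)
        return KineticsFit(km=float(km_lb), vmax=float(vmax_lb), method=method, r_squared=r2, se=se)

    if method != "nonlinear":
        raise InputError(f"unknown method {method!r}")
    p0 = [max(vmax_lb, np.max(v)), max(km_lb, 1e-6)]
    try:
        # assay noise scales with the rate (constant CV), so minimize
        # relative residuals rather than absolute ones
        popt, pcov = optimize.curve_fit(_michaelis_menten, s, v, p0=p0, sigma=v, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"nonlinear fit failed to converge: {exc}") from exc
    vmax_nl, km_nl = float(popt[0]), float(popt[1])
    if km_nl <= 1e-9:
        warnings.warn("fitted Km at the zero boundary: rates look saturated", stacklevel=2)
    pred = _michaelis_menten(s, *popt)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    perr = np.sqrt(np.diag(pcov))
    se = {"vmax": float(perr[0]), "km": float(perr[1])}
    return KineticsFit(km=km_nl, vmax=vmax_nl, method="nonlinear", r_squared=min(max(r2, 0.0), 1.0), se=se)


# ---------------------------------------------------------------------------
# fold changes


@dataclass(frozen=True)
class FoldChangeSummary:
    folds: dict[str, float]
    min_fold: float  # across non-reference entries
    max_fold: float
    reference: str


def fold_changes(values: Mapping[str, float], reference: str) -> FoldChangeSummary:
    """Per-enzyme fold change of any scalar metric relative to a reference."""
    if reference not in values:
        raise InputError(f"reference {reference!r} not in table")
    ref = values[reference]
    if ref == 0:
        raise DomainError("reference value is zero")
    folds = {name: val / ref for name, val in values.items()}
    others = [f for name, f in folds.items() if name != reference]
    if not others:
        raise InputError("no non-reference entries")
    return FoldChangeSummary(folds=folds, min_fold=min(others), max_fold=max(others), reference=reference)


# ---------------------------------------------------------------------------
# thermal fits


@dataclass
class ThermalSummary:
    """T50 and half-life are fitted; Tm is an external calorimetric datum
    recorded as-is and never computed here."""

    t50_c: float | None = None
    t50_slope_c: float | None = None
    t50_r_squared: float | None = None
    t_half_h: float | None = None
    decay_rate_per_h: float | None = None
    decay_r_squared: float | None = None
    tm_c: float | None = None


def _logistic_residual(t, t50, s):
    return 100.0 / (1.0 + np.exp((t - t50) / s))


def fit_t50(data: AssayTable, model: Literal["logistic", "interpolate"] = "logistic") -> ThermalSummary:
    """Temperature of half-maximal residual activity after fixed heating.

    Default: least-squares fit of R(T) = 100 / (1 + exp((T - T50)/s)) on
    the percent scale.  ``model="interpolate"`` is the model-free
    fallback: linear interpolation of the 50% crossing.
    """
    if data.kind != "thermal_T50":
        raise InputError("expected a thermal_T50 assay table")
    temp = data.column("temperature_C")
    resid = data.column("residual_pct")
    if len(temp) < 5 and model == "logistic":
        raise FitError("need >= 5 temperature points spanning the transition")
    if resid.min() > 50.0 or resid.max() < 50.0:
        raise FitError("residual activity never crosses 50% in the assayed range")
    t50_guess = float(np.interp(50.0, resid[::-1], temp[::-1]))
    if model == "interpolate":
        return ThermalSummary(t50_c=t50_guess)
    popt, pcov = optimize.curve_fit(
        _logistic_residual, temp, resid, p0=[t50_guess, 2.0],
        bounds=([temp.min() - 50.0, 1e-6], [temp.max() + 50.0, 1e3]), maxfev=20000,
    )
    t50, slope = float(popt[0]), float(popt[1])
    if not temp.min() <= t50 <= temp.max():
        raise FitError(f"fitted T50 {t50:.2f} degC falls outside the assayed range")
    pred = _logistic_residual(temp, *popt)
    ss_res = float(np.sum((resid - pred) ** 2))
    ss_tot = float(np.sum((resid - np.mean(resid)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ThermalSummary(t50_c=t50, t50_slope_c=slope, t50_r_squared=min(max(r2, 0.0), 1.0))


def fit_half_life(data: AssayTable) -> ThermalSummary:
    """First-order inactivation: ln R = ln R0 - k t; t1/2 = ln 2 / k."""
    if data.kind != "thermal_decay":
        raise InputError("expected a thermal_decay assay table")
    t = data.column("time_h")
    resid = data.column("residual_pct")
    if len(t) < 3:
        raise FitError("need >= 3 time points")
    if np.any(resid <= 0):
        raise DomainError("residual activity must be positive for a log-linear fit")
    reg = stats.linregress(t, np.log(resid))
    k = -float(reg.slope)
    if k <= 0:
        warnings.warn("no measurable decay (k <= 0); half-life reported as infinity", stacklevel=2)
        return ThermalSummary(t_half_h=math.inf, decay_rate_per_h=k, decay_r_squared=float(reg.rvalue**2))
    return ThermalSummary(
        t_half_h=math.log(2.0) / k,
        decay_rate_per_h=k,
        decay_r_squared=float(reg.rvalue**2),
    )


# ---------------------------------------------------------------------------
# synergy


@dataclass
class SynergyResult:
    time_h: np.ndarray
    ds: np.ndarray  # NaN where the denominator is not positive
    max_ds: float
    time_max_ds: float
    first_time_ds_above_1: float | None


def degree_of_synergy(data: AssayTable, subtract_control: bool = False) -> SynergyResult:
    """DS(t) = Y_both / (Y_cellulase + Y_xylanase) per shared time point.

    Y are reducing-sugar amounts (umol/mL) from simultaneous vs separate
    hydrolysis.  DS > 1 marks synergy beyond additivity.  The raw arms
    are used by default; ``subtract_control`` removes the no-enzyme arm
    first (requires a ``control`` column).
    """
    if data.kind != "synergy":
        raise InputError("expected a synergy assay table")
    t = data.column("time_h")
    y_both = data.column("both").astype(float).copy()
    y_cel = data.column("cellulase_only").astype(float).copy()
    y_xyl = data.column("xylanase_only").astype(float).copy()
    if subtract_control:
        ctrl = data.column("control")
        y_both = y_both - ctrl
        y_cel = y_cel - ctrl
        y_xyl = y_xyl - ctrl
    if np.any(y_both < 0) or np.any(y_cel < 0) or np.any(y_xyl < 0):
        raise DomainError("negative reducing-sugar value")
    denom = y_cel + y_xyl
    ds = np.full_like(denom, np.nan, dtype=float)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn(
            f"DS undefined at {int(np.sum(~ok))} time point(s) with zero single-enzyme yield",
            stacklevel=2,
        )
    ds[ok] = y_both[ok] / denom[ok]
    if not np.any(ok):
        raise DomainError("DS undefined at every time point")
    imax = int(np.nanargmax(ds))
    above = np.where(np.nan_to_num(ds, nan=-np.inf) > 1.0)[0]
    return SynergyResult(
        time_h=t,
        ds=ds,
        max_ds=float(ds[imax]),
        time_max_ds=float(t[imax]),
        first_time_ds_above_1=float(t[above[0]]) if len(above) else None,
    )
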