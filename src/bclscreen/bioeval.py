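"""Downstream assay and pharmacokinetic evaluation formulas.

Collects the quantitative post-screening calculations: viability
normalization against vehicle controls, clonogenic surviving fraction,
tumor-sphere percentage, four-parameter-logistic (4PL) IC50 fitting,
ellipsoid tumor-volume estimation, and non-compartmental pharmacokinetic
analysis (NCA: Cmax, Tmax, AUC by linear trapezoid, terminal slope λz by
best-tail log-linear regression, t½ = ln2/λz, clearance = dose/AUC_inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .exceptions import FitError, InputError

__all__ = [
    "DoseResponse",
    "IC50Fit",
    "PKProfile",
    "NCAResult",
    "TumorMeasurement",
    "four_param_logistic",
    "viability_percent",
    "surviving_fraction",
    "sphere_percent",
    "fit_ic50",
    "tumor_volume",
    "nca",
]


def viability_percent(treated_signal: float, control_signal: float) -> float:
    """Viability as percent of control: 100 · treated / control."""
    if control_signal <= 0:
        raise InputError("control signal must be positive")
    return 100.0 * treated_signal / control_signal


def surviving_fraction(treated_count: float, control_count: float) -> float:
    """Clonogenic surviving fraction: treated colonies / control colonies."""
    if control_count <= 0:
        raise InputError("control colony count must be positive")
    if treated_count < 0:
        raise InputError("treated colony count must be >= 0")
    return treated_count / control_count


def sphere_percent(spheres: float, seeded: float) -> float:
    """Tumor-sphere formation as percent of seeded cells."""
    if seeded <= 0:
        raise InputError("seeded cell count must be positive")
    if spheres < 0:
        raise InputError("sphere count must be >= 0")
    return 100.0 * spheres / seeded


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement in mm, longest axis first."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.length < self.width:
            raise InputError("require length >= width >= 0")


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid tumor volume (mm³): length · width² · π/6."""
    return m.length * m.width**2 * np.pi / 6.0


def four_param_logistic(
    c: np.ndarray, top: float, bottom: float, ic50: float, hill: float
) -> np.ndarray:
    """4PL response: bottom + (top − bottom) / (1 + (c / ic50)^hill)."""
    c = np.asarray(c, float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass(frozen=True)
class DoseResponse:
    """Paired concentrations (µM) and viability (% of control)."""

    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, float)
        v = np.asarray(self.viability, float)
        if c.shape != v.shape or c.ndim != 1:
            raise InputError("concentrations and viability must be 1-D and aligned")
        if np.any(c <= 0):
            raise InputError("concentrations must be positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "viability", v)


@dataclass(frozen=True)
class IC50Fit:
    """4PL fit; ``censored`` carries '> max tested' when 50% is never reached."""

    top: float
    bottom: float
    ic50: float | None
    hill: float
    rss: float
    censored: str | None = None


def fit_ic50(
    data: DoseResponse,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
    midpoint_level: float = 50.0,
) -> IC50Fit:
    """Least-squares 4PL fit of a viability dose-response.

    Requires >= 4 distinct concentrations. If the observed response never
    drops below ``midpoint_level`` (% of control), the IC50 is not
    identifiable within the tested range and is reported censored as
    "> max tested concentration" instead of extrapolated.
    """
    c, v = data.concentrations, data.viability
    if len(np.unique(c)) < 4:
        raise InputError("need >= 4 distinct concentrations")
    if np.min(v) > midpoint_level:
        return IC50Fit(
            top=float(np.max(v)),
            bottom=float(np.min(v)),
            ic50=None,
            hill=np.nan,
            rss=np.nan,
            censored=f"> {np.max(c):g} µM",
        )

    def model(x, *theta):
        params = list(theta)
        top = fix_top if fix_top is not None else params.pop(0)
        bottom = fix_bottom if fix_bottom is not None else params.pop(0)
        log_ic50, hill = params
        return four_param_logistic(x, top, bottom, 10.0**log_ic50, hill)

    p0: list[float] = []
    if fix_top is None:
        p0.append(float(np.max(v)))
    if fix_bottom is None:
        p0.append(float(np.min(v)))
    p0 += [float(np.log10(np.exp(np.mean(np.log(c))))), 1.0]
    try:
        popt, _ = curve_fit(model, c, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"4PL fit failed: {exc}") from exc
    params = list(popt)
    top = fix_top if fix_top is not None else params.pop(0)
    bottom = fix_bottom if fix_bottom is not None else params.pop(0)
    log_ic50, hill = params
    resid = v - model(c, *popt)
    return IC50Fit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        rss=float(resid @ resid),
    )


@dataclass(frozen=True)
class PKProfile:
    """Plasma concentration-time profile after a single dose."""

    times: np.ndarray  # h
    concentrations: np.ndarray
    dose: float  # mg/kg
    route: str = "intraperitoneal"
    conc_unit: str = "uM"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        if t.shape != c.shape or t.ndim != 1:
            raise InputError("times and concentrations must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(c < 0):
            raise InputError("concentrations must be >= 0")
        if self.dose <= 0:
            raise InputError("dose must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental summary; clearance only when MW allows unit conversion."""

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None
    lambda_z: float | None  # 1/h
    t_half: float | None  # h
    n_lambda_z: int | None
    clearance_mL_min_kg: float | None
    clearance_raw: float | None  # dose units / (conc·h) / kg, when MW missing


def _lambda_z_auto(times: np.ndarray, concs: np.ndarray, tmax_idx: int):
    """Best-tail log-linear terminal slope (highest adjusted R², >= 3 points)."""
    cand_idx = np.arange(tmax_idx + 1, len(times))
    if len(cand_idx) < 3:
        raise InputError("need >= 3 points after Tmax for the terminal slope")
    best = None
    for m in range(3, len(cand_idx) + 1):
        tail = cand_idx[-m:]
        ct = concs[tail]
        if np.any(ct <= 0):
            continue
        res = linregress(times[tail], np.log(ct))
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best[0]:
            best = (adj, -res.slope, m)
    if best is None:
        raise InputError("no positive-concentration tail for the terminal slope")
    return best[1], best[2]


def nca(
    profile: PKProfile,
    lambda_z_points: int | str = "auto",
    mw: float | None = None,
) -> NCAResult:
    """Non-compartmental analysis of a single-dose concentration profile.

    Cmax/Tmax are the maximum observed point; AUC_last uses the linear
    trapezoid; λz comes from a log-linear regression on terminal points
    (auto mode picks the tail of >= 3 post-Tmax points with the best
    adjusted R²); AUC_inf = AUC_last + C_last/λz; CL = dose/AUC_inf.
    When λz is not estimable (or non-positive), extrapolation is refused and
    an AUC_last-only result is returned. Clearance in mL/min/kg requires the
    compound molecular weight (g/mol) to convert molar concentrations; with
    ``mw`` omitted it is reported in raw (mg/kg)/(conc·h) units.
    """
    t, c = profile.times, profile.concentrations
    if len(t) < 3:
        raise InputError("need >= 3 samples for NCA")
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = float(np.trapezoid(c, t))

    try:
        if lambda_z_points == "auto":
            lam, n_pts = _lambda_z_auto(t, c, imax)
        else:
            m = int(lambda_z_points)
            if m < 3 or m > len(t) - imax - 1:
                raise InputError("lambda_z_points must cover >= 3 post-Tmax samples")
            tail = np.arange(len(t) - m, len(t))
            ct = c[tail]
            if np.any(ct <= 0):
                raise InputError("non-positive terminal concentrations")
            res = linregress(t[tail], np.log(ct))
            lam, n_pts = -res.slope, m
    except InputError:
        raise
    if lam <= 0:
        return NCAResult(cmax, tmax, auc_last, None, None, None, None, None, None)

    auc_inf = auc_last + float(c[-1]) / lam
    t_half = float(np.log(2.0) / lam)
    cl_raw = profile.dose / auc_inf
    cl_ml_min = None
    if mw is not None and profile.conc_unit in ("uM", "µM"):
        auc_mg_L_h = auc_inf * mw / 1000.0  # µM·h -> mg/L·h
        cl_L_h_kg = profile.dose / auc_mg_L_h
        cl_ml_min = cl_L_h_kg * 1000.0 / 60.0
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=float(auc_inf),
        lambda_z=float(lam),
        t_half=t_half,
        n_lambda_z=int(n_pts),
        clearance_mL_min_kg=cl_ml_min,
        clearance_raw=float(cl_raw),
    )
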