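"""Multi-site Langmuir SPR kinetics under piecewise-constant injection schedules.

The model is a sum of independent 1:1 Langmuir binding sites. For site *i*
with association rate ``ka_i`` (1/(M*s)), dissociation rate ``kd_i`` (1/s)
and capacity ``Rmax_i`` (RU), the bound response obeys::

    dR_i/dt = ka_i * C(t) * (Rmax_i - R_i) - kd_i * R_i,   R(t) = sum_i R_i(t)

with analyte concentration ``C(t)`` held piecewise-constant by the injection
schedule. Within a constant-concentration segment the solution is a
mono-exponential approach to the Langmuir steady state
``Req = Rmax * C / (C + KD)`` with observed rate ``kobs = ka*C + kd``, so the
whole sensorgram is assembled analytically, segment by segment, continuous at
the boundaries. No mass-transport or bulk refractive-index terms are
modelled; solvent correction is assumed to have been applied upstream.

Two schedule presets mirror common experimental designs: a step-gradient
("FastStep") staircase of six doubling analyte concentrations in a single
cycle, and a classic multi-cycle titration with a fixed association window
per concentration.

Fits report per-site (ka, kd, Rmax) with sites ordered by affinity
(``KD_i = kd_i / ka_i`` ascending) and a headline KD equal to the
highest-affinity site's constant, the convention used when a two-site model
is the best description of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, InputError

__all__ = [
    "InjectionSchedule",
    "KineticParams",
    "Sensorgram",
    "KineticFit",
    "build_schedule",
    "simulate_sensorgram",
    "fit_sensorgram",
    "selectivity_index",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """Piecewise-constant analyte concentration program.

    segments : ordered (t_start_s, t_end_s, concentration_M) triples,
        contiguous and strictly increasing in time, starting at t = 0.
    dissociation_s : buffer-only window appended after the last segment.
    flow_uL_min : flow-rate annotation; not used by the kinetic model.
    """

    segments: tuple[tuple[float, float, float], ...]
    dissociation_s: float = 150.0
    flow_uL_min: float = 100.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise InputError("schedule needs at least one segment")
        prev_end = 0.0
        for t0, t1, c in self.segments:
            if t1 <= t0:
                raise InputError(f"segment ({t0}, {t1}) is not increasing")
            if abs(t0 - prev_end) > 1e-9:
                raise InputError(
                    f"segments must be contiguous; gap/overlap at t={t0}"
                )
            if c < 0:
                raise InputError("concentrations must be >= 0")
            prev_end = t1
        if self.dissociation_s < 0:
            raise InputError("dissociation window must be >= 0")

    @property
    def t_end(self) -> float:
        """End of the last injection segment (s)."""
        return self.segments[-1][1]

    @property
    def total_time(self) -> float:
        """End of the dissociation window (s)."""
        return self.t_end + self.dissociation_s

    def with_dissociation(self) -> tuple[tuple[float, float, float], ...]:
        """Segments plus the trailing buffer (C = 0) window."""
        segs = list(self.segments)
        if self.dissociation_s > 0:
            segs.append((self.t_end, self.total_time, 0.0))
        return tuple(segs)

    def concentration_at(self, t: np.ndarray) -> np.ndarray:
        """C(t) in molar; 0 outside the programmed segments."""
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        for t0, t1, conc in self.segments:
            c[(t >= t0) & (t < t1)] = conc
        return c


# FastStep staircase: six doubling steps, 0.625 -> 20 µM, injection ends at
# 165 s, then buffer. Boundaries are placed at contiguous integer seconds.
_FASTSTEP_STEPS = (
    (0.0, 30.0, 0.625e-6),
    (30.0, 60.0, 1.25e-6),
    (60.0, 90.0, 2.5e-6),
    (90.0, 120.0, 5.0e-6),
    (120.0, 150.0, 10.0e-6),
    (150.0, 165.0, 20.0e-6),
)

#: Titration analyte concentrations (M); the 0.3 µM step is used for Mcl-1.
_TITRATION_CONCS_M = (1e-6, 3e-6, 10e-6, 30e-6)
_TITRATION_LOW_M = 0.3e-6


def build_schedule(
    preset: str = "faststep_bcl2",
    *,
    segments: tuple[tuple[float, float, float], ...] | None = None,
    dissociation_s: float | None = None,
    flow_uL_min: float | None = None,
    include_low_concentration: bool = False,
    association_s: float = 180.0,
) -> InjectionSchedule:
    """Build an injection schedule from a named preset or custom segments.

    Presets
    -------
    ``faststep_bcl2``
        Single-cycle step gradient: 0.625 / 1.25 / 2.5 / 5 / 10 / 20 µM in
        30-s steps (final step 15 s), injection ending at 165 s, then a
        buffer dissociation window. Flow 100 µL/min.
    ``titration_bclxl_mcl1``
        Multi-cycle titration at 1, 3, 10, 30 µM with an ``association_s``
        (default 180 s) association phase per concentration, each followed by
        an equal buffer window; ``include_low_concentration`` prepends a
        0.3 µM cycle (used for Mcl-1). Flow 30 µL/min. Cycles are
        concatenated into one schedule; the model carries bound material
        across cycle boundaries rather than assuming regeneration.
    ``custom``
        Uses ``segments`` as given.
    """
    if preset == "faststep_bcl2":
        return InjectionSchedule(
            segments=_FASTSTEP_STEPS,
            dissociation_s=150.0 if dissociation_s is None else dissociation_s,
            flow_uL_min=100.0 if flow_uL_min is None else flow_uL_min,
        )
    if preset == "titration_bclxl_mcl1":
        concs = list(_TITRATION_CONCS_M)
        if include_low_concentration:
            concs.insert(0, _TITRATION_LOW_M)
        segs: list[tuple[float, float, float]] = []
        t = 0.0
        for i, c in enumerate(concs):
            segs.append((t, t + association_s, c))
            t += association_s
            if i < len(concs) - 1:  # inter-cycle buffer; final handled below
                segs.append((t, t + association_s, 0.0))
                t += association_s
        return InjectionSchedule(
            segments=tuple(segs),
            dissociation_s=association_s if dissociation_s is None else dissociation_s,
            flow_uL_min=30.0 if flow_uL_min is None else flow_uL_min,
        )
    if preset == "custom":
        if segments is None:
            raise InputError("custom preset requires segments")
        return InjectionSchedule(
            segments=tuple(segments),
            dissociation_s=150.0 if dissociation_s is None else dissociation_s,
            flow_uL_min=100.0 if flow_uL_min is None else flow_uL_min,
        )
    raise InputError(f"unknown schedule preset: {preset!r}")


@dataclass(frozen=True)
class KineticParams:
    """Per-site Langmuir parameters; arrays indexed by site."""

    ka: tuple[float, ...]  # 1/(M*s)
    kd: tuple[float, ...]  # 1/s
    rmax: tuple[float, ...]  # RU

    def __post_init__(self) -> None:
        if not (len(self.ka) == len(self.kd) == len(self.rmax)):
            raise InputError("ka, kd, rmax must have equal length")
        if len(self.ka) == 0:
            raise InputError("at least one site required")
        for name, vals in (("ka", self.ka), ("kd", self.kd), ("rmax", self.rmax)):
            if any(v <= 0 for v in vals):
                raise InputError(f"all {name} values must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.ka)

    @property
    def kD(self) -> tuple[float, ...]:
        """Equilibrium dissociation constants kd/ka (M) per site."""
        return tuple(d / a for a, d in zip(self.ka, self.kd))

    def sorted_by_affinity(self) -> "KineticParams":
        """Sites reordered so KD_1 <= KD_2 <= ..."""
        order = np.argsort(self.kD)
        return KineticParams(
            ka=tuple(self.ka[i] for i in order),
            kd=tuple(self.kd[i] for i in order),
            rmax=tuple(self.rmax[i] for i in order),
        )


@dataclass(frozen=True)
class Sensorgram:
    """Time-resolved SPR response."""

    times: np.ndarray  # s
    response: np.ndarray  # RU

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise InputError("times and response must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise InputError("responses must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "response", r)


def _segment_response(
    r0: float, ka: float, kd: float, rmax: float, conc: float, t_rel: np.ndarray
) -> np.ndarray:
    """Exact single-site solution over one constant-C segment."""
    kobs = ka * conc + kd
    req = ka * conc * rmax / kobs
    return req + (r0 - req) * np.exp(-kobs * t_rel)


def simulate_sensorgram(
    params: KineticParams,
    schedule: InjectionSchedule,
    sampling_interval: float = 0.5,
) -> Sensorgram:
    """Analytic forward simulation of the multi-site model, R(0) = 0.

    The per-site state is propagated exactly across segment boundaries, so
    the result is the closed-form solution of the ODE system sampled on a
    uniform grid (the final time point is always included).
    """
    if sampling_interval <= 0:
        raise InputError("sampling interval must be > 0")
    total = schedule.total_time
    times = np.arange(0.0, total, sampling_interval)
    if times[-1] < total - 1e-12:
        times = np.append(times, total)
    response = np.zeros_like(times)
    for ka, kd, rmax in zip(params.ka, params.kd, params.rmax):
        r_state = 0.0
        for t0, t1, conc in schedule.with_dissociation():
            mask = (times >= t0) & (times <= t1 if t1 >= total else times < t1)
            response[mask] += _segment_response(
                r_state, ka, kd, rmax, conc, times[mask] - t0
            )
            r_state = float(_segment_response(r_state, ka, kd, rmax, conc, np.array([t1 - t0]))[0])
    return Sensorgram(times=times, response=response)


@dataclass(frozen=True)
class KineticFit:
    """Result of a multi-site kinetic fit.

    ``kd_report`` is the KD of the highest-affinity *non-degenerate* site
    (sites whose fitted Rmax falls below ``degenerate_rmax`` contribute too
    little signal for their rate constants to be meaningful).
    """

    params: KineticParams  # sites ordered by KD ascending
    rss: float
    kd_report: float  # M
    param_se: tuple[float, ...] | None  # approximate SE of log10-params
    n_starts: int
    degenerate_sites: tuple[int, ...] = field(default=())


def _pack(params: KineticParams) -> np.ndarray:
    return np.log10(np.concatenate([params.ka, params.kd, params.rmax]))


def _unpack(theta: np.ndarray, n_sites: int) -> KineticParams:
    # clamp to a huge-but-finite range so LM exploration never overflows
    v = 10.0 ** np.clip(np.asarray(theta, dtype=float), -150.0, 150.0)
    return KineticParams(
        ka=tuple(v[:n_sites]),
        kd=tuple(v[n_sites : 2 * n_sites]),
        rmax=tuple(v[2 * n_sites :]),
    )


def _model_on_times(
    theta: np.ndarray, n_sites: int, schedule: InjectionSchedule, times: np.ndarray
) -> np.ndarray:
    """Forward model evaluated at arbitrary (sorted) observation times."""
    params = _unpack(theta, n_sites)
    total = schedule.total_time
    out = np.zeros_like(times)
    for ka, kd, rmax in zip(params.ka, params.kd, params.rmax):
        r_state = 0.0
        for t0, t1, conc in schedule.with_dissociation():
            mask = (times >= t0) & (times <= t1 if t1 >= total else times < t1)
            if mask.any():
                out[mask] += _segment_response(r_state, ka, kd, rmax, conc, times[mask] - t0)
            r_state = float(
                _segment_response(r_state, ka, kd, rmax, conc, np.array([t1 - t0]))[0]
            )
    return out


def fit_sensorgram(
    data: Sensorgram,
    schedule: InjectionSchedule,
    n_sites: int = 2,
    *,
    n_starts: int = 32,
    seed: int = 0,
    weights: np.ndarray | None = None,
    ka_range: tuple[float, float] = (1e3, 1e7),
    kd_range: tuple[float, float] = (1e-4, 1.0),
    degenerate_rmax_fraction: float = 0.01,
) -> KineticFit:
    """Weighted least-squares fit of the multi-site Langmuir model.

    Multi-start local optimization: ``n_starts`` starting points with rate
    constants drawn log-uniformly over ``ka_range`` x ``kd_range`` and site
    capacities splitting the observed peak response, refined by
    Levenberg-Marquardt in log10-parameter space (which also enforces
    positivity). Sites in the returned fit are ordered by KD ascending; the
    headline KD is the smallest KD among sites whose Rmax exceeds
    ``degenerate_rmax_fraction`` of the peak response. Degenerate sites are
    reported with a warning, not silently dropped.
    """
    if len(data.times) < 10:
        raise InputError("need at least 10 data points to fit")
    if n_sites not in (1, 2):
        raise InputError("n_sites must be 1 or 2")
    w = np.ones_like(data.response) if weights is None else np.asarray(weights, float)
    if w.shape != data.response.shape or np.any(w < 0):
        raise InputError("weights must be non-negative and aligned with data")

    times = data.times
    obs = data.response
    peak = float(np.max(np.abs(obs)))
    if peak <= 0:
        raise InputError("flat zero sensorgram cannot be fitted")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (_model_on_times(theta, n_sites, schedule, times) - obs) * w

    rng = np.random.default_rng(seed)
    la, ua = np.log10(ka_range)
    ld, ud = np.log10(kd_range)
    best = None
    for s in range(n_starts):
        if s == 0:  # deterministic mid-grid start
            ka0 = np.full(n_sites, 10 ** ((la + ua) / 2))
            kd0 = np.full(n_sites, 10 ** ((ld + ud) / 2)) * (
                np.logspace(-0.5, 0.5, n_sites) if n_sites > 1 else 1.0
            )
            frac = np.full(n_sites, 1.0 / n_sites)
        else:
            ka0 = 10 ** rng.uniform(la, ua, n_sites)
            kd0 = 10 ** rng.uniform(ld, ud, n_sites)
            frac = rng.dirichlet(np.ones(n_sites))
        rmax0 = np.maximum(peak * 1.2 * frac, peak * 1e-3)
        theta0 = np.log10(np.concatenate([ka0, kd0, rmax0]))
        try:
            res = least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("no start converged; inspect data and schedule")

    fitted = _unpack(best.x, n_sites).sorted_by_affinity()
    rss = float(2 * best.cost)

    # approximate covariance of log10-params from the local curvature
    m, p = len(obs), len(best.x)
    param_se: tuple[float, ...] | None = None
    if m > p:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * (rss / (m - p))
            # reorder SEs to match affinity-sorted sites
            order = np.argsort(_unpack(best.x, n_sites).kD)
            idx = np.concatenate([order, order + n_sites, order + 2 * n_sites])
            param_se = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0))[idx])
        except np.linalg.LinAlgError:
            param_se = None

    floor = degenerate_rmax_fraction * peak
    degenerate = tuple(i for i, r in enumerate(fitted.rmax) if r < floor)
    if degenerate:
        warnings.warn(
            f"site(s) {degenerate} have Rmax below {floor:.3g} RU; "
            "their rate constants are not identifiable",
            stacklevel=2,
        )
    usable = [kd for i, kd in enumerate(fitted.kD) if i not in degenerate]
    kd_report = min(usable) if usable else min(fitted.kD)

    return KineticFit(
        params=fitted,
        rss=rss,
        kd_report=kd_report,
        param_se=param_se,
        n_starts=n_starts,
        degenerate_sites=degenerate,
    )


def selectivity_index(kd_reference: float, kd_other: float) -> float:
    """Fold-selectivity for the reference target: kd_other / kd_reference.

    Values > 1 mean the compound binds the reference target more tightly
    than the comparison target (e.g. Bcl-2 vs Mcl-1).
    """
    if kd_reference <= 0 or kd_other <= 0:
        raise InputError("dissociation constants must be > 0")
    return kd_other / kd_reference
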