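"""Freezable-water kinetics: the FPD-WF map, Gompertz fit, derivative landmarks.

As ice forms, the unfrozen serum concentrates and its equilibrium freezing
temperature drops.  Treating the mix as a pure sucrose solution of its
sucrose-equivalent concentration SE0, removing a water fraction w leaves a
solution at SE0/(1-w), whose depression the packaged sucrose table gives.
Simulating 14 such levels (w = 5% ... 70%, at most 70% of the water is
considered freezable) and fitting a fourth-order polynomial WF = P(FPD)
yields an invertible map between calibrated temperature and freezable water
fraction WF(t).

The kinetic model is the re-parameterized (Zwietering) Gompertz function

    WF(t) = WFmax * exp(-exp(GRmax*e/WFmax * (lag - t) + 1)),

with asymptote WFmax, maximum growth rate GRmax (fraction/min) and lag time
(the heterogeneous-nucleation time).  With k = GRmax*e/WFmax and
u(t) = exp(k*(lag - t) + 1), derivative analysis gives closed-form landmark
times: maximum acceleration (the effective freezing point IFP_eff) at
u = (3+sqrt(5))/2, maximum rate at u = 1 (the inflection, WF = WFmax/e), and
maximum deceleration (onset of air whipping domination) at u = (3-sqrt(5))/2.
Landmark temperatures come from inverting the FPD-WF map at the landmark WF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .curve_io import CoolingCurve
from .errors import FitError, RangeError, ValidationError
from .formulation import SucroseFpdTable, default_sucrose_table

E = np.e
#: maximum freezable fraction of the initial water
MAX_WF = 0.70
#: number of simulated concentration levels in the FPD-WF map
N_LEVELS = 14
#: fitted-value floor below which points are excluded from the error metric
ERR_EPS = 1e-3

U_ACCEL = (3 + np.sqrt(5)) / 2  # u at maximum acceleration
U_DECEL = (3 - np.sqrt(5)) / 2  # u at maximum deceleration


def gompertz(t, wfmax: float, grmax: float, lag: float):
    """Re-parameterized Gompertz curve WF(t)."""
    z = grmax * E / wfmax * (lag - np.asarray(t, dtype=float)) + 1.0
    with np.errstate(over="ignore"):  # exp overflow far before lag -> WF = 0
        return wfmax * np.exp(-np.exp(z))


@dataclass(frozen=True)
class FpdWfMap:
    """Fourth-order polynomial map WF = P(FPD) built from simulated levels."""

    se0: float
    coeffs: np.ndarray  # highest power first (np.polyval order)
    fpd_levels: np.ndarray
    wf_levels: np.ndarray
    max_wf: float

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.fpd_levels[0]), float(self.fpd_levels[-1])

    @property
    def levels(self) -> np.ndarray:
        """The simulated WF levels (anchor at WF = 0 excluded)."""
        return self.wf_levels[1:]

    def wf(self, fpd) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(fpd, dtype=float))

    def invert(self, wf_value: float) -> float:
        """FPD (degC) at which the polynomial map equals ``wf_value``."""
        lo, hi = self.domain
        if not (self.wf(lo) - 1e-9 <= wf_value <= self.wf(hi) + 1e-9):
            raise RangeError(f"WF {wf_value} outside map range [{self.wf(lo):.4f}, {self.wf(hi):.4f}]")
        return brentq(lambda d: self.wf(d) - wf_value, lo, hi, xtol=1e-12)


def build_fpd_wf_map(
    se0: float,
    table: SucroseFpdTable | None = None,
    max_wf: float = MAX_WF,
    n_levels: int = N_LEVELS,
    order: int = 4,
) -> FpdWfMap:
    """Simulate concentration levels and fit the polynomial FPD-WF map.

    Level j (j = 1..n_levels) removes a water fraction w_j = j*max_wf/n_levels,
    concentrating the solution to SE0/(1-w_j).  The unfrozen state (w = 0,
    FPD(SE0)) is added as an anchor pair so the map starts near zero at the
    initial freezing point.
    """
    if se0 <= 0:
        raise ValidationError("SE0 must be positive")
    tab = table if table is not None else default_sucrose_table()
    wf = np.linspace(0.0, max_wf, n_levels + 1)  # anchor + n_levels simulated levels
    se = se0 / (1.0 - wf)
    try:
        fpd = np.array([tab.fpd(s) for s in se])
    except RangeError as err:
        bad = se[se > tab.domain[1]]
        raise RangeError(
            f"concentrated SE {bad.min():.1f} g/100 g water (level WF={wf[se > tab.domain[1]][0]:.2f}) "
            f"outside sucrose table domain {tab.domain}"
        ) from err
    coeffs = np.polyfit(fpd, wf, order)
    return FpdWfMap(se0, coeffs, fpd, wf, max_wf)


@dataclass(frozen=True)
class WFSeries:
    """Freezable-water-fraction kinetic extracted from a calibrated curve."""

    time: np.ndarray
    wf: np.ndarray
    t_ifp: float
    t_exit: float


def wf_series(
    calibrated: CoolingCurve,
    fpd_map: FpdWfMap,
    t_ifp: float,
    t_exit: float | None = None,
    monotonic: bool = False,
) -> WFSeries:
    """Convert calibrated temperatures in [t_IFP, t_exit] to WF(t).

    FPD = -T_calibrated; the polynomial map is evaluated and clamped to
    [0, max_wf].  Samples warmer than the theoretical freezing point map to
    WF = 0 with a warning.  ``monotonic`` applies a running-maximum cleanup.
    """
    t_end = calibrated.t_exit if t_exit is None else t_exit
    sel = (calibrated.time >= t_ifp) & (calibrated.time <= t_end)
    if not sel.any():
        raise ValidationError("empty [t_IFP, t_exit] window")
    t = calibrated.time[sel]
    fpd = -calibrated.temperature[sel]
    lo, hi = fpd_map.domain
    if np.any(fpd < lo):
        warnings.warn("calibrated temperatures above FPt inside the window; clamping WF to 0")
    wf = np.polyval(fpd_map.coeffs, np.clip(fpd, lo, hi))
    wf = np.clip(wf, 0.0, fpd_map.max_wf)
    if monotonic:
        wf = np.maximum.accumulate(wf)
    return WFSeries(t, wf, float(t_ifp), float(t_end))


def error_pct(
    observed: np.ndarray,
    fitted: np.ndarray,
    eps: float = ERR_EPS,
    root: bool = False,
    denominator: str = "fitted",
) -> float:
    """Lack-of-fit E% of a kinetic fit: mean squared relative error x 100.

    Relative residuals are (fitted - observed)/denominator with the fitted
    value as default denominator; points whose denominator falls below
    ``eps`` are excluded.  ``root=True`` returns the rooted variant instead.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    den = {"fitted": fit, "observed": obs, "max": np.full_like(fit, fit.max())}[denominator]
    keep = den > eps
    if not keep.any():
        raise ValidationError("no points above eps for the error metric")
    rel2 = ((fit[keep] - obs[keep]) / den[keep]) ** 2
    val = rel2.mean()
    return 100.0 * (np.sqrt(val) if root else val)


@dataclass(frozen=True)
class GompertzParams:
    wfmax: float  # asymptote, fraction of initial water
    grmax: float  # maximum rate, fraction/min
    lag: float  # lag (heterogeneous nucleation) time, min
    e_pct: float  # lack of fit, %

    @property
    def k(self) -> float:
        return self.grmax * E / self.wfmax


def fit_gompertz(
    time: np.ndarray,
    wf: np.ndarray,
    max_wf: float = MAX_WF,
    n_multistart: int = 5,
    seed: int = 0,
) -> GompertzParams:
    """Nonlinear least-squares fit of the re-parameterized Gompertz model.

    Initial values: WFmax from the observed maximum, GRmax from the largest
    finite-difference slope, lag from the first time WF exceeds 5% of the
    observed maximum; on failure the start point is jittered ``n_multistart``
    times before giving up with :class:`FitError`.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(wf, dtype=float)
    if t.size < 10:
        raise ValidationError("need at least 10 points to fit the Gompertz model")
    if y.max() - y.min() < 1e-6 or y.max() <= 0:
        raise FitError("WF series has no sigmoidal rise (constant or empty signal)")
    wf0 = min(max(y.max(), 1e-3), max_wf)
    slopes = np.diff(y) / np.diff(t)
    gr0 = max(float(slopes.max()), 1e-4)
    above = np.nonzero(y > 0.05 * y.max())[0]
    lag0 = float(t[above[0]]) if above.size else float(t[0])
    bounds = ([1e-6, 1e-6, -np.inf], [max_wf, np.inf, np.inf])
    rng = np.random.default_rng(seed)
    start = np.array([wf0, gr0, lag0])
    last_err: Exception | None = None
    for trial in range(n_multistart + 1):
        p0 = start if trial == 0 else start * rng.uniform(0.5, 1.5, size=3)
        p0 = np.clip(p0, bounds[0], [max_wf, 1e6, t[-1]])
        try:
            popt, _ = curve_fit(gompertz, t, y, p0=p0, bounds=bounds, maxfev=20000)
            fit = gompertz(t, *popt)
            return GompertzParams(*map(float, popt), e_pct=error_pct(y, fit))
        except (RuntimeError, ValueError) as err:
            last_err = err
    raise FitError(f"Gompertz fit failed after {n_multistart + 1} starts: {last_err}")


@dataclass(frozen=True)
class KineticLandmarks:
    """Derivative landmarks of the fitted kinetic, times in min, temps in degC."""

    ifp_eff_time: float
    ifp_eff_temp: float | None
    gr_time: float
    grt: float | None  # temperature at maximum rate
    t_whipp_time: float
    t_whipp_temp: float | None
    fw_max: float  # fitted WF at t_exit
    t_exit: float
    T_exit: float | None
    out_of_window: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "IFP_eff_min": self.ifp_eff_time,
            "IFP_eff_c": self.ifp_eff_temp,
            "GR_time_min": self.gr_time,
            "GRT_c": self.grt,
            "tT_whipp_min": self.t_whipp_time,
            "T_whipp_c": self.t_whipp_temp,
            "FW_max": self.fw_max,
            "t_exit_min": self.t_exit,
            "T_exit_c": self.T_exit,
            "out_of_window": list(self.out_of_window),
        }


def landmark_times(params: GompertzParams) -> tuple[float, float, float]:
    """Closed-form (t_IFP_eff, GR_time, tT_whipp) of the fitted model."""
    k = params.k
    t_accel = params.lag + (1.0 - np.log(U_ACCEL)) / k
    t_infl = params.lag + 1.0 / k
    t_decel = params.lag + (1.0 - np.log(U_DECEL)) / k
    return float(t_accel), float(t_infl), float(t_decel)


def landmarks(
    params: GompertzParams,
    fpd_map: FpdWfMap | None = None,
    t_ifp: float | None = None,
    t_exit: float | None = None,
) -> KineticLandmarks:
    """Derivative landmarks with temperatures recovered through the FPD-WF map.

    Temperatures are read from the fitted smooth model (WF at the landmark
    time, inverted through the map to a calibrated temperature -FPD), not
    from the raw curve, for noise robustness.  Landmarks outside
    [t_ifp, t_exit] are reported but flagged.
    """
    t_accel, t_infl, t_decel = landmark_times(params)

    def temp_at(t: float) -> float | None:
        if fpd_map is None:
            return None
        w = float(gompertz(t, params.wfmax, params.grmax, params.lag))
        lo, hi = fpd_map.domain
        w = float(np.clip(w, fpd_map.wf(lo), fpd_map.wf(hi)))
        return -fpd_map.invert(w)

    flags = []
    for name, tt in (("IFP_eff", t_accel), ("GR_time", t_infl), ("tT_whipp", t_decel)):
        if (t_ifp is not None and tt < t_ifp) or (t_exit is not None and tt > t_exit):
            flags.append(name)
    t_end = t_exit if t_exit is not None else t_decel
    fw_max = float(gompertz(t_end, params.wfmax, params.grmax, params.lag))
    return KineticLandmarks(
        ifp_eff_time=t_accel,
        ifp_eff_temp=temp_at(t_accel),
        gr_time=t_infl,
        grt=temp_at(t_infl),
        t_whipp_time=t_decel,
        t_whipp_temp=temp_at(t_decel),
        fw_max=fw_max,
        t_exit=float(t_end),
        T_exit=temp_at(t_end),
        out_of_window=tuple(flags),
    )
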