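"""Pattern recognition on the cooling curve: chilling line, supercooling, IFP.

A batch freezing run shows a stereotyped anatomy: a steep linear *chilling*
ramp above 0 degC, a slower descent while unstable ice nuclei form, one or
more *supercooling* dips, a rebound to the *initial freezing point* (IFP,
the first equilibrium temperature), a short steady state, and a slow decline
as freeze concentration pushes the equilibrium point down.

Detection is driven by a quadratic departure statistic: with T_CL the
extrapolated chilling line,

    delta(t) = (T_CL(t) - T_exp(t))^2 / max(|T_exp(t)|, eps)   for t > TP1,

which stays near zero while the curve rides the chilling line and grows
rapidly once latent-heat release bends the curve away from it.  The first
threshold crossing (default 10) opens the supercooling window; the IFP is
the highest temperature reached after the first supercooling minimum, with
the time-intercept of a line through the largest delta values bounding the
search window.

The theoretical freezing point FPt computed from composition calibrates the
curve: the probe sits between the cold barrel wall and the warm bulk, so the
measured IFP overestimates the equilibrium value by a roughly constant
offset, removed by shifting the whole profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .curve_io import CoolingCurve, smooth_sg3
from .errors import DetectionError, ValidationError

#: default threshold of the delta statistic opening the supercooling window
DELTA_THRESHOLD = 10.0
#: default number of top delta values in the IFP time-intercept regression
N_TOP_DELTA = 10
#: guard on |T_exp| in the delta denominator, degC
EPS_TEMP = 0.5
#: extra smoothing (samples) applied before local-minimum search
DETECT_SMOOTH_WINDOW = 9
#: minimum dip prominence, degC (the measurement-uncertainty envelope)
DIP_PROMINENCE = 0.2


@dataclass(frozen=True)
class ChillingLine:
    """OLS line fitted to the above-0-degC part of the curve."""

    cl_rate: float  # slope, degC/min (< 0)
    intercept: float  # degC
    window: tuple[float, float]  # time span used for the fit, min
    tp1: float  # first time the smoothed curve reaches 0 degC, min

    def extrapolate(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.cl_rate * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class DeltaSeries:
    time: np.ndarray
    delta: np.ndarray
    threshold: float


@dataclass(frozen=True)
class FreezeEvents:
    """All detected landmarks of one cooling curve."""

    tp1: float
    s_time: float
    s_temp: float
    ifp_time: float
    ifp_temp: float
    nur: float  # degC/min
    hnt: float  # min
    supercooling_count: int
    calibration_offset: float | None = None
    ifp_method: str = "delta-regression"

    def to_dict(self) -> dict:
        return {
            "TP1_min": self.tp1,
            "S_min": self.s_time,
            "S_c": self.s_temp,
            "IFP_min": self.ifp_time,
            "IFP_c": self.ifp_temp,
            "NUR_c_per_min": self.nur,
            "HNT_min": self.hnt,
            "supercooling_count": self.supercooling_count,
            "calibration_offset_c": self.calibration_offset,
            "ifp_method": self.ifp_method,
        }


def _detection_trace(curve: CoolingCurve, window: int = DETECT_SMOOTH_WINDOW) -> np.ndarray:
    """Stronger smoothing used only for extremum search, never for reported values."""
    if len(curve) <= window:
        return curve.temperature
    return savgol_filter(curve.temperature, window, 2)


def fit_chilling(curve: CoolingCurve, skip_initial: float = 0.0) -> ChillingLine:
    """Fit the linear chilling ramp (samples above 0 degC) by OLS.

    ``skip_initial`` (minutes) drops a leading transient, e.g. probe
    equilibration after loading the barrel.  TP1 is the first sample at or
    below 0 degC.
    """
    curve.require_analysis_length()
    t, T = curve.time, curve.temperature
    mask = (T > 0) & (t >= t[0] + skip_initial)
    if mask.sum() < 3:
        raise DetectionError("curve is never (or barely) above 0 degC; no chilling phase")
    below = np.nonzero(T <= 0)[0]
    if below.size == 0:
        raise DetectionError("curve never crosses 0 degC")
    tp1 = float(t[below[0]])
    # only the contiguous ramp before TP1
    mask &= t < tp1
    if mask.sum() < 3:
        raise DetectionError("fewer than 3 chilling samples before the 0 degC crossing")
    slope, intercept = np.polyfit(t[mask], T[mask], 1)
    if slope >= 0:
        raise DetectionError(f"chilling slope {slope:.3f} degC/min is not negative")
    return ChillingLine(float(slope), float(intercept), (float(t[mask][0]), float(t[mask][-1])), tp1)


def delta_function(curve: CoolingCurve, line: ChillingLine, eps: float = EPS_TEMP,
                   threshold: float = DELTA_THRESHOLD) -> DeltaSeries:
    """Quadratic departure of the curve from the extrapolated chilling line."""
    sel = curve.time > line.tp1
    t = curve.time[sel]
    T = curve.temperature[sel]
    dev = line.extrapolate(t) - T
    denom = np.maximum(np.abs(T), eps)
    return DeltaSeries(t, dev**2 / denom, threshold)


def detect_first_supercooling(
    curve: CoolingCurve,
    delta: DeltaSeries,
    prominence: float = DIP_PROMINENCE,
    min_separation: float = 0.25,
) -> tuple[float, float, int]:
    """Locate the first supercooling minimum and count distinct dip events.

    Returns (time, temperature, count).  The search starts at the first time
    delta exceeds its threshold; dips are local minima of the smoothed trace
    with at least ``prominence`` degC of rebound, merged when closer than
    ``min_separation`` minutes (noise wiggles on the flat dip bottom are not
    separate nucleation events).  A curve whose delta never crosses the
    threshold (monotone cooling) raises :class:`DetectionError`.
    """
    above = np.nonzero(delta.delta > delta.threshold)[0]
    if above.size == 0:
        raise DetectionError("no supercooling detected: delta never exceeds threshold")
    t_open = delta.time[above[0]]
    trace = _detection_trace(curve)
    sel = curve.time >= t_open
    t, T = curve.time[sel], trace[sel]
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(-T, prominence=prominence, distance=distance)
    if idx.size == 0:
        i = int(np.argmin(T))
        if i >= T.size - 3:
            # coldest point at the tail: the curve declines monotonically
            raise DetectionError("no supercooling detected: no rebound after the minimum")
        # interior minimum with a rebound weaker than the prominence bound
        warnings.warn("supercooling rebound below prominence bound; weak event")
        return float(t[i]), float(T[i]), 1
    first = idx[0]
    return float(t[first]), float(T[first]), int(idx.size)


def locate_ifp(
    curve: CoolingCurve,
    delta: DeltaSeries,
    s_time: float,
    n_top: int = N_TOP_DELTA,
    min_span: float = 1.0,
    level_halfwidth: float = 0.35,
) -> tuple[float, float, str]:
    """Find the initial freezing point after the first supercooling.

    A line is fitted to at least ``n_top`` of the largest delta values
    (after the first threshold crossing); its delta = 0 time-intercept
    bounds the window (s_time, t0] in which the IFP is read as the maximum
    of the smoothed temperature.  Because the largest values cluster at the
    end of the run, the top set is grown until it spans ``min_span`` minutes
    so the extrapolation is conditioned.  An unusable intercept (non-growing
    delta, or earlier than the rebound peak after the supercooling minimum)
    falls back to the post-supercooling maximum over the whole remaining
    curve.

    Returns (time, temperature, method).
    """
    trace = _detection_trace(curve)
    method = "delta-regression"
    t0 = None
    above = delta.delta > delta.threshold
    if above.sum() < n_top:
        warnings.warn(
            f"only {int(above.sum())} delta values above threshold; "
            "falling back to post-supercooling maximum"
        )
        method = "max-after-S"
    else:
        region_t = delta.time[above]
        region_d = delta.delta[above]
        order = np.argsort(region_d)[::-1]
        k = n_top
        while k < order.size and np.ptp(region_t[order[:k]]) < min_span:
            k += 1
        a, b = np.polyfit(region_t[order[:k]], region_d[order[:k]], 1)
        # rebound peak after S: the intercept must not clip it off
        after = curve.time > s_time
        peaks, _ = find_peaks(trace[after])
        t_reb = float(curve.time[after][peaks[0]]) if peaks.size else s_time
        if a <= 0:
            method = "max-after-S"
        else:
            t0 = -b / a
            if t0 <= max(s_time, t_reb):
                method = "max-after-S"

    sel = curve.time > s_time
    if method == "delta-regression":
        sel &= curve.time <= t0
    if not sel.any():
        # no rebound window at all: IFP degenerates to the supercooling point
        warnings.warn("no samples after supercooling; IFP degenerates to S")
        i = int(np.argmin(np.abs(curve.time - s_time)))
        return float(curve.time[i]), float(trace[i]), "degenerate-S"
    t, T = curve.time[sel], trace[sel]
    i = int(np.argmax(T))
    # read the level by a short local mean at the located maximum: the single
    # argmax sample of a noisy trace is a selected-high (biased) estimator.
    # Contamination at a local maximum is one-sided (neighbours can only be
    # lower, e.g. the rebound corner), so the lowest quartile is trimmed.
    near = np.sort(T[np.abs(t - t[i]) <= level_halfwidth])
    level = near[near.size // 4:].mean()
    return float(t[i]), float(level), method


def nucleation_metrics(
    curve: CoolingCurve, tp1: float, s_time: float, ifp_time: float
) -> tuple[float, float]:
    """Nucleation rate NUR (OLS slope on [TP1, S], degC/min) and HNT = t_IFP - TP1."""
    if s_time <= tp1:
        raise ValidationError(f"supercooling time {s_time} must exceed TP1 {tp1}")
    sel = (curve.time >= tp1) & (curve.time <= s_time)
    if sel.sum() < 3:
        raise ValidationError("fewer than 3 samples between TP1 and the supercooling point")
    slope, _ = np.polyfit(curve.time[sel], curve.temperature[sel], 1)
    return float(slope), float(ifp_time - tp1)


def calibrate(curve: CoolingCurve, ifp_temp: float, fpt: float) -> tuple[CoolingCurve, float]:
    """Shift the whole profile so the measured IFP coincides with FPt.

    offset = IFP - FPt is subtracted from every temperature; a negative
    offset (probe below theory) is allowed with a warning.
    """
    offset = ifp_temp - fpt
    if offset < 0:
        warnings.warn(f"calibration offset {offset:.3f} degC is negative (IFP below FPt)")
    shifted = replace(curve, temperature=curve.temperature - offset)
    return shifted, float(offset)


def detect_events(
    curve: CoolingCurve,
    fpt: float | None = None,
    skip_initial: float = 0.0,
    eps: float = EPS_TEMP,
    threshold: float = DELTA_THRESHOLD,
    n_top: int = N_TOP_DELTA,
    prominence: float = DIP_PROMINENCE,
    presmooth: bool = True,
    min_span: float = 1.0,
    level_halfwidth: float = 0.35,
) -> FreezeEvents:
    """Run the full detection chain on one curve.

    The raw curve is first passed through the 3-point Savitzky-Golay filter
    (``presmooth``); supply ``fpt`` to also record the calibration offset.
    """
    work = smooth_sg3(curve) if presmooth else curve
    line = fit_chilling(work, skip_initial=skip_initial)
    delta = delta_function(work, line, eps=eps, threshold=threshold)
    s_time, s_temp, count = detect_first_supercooling(work, delta, prominence=prominence)
    ifp_time, ifp_temp, method = locate_ifp(
        work, delta, s_time, n_top=n_top, min_span=min_span, level_halfwidth=level_halfwidth
    )
    nur, hnt = nucleation_metrics(work, line.tp1, s_time, ifp_time)
    offset = ifp_temp - fpt if fpt is not None else None
    return FreezeEvents(
        tp1=line.tp1,
        s_time=s_time,
        s_temp=s_temp,
        ifp_time=ifp_time,
        ifp_temp=ifp_temp,
        nur=nur,
        hnt=hnt,
        supercooling_count=count,
        calibration_offset=offset,
        ifp_method=method,
    )


#: canonical ordering of the six curve phases
PHASES = (
    "chilling",
    "dynamic_nucleation",
    "ifp",
    "steady_state",
    "ifp_eff",
    "dynamic_ice_crystallization",
)


def label_segments(
    curve: CoolingCurve,
    events: FreezeEvents,
    ifp_eff_time: float | None = None,
) -> np.ndarray:
    """Assign each sample to exactly one curve phase.

    The two point landmarks (IFP and the effective freezing point IFP_eff)
    are carried by their nearest single sample so the labels partition the
    time axis.  Without an ``ifp_eff_time`` (e.g. a curve truncated before
    the kinetics can be fitted) only the phases up to the steady state are
    assigned, with a warning.
    """
    t = curve.time
    labels = np.empty(t.size, dtype=object)
    labels[t <= events.tp1] = "chilling"
    labels[t > events.tp1] = "dynamic_nucleation"
    i_ifp = int(np.argmin(np.abs(t - events.ifp_time)))
    labels[i_ifp] = "ifp"
    after_ifp = np.arange(t.size) > i_ifp
    labels[after_ifp] = "steady_state"
    if ifp_eff_time is None or ifp_eff_time >= t[-1]:
        warnings.warn("no effective freezing point supplied; partial labelling only")
        return labels
    i_eff = int(np.argmin(np.abs(t - ifp_eff_time)))
    if i_eff <= i_ifp:
        i_eff = min(i_ifp + 1, t.size - 1)
    labels[i_eff] = "ifp_eff"
    labels[np.arange(t.size) > i_eff] = "dynamic_ice_crystallization"
    return labels
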