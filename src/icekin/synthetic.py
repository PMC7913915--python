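"""Synthetic cooling curves, WF series and melt records with known ground truth.

Real batch-freezer logs are rarely shareable, so every pipeline stage here
is exercised against generated data whose true landmarks are known exactly.
The curve generator reproduces the anatomy seen in-situ: a linear chilling
ramp, a slower nucleation descent after the 0 degC crossing, one or more
supercooling dips with a rebound to the equilibrium plateau, and a slow
decline obtained by inverting the quartic FPD-WF map along a Gompertz
freezable-water trajectory, exactly the relation the analysis pipeline uses
in the forward direction.  Event detection, calibration and the nonlinear
fit are exercised end to end against the known construction.  Gaussian
sensor noise is seeded and additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve_io import CoolingCurve, MeltRecord
from .errors import ValidationError
from .formulation import SucroseFpdTable, default_sucrose_table
from .kinetics import E, FpdWfMap, GompertzParams, build_fpd_wf_map, gompertz, landmark_times
from .quality import melt_fraction


@dataclass(frozen=True)
class SupercoolEvent:
    """One supercooling dip: time of the minimum, its temperature, half-width."""

    time: float  # min
    t_min: float  # degC
    width: float = 0.3  # min, dip-to-plateau transition width


@dataclass(frozen=True)
class CurveScenario:
    """Ground-truth description of one simulated freezing run.

    Defaults follow a typical batch run: chilling at -16 degC/min from
    20 degC, a single supercooling dip to -2.8 degC at 2.5 min rebounding to
    a -2.2 degC plateau (theoretical freezing point -2.9 degC plus a
    0.7 degC probe offset), Gompertz kinetics (WFmax 0.55, GRmax 0.12 /min,
    lag 3.8 min, leaving a ~1 min steady state between the rebound and the
    acceleration of ice growth), 1 Hz sampling to an 8 min exit, sensor
    noise 0.1 degC.
    """

    t0: float = 20.0
    cl_rate: float = -16.0
    events: tuple[SupercoolEvent, ...] = (SupercoolEvent(2.5, -2.8),)
    fpt: float = -2.9
    probe_offset: float = 0.7
    wfmax: float = 0.55
    grmax: float = 0.12
    lag: float = 3.8
    t_exit: float = 8.0
    noise_sigma: float = 0.1
    sample_rate_hz: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.cl_rate >= 0:
            raise ValidationError("cl_rate must be negative")
        if self.t0 <= 0:
            raise ValidationError("curve must start above 0 degC")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.fpt >= 0:
            raise ValidationError("theoretical freezing point must be below 0 degC")
        plateau_ceiling = self.fpt + self.probe_offset
        if plateau_ceiling >= 0:
            raise ValidationError("plateau (FPt + probe offset) must stay below 0 degC")
        for ev in self.events:
            if ev.t_min > plateau_ceiling:
                raise ValidationError("supercooling minimum must lie below the plateau")
        if not 0 < self.wfmax <= 0.70:
            raise ValidationError("WFmax must lie in (0, 0.70]")

    @property
    def tp1(self) -> float:
        return -self.t0 / self.cl_rate


@dataclass(frozen=True)
class CurveTruth:
    """Exact landmark values the pipeline should recover."""

    tp1: float
    s_time: float | None
    s_temp: float | None
    ifp_time: float | None
    ifp_temp: float | None
    supercooling_count: int
    cl_rate: float
    fpt: float
    probe_offset: float
    se0: float
    params: GompertzParams
    ifp_eff_time: float
    gr_time: float
    t_whipp_time: float
    t_exit: float
    T_exit: float


def _equilibrium_temperature(scenario: CurveScenario, t, fpd_map: FpdWfMap):
    """Observed temperature on the equilibrium branch: -FPD(WF(t)) + probe offset.

    The freezable-water trajectory is pushed through the inverse of the same
    quartic FPD-WF map the analysis pipeline evaluates forward; fractions
    below the map's anchor stay at the initial freezing point (flat plateau).
    """
    wf = gompertz(t, scenario.wfmax, scenario.grmax, scenario.lag)
    lo, hi = fpd_map.domain
    wf = np.clip(np.atleast_1d(wf), fpd_map.wf(lo), fpd_map.wf(hi))
    fpd = np.array([fpd_map.invert(w) for w in wf])
    out = -fpd + scenario.probe_offset
    return out if np.ndim(t) else float(out[0])


def skeleton_temperature(scenario: CurveScenario, t: np.ndarray,
                         table: SucroseFpdTable | None = None) -> np.ndarray:
    """Deterministic (noise-free) temperature trace of a scenario."""
    tab = table if table is not None else default_sucrose_table()
    se0 = tab.inverse(-scenario.fpt)
    fpd_map = build_fpd_wf_map(se0, table=tab)
    t = np.asarray(t, dtype=float)
    T = scenario.t0 + scenario.cl_rate * t
    tp1 = scenario.tp1

    if scenario.events:
        first = scenario.events[0]
        t_s, T_s, w = first.time, first.t_min, first.width
        if t_s <= tp1:
            raise ValidationError("first supercooling must follow the 0 degC crossing")
        t_r = t_s + w
        # nucleation descent: monotone quadratic, zero slope at the dip minimum
        x = np.clip((t - tp1) / (t_s - tp1), 0.0, 1.0)
        seg = T_s * x * (2.0 - x)
        T = np.where(t > tp1, seg, T)
        # rebound: smoothstep up to the equilibrium branch
        plateau = _equilibrium_temperature(scenario, t_r, fpd_map)
        y = np.clip((t - t_s) / w, 0.0, 1.0)
        s = y * y * (3.0 - 2.0 * y)
        T = np.where(t > t_s, T_s + (plateau - T_s) * s, T)
        eq_start = t_r
    else:
        # no supercooling: monotone descent straight onto the equilibrium branch
        t_r = tp1 + 1.0
        target = _equilibrium_temperature(scenario, t_r, fpd_map)
        x = np.clip((t - tp1) / (t_r - tp1), 0.0, 1.0)
        T = np.where(t > tp1, target * x * (2.0 - x), T)
        eq_start = t_r

    eq = t > eq_start
    if eq.any():
        T[eq] = _equilibrium_temperature(scenario, t[eq], fpd_map)

    # secondary supercooling dips superposed on the equilibrium branch
    for ev in scenario.events[1:]:
        u = (t - ev.time) / ev.width
        inside = np.abs(u) < 1.0
        base = _equilibrium_temperature(scenario, ev.time, fpd_map)
        depth = ev.t_min - base
        T = np.where(inside, T + depth * (1.0 - u**2) ** 2, T)
    return T


def generate_cooling_curve(
    scenario: CurveScenario = CurveScenario(),
    seed: int | None = None,
    table: SucroseFpdTable | None = None,
) -> tuple[CoolingCurve, CurveTruth]:
    """Sample a scenario at its probe rate and return (curve, ground truth)."""
    tab = table if table is not None else default_sucrose_table()
    se0 = tab.inverse(-scenario.fpt)
    fpd_map = build_fpd_wf_map(se0, table=tab)
    dt = 1.0 / (60.0 * scenario.sample_rate_hz)
    t = np.arange(0.0, scenario.t_exit + dt / 2, dt)
    T = skeleton_temperature(scenario, t, tab)
    use_seed = seed if seed is not None else scenario.seed
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(use_seed)
        T = T + rng.normal(0.0, scenario.noise_sigma, size=T.shape)

    params = GompertzParams(scenario.wfmax, scenario.grmax, scenario.lag, e_pct=0.0)
    t_accel, t_infl, t_decel = landmark_times(params)
    if scenario.events:
        first = scenario.events[0]
        t_r = first.time + first.width
        ifp_time = t_r
        ifp_temp = _equilibrium_temperature(scenario, t_r, fpd_map)
        s_time, s_temp = first.time, first.t_min
    else:
        ifp_time = ifp_temp = s_time = s_temp = None
    curve = CoolingCurve(
        t, T, sample_rate=scenario.sample_rate_hz,
        label=f"synthetic(seed={use_seed})",
    )
    truth = CurveTruth(
        tp1=scenario.tp1,
        s_time=s_time,
        s_temp=s_temp,
        ifp_time=ifp_time,
        ifp_temp=ifp_temp,
        supercooling_count=len(scenario.events),
        cl_rate=scenario.cl_rate,
        fpt=scenario.fpt,
        probe_offset=scenario.probe_offset,
        se0=se0,
        params=params,
        ifp_eff_time=t_accel,
        gr_time=t_infl,
        t_whipp_time=t_decel,
        t_exit=scenario.t_exit,
        T_exit=float(T[-1]),
    )
    return curve, truth


def generate_wf_series(
    params: GompertzParams | tuple[float, float, float],
    grid: np.ndarray,
    sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gompertz WF(t) on a time grid plus seeded Gaussian noise, clipped to [0, 0.70]."""
    if isinstance(params, tuple):
        params = GompertzParams(*params, e_pct=0.0)
    grid = np.asarray(grid, dtype=float)
    wf = gompertz(grid, params.wfmax, params.grmax, params.lag)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        wf = np.clip(wf + rng.normal(0.0, sigma, size=wf.shape), 0.0, 0.70)
    return grid, wf


def generate_melt_record(
    lagtime: float = 12.0,
    mrate: float = 0.03,
    m0: float = 100.0,
    times: np.ndarray | None = None,
    sigma: float = 0.0,
    seed: int | None = None,
) -> MeltRecord:
    """Melt record at the standard weighing times (first drop, 15, 30, 45 min).

    The first-drop time is where the melt model reaches 0.5% of the mass;
    noise is added on the melted fraction, then monotonized and clipped so
    the record stays physically valid.
    """
    if times is None:
        z_first = np.log(-np.log(0.005))
        t_first = lagtime - (z_first - 1.0) / (mrate * E)
        t_first = max(t_first, 0.1)
        times = np.array(sorted({round(t_first, 3), 15.0, 30.0, 45.0}))
    times = np.asarray(times, dtype=float)
    frac = melt_fraction(times, lagtime, mrate)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(0.0, sigma, size=frac.shape)
        frac = np.maximum.accumulate(np.clip(frac, 0.0, 1.0))
    return MeltRecord(times, frac * m0, m0, label="synthetic-melt")
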