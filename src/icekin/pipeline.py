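"""End-to-end analysis of one cooling curve against its formulation.

Chains smoothing, chilling-line fit, delta-based supercooling detection,
IFP location, calibration against the theoretical freezing point, the
FPD-WF map, the Gompertz fit and derivative landmarks into a single report.

The map is anchored at the calibrated initial freezing point: the initial
sucrose-equivalent concentration is taken as the sucrose solution whose
tabulated depression equals -FPt, so all colligative contributions (sugars,
MSNF, NaCl) are expressed on the pure-sucrose scale and WF = 0 exactly at
the calibrated IFP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curve_io import CoolingCurve
from .formulation import SucroseFpdTable, default_sucrose_table
from .freeze_events import FreezeEvents, calibrate, detect_events
from .kinetics import (
    FpdWfMap,
    GompertzParams,
    KineticLandmarks,
    WFSeries,
    build_fpd_wf_map,
    fit_gompertz,
    landmarks,
    wf_series,
)


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the pipeline extracted from one run."""

    events: FreezeEvents
    calibrated: CoolingCurve
    fpd_map: FpdWfMap
    wf: WFSeries
    params: GompertzParams
    kinetic_landmarks: KineticLandmarks
    fpt: float

    def to_dict(self) -> dict:
        out = {
            "FPt_c": self.fpt,
            "SE0_g_per_100g_water": self.fpd_map.se0,
            "WFmax": self.params.wfmax,
            "GRmax_per_min": self.params.grmax,
            "HNT_lag_min": self.params.lag,
            "E_pct": self.params.e_pct,
        }
        out.update(self.events.to_dict())
        out.update(self.kinetic_landmarks.to_dict())
        return out


def analyze_curve(
    curve: CoolingCurve,
    fpt: float,
    table: SucroseFpdTable | None = None,
    monotonic_wf: bool = False,
    **detect_kwargs,
) -> AnalysisReport:
    """Run the full pipeline; raises Detection/Fit errors from the stages."""
    tab = table if table is not None else default_sucrose_table()
    events = detect_events(curve, fpt=fpt, **detect_kwargs)
    calibrated, _offset = calibrate(curve, events.ifp_temp, fpt)
    se0 = tab.inverse(-fpt)
    fpd_map = build_fpd_wf_map(se0, table=tab)
    wf = wf_series(calibrated, fpd_map, events.ifp_time, monotonic=monotonic_wf)
    params = fit_gompertz(wf.time, wf.wf)
    lm = landmarks(params, fpd_map, t_ifp=events.ifp_time, t_exit=wf.t_exit)
    return AnalysisReport(events, calibrated, fpd_map, wf, params, lm, float(fpt))
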