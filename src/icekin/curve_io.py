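"""Time-temperature and drip-loss records: containers, CSV I/O, noise filtering.

The probe in a batch scraped-surface freezer logs at 1 Hz; all analysis in
this package runs in minutes and degrees Celsius, so readers convert on the
way in.  Noise filtering follows the 3-point Savitzky-Golay scheme used for
the experimental curves; replicate agreement is summarised as twice the
per-time standard deviation, checked against the +/-0.2 degC uncertainty
envelope of the measurement chain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_coeffs

from .errors import ParseError, ValidationError

#: minimum number of samples required by the event-detection pipeline
MIN_ANALYSIS_SAMPLES = 30


@dataclass(frozen=True)
class CoolingCurve:
    """Uniformly sampled in-situ temperature log.

    time
        Sample times in minutes, strictly increasing.
    temperature
        Bulk temperature in degC, same length as ``time``.
    sample_rate
        Acquisition rate in Hz, if known.
    label
        Free-form run identifier.
    """

    time: np.ndarray
    temperature: np.ndarray
    sample_rate: float | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        T = np.asarray(self.temperature, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temperature", T)
        if t.ndim != 1 or T.shape != t.shape:
            raise ValidationError("time and temperature must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValidationError("a cooling curve needs at least two samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(T)):
            raise ValidationError("time and temperature must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    @property
    def t_exit(self) -> float:
        """Time of the last sample (exit from the freezer barrel), minutes."""
        return float(self.time[-1])

    @property
    def T_exit(self) -> float:
        """Temperature of the last sample, degC."""
        return float(self.temperature[-1])

    def require_analysis_length(self) -> None:
        if len(self) < MIN_ANALYSIS_SAMPLES:
            raise ValidationError(
                f"need >= {MIN_ANALYSIS_SAMPLES} samples for event analysis, got {len(self)}"
            )


@dataclass(frozen=True)
class MeltRecord:
    """Drip-loss masses collected under a melting sieve.

    time is in minutes, drip_mass in grams (non-decreasing), m0 the total
    ice-cream mass in grams.
    """

    time: np.ndarray
    drip_mass: np.ndarray
    m0: float
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        m = np.asarray(self.drip_mass, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "drip_mass", m)
        if t.ndim != 1 or m.shape != t.shape:
            raise ValidationError("time and drip_mass must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.m0 <= 0:
            raise ValidationError("total mass m0 must be positive")
        if np.any(m < 0) or np.any(m > self.m0 + 1e-9):
            raise ValidationError("drip mass must lie in [0, m0]")
        if np.any(np.diff(m) < 0):
            raise ValidationError("drip mass must be non-decreasing")

    @property
    def fraction(self) -> np.ndarray:
        """Melted fraction m_D/m_0."""
        return self.drip_mass / self.m0


def _read_numeric_rows(path, n_cols: int, delimiter: str):
    """Parse a CSV into float columns, tolerating one optional header row."""
    rows = []
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if row and row[0].lstrip().startswith("#"):
                continue
            if len(row) < n_cols:
                raise ParseError(f"expected {n_cols} columns, got {len(row)}", line=lineno)
            try:
                rows.append([float(c) for c in row[:n_cols]])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header row
                raise ParseError(f"non-numeric value in {row[:n_cols]}", line=lineno)
    if not rows:
        raise ParseError("no numeric data rows found")
    return np.asarray(rows, dtype=float).T


def read_cooling_curve(
    path,
    time_unit: str = "s",
    delimiter: str = ",",
    label: str | None = None,
) -> CoolingCurve:
    """Read a (time, temperature) CSV and return a curve in minutes/degC.

    ``time_unit`` declares the unit of the file's time column ("s" or "min").
    A single header row is skipped if present; malformed rows raise
    :class:`ParseError` with the line number.
    """
    if time_unit not in ("s", "min"):
        raise ValidationError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    t, T = _read_numeric_rows(path, 2, delimiter)
    if time_unit == "s":
        t = t / 60.0
    dt = np.diff(t)
    rate = None
    if dt.size and np.allclose(dt, dt[0], rtol=1e-6):
        rate = 1.0 / (dt[0] * 60.0)
    return CoolingCurve(t, T, sample_rate=rate, label=label or str(path))


def write_cooling_curve(curve: CoolingCurve, path, time_unit: str = "min", precision: int = 6) -> None:
    """Write a curve as two-column CSV with a header, round-trip safe at ``precision``."""
    t = curve.time * 60.0 if time_unit == "s" else curve.time
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"time_{time_unit}", "temperature_c"])
        for ti, Ti in zip(t, curve.temperature):
            w.writerow([f"{ti:.{precision}f}", f"{Ti:.{precision}f}"])


def read_melt_record(path, delimiter: str = ",", label: str | None = None) -> MeltRecord:
    """Read a (time min, drip g, total g) CSV; the total-mass column must be constant."""
    t, m, m0 = _read_numeric_rows(path, 3, delimiter)
    if not np.allclose(m0, m0[0]):
        raise ValidationError("total mass column must be constant")
    return MeltRecord(t, m, float(m0[0]), label=label or str(path))


def write_melt_record(record: MeltRecord, path, precision: int = 6) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_min", "drip_g", "total_g"])
        for ti, mi in zip(record.time, record.drip_mass):
            w.writerow([f"{ti:.{precision}f}", f"{mi:.{precision}f}", f"{record.m0:.{precision}f}"])


def smooth_sg3(curve: CoolingCurve, window: int = 3, polyorder: int = 1) -> CoolingCurve:
    """Savitzky-Golay smoothing of the temperature trace.

    Default is the 3-point, order-1 kernel (equal to a centred moving
    average), which preserves linear trends exactly.  Endpoints are copied
    through unfiltered.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValidationError("polyorder must be < window")
    if len(curve) < window:
        raise ValidationError(f"need >= {window} samples to smooth, got {len(curve)}")
    kernel = savgol_coeffs(window, polyorder)
    T = curve.temperature
    out = T.copy()
    half = window // 2
    out[half:-half] = np.convolve(T, kernel, mode="valid")
    return replace(curve, temperature=out)


@dataclass(frozen=True)
class ReplicateEnvelope:
    """Per-time reproducibility of replicate runs.

    envelope holds 2x the per-time standard deviation across replicates
    (the doubled experimental scatter); exceeds flags times where it is
    larger than ``bound`` (default the 0.2 degC measurement envelope).
    """

    time: np.ndarray
    envelope: np.ndarray
    bound: float
    mean: np.ndarray = field(repr=False, default=None)

    @property
    def exceeds(self) -> np.ndarray:
        return self.envelope > self.bound


def replicate_envelope(curves: list[CoolingCurve], bound: float = 0.2) -> ReplicateEnvelope:
    """Pool >= 2 replicate curves onto a common grid and double their scatter.

    Replicates on mismatched grids are linearly resampled onto the grid of
    the replicate with the shortest span before pooling.
    """
    if len(curves) < 2:
        raise ValidationError("need at least two replicates for an envelope")
    shortest = min(curves, key=lambda c: c.t_exit)
    grid = shortest.time
    grid = grid[(grid >= max(c.time[0] for c in curves))]
    stack = np.vstack([np.interp(grid, c.time, c.temperature) for c in curves])
    sd = np.std(stack, axis=0, ddof=1)
    return ReplicateEnvelope(grid, 2.0 * sd, bound, mean=stack.mean(axis=0))


def curve_to_json_dict(curve: CoolingCurve) -> dict:
    return {
        "label": curve.label,
        "sample_rate_hz": curve.sample_rate,
        "time_min": curve.time.tolist(),
        "temperature_c": curve.temperature.tolist(),
    }
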