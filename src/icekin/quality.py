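"""Product-quality metrics: melting kinetics, overrun, sensory liking level.

Melting of a tempered ice cream under gravity follows a sigmoid in the
melted fraction m_D/m_0; it is modelled with the same re-parameterized
Gompertz form as the crystallization kinetic, with unit asymptote (all mass
eventually melts), a LAGTIME before the first drip and a maximum melting
rate Mrate (fraction/min).

Overrun is the percent air incorporation at fixed volume; the liking level
condenses a judged sensory matrix to one 0-100 score by crediting desired
attributes and debiting undesired ones, per judge, then averaging.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy.optimize import curve_fit

from .curve_io import MeltRecord
from .errors import FitError, ValidationError
from .kinetics import E, error_pct


def melt_fraction(t, lagtime: float, mrate: float):
    """Unit-asymptote Gompertz melt model m_D/m_0 (t in minutes)."""
    z = mrate * E * (lagtime - np.asarray(t, dtype=float)) + 1.0
    with np.errstate(over="ignore"):  # exp overflow far before the lag -> 0
        return np.exp(-np.exp(z))


@dataclass(frozen=True)
class MeltKinetics:
    lagtime: float  # min
    mrate: float  # fraction/min
    e_pct: float  # lack of fit, %


def fit_melting(record: MeltRecord, n_multistart: int = 5, seed: int = 0) -> MeltKinetics:
    """Least-squares fit of the melt model to a drip-loss record.

    Requires >= 4 observations (first drop plus the 15/30/45 min weighings
    of the standard protocol, or denser logs).
    """
    t = record.time
    y = record.fraction
    if t.size < 4:
        raise ValidationError("need at least 4 melting observations")
    if y.max() <= 0:
        raise FitError("no drip loss recorded; nothing to fit")
    above = np.nonzero(y > 0.05 * y.max())[0]
    lag0 = float(t[above[0]]) if above.size else float(t[0])
    slopes = np.diff(y) / np.diff(t)
    m0 = max(float(slopes.max()), 1e-4)
    rng = np.random.default_rng(seed)
    start = np.array([lag0, m0])
    last_err: Exception | None = None
    for trial in range(n_multistart + 1):
        p0 = start if trial == 0 else start * rng.uniform(0.5, 1.5, size=2)
        try:
            popt, _ = curve_fit(
                melt_fraction, t, y, p0=p0,
                bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000,
            )
            fit = melt_fraction(t, *popt)
            return MeltKinetics(float(popt[0]), float(popt[1]), error_pct(y, fit))
        except (RuntimeError, ValueError) as err:
            last_err = err
    raise FitError(f"melting fit failed after {n_multistart + 1} starts: {last_err}")


def overrun(w_mixture: float, w_ice_cream: float) -> float:
    """Percent overrun from the weights of mix and ice cream at equal volume.

    overrun = 100 * (w_mixture - w_ice_cream) / w_ice_cream.  A negative
    result (ice cream denser than mix) is returned but physically
    implausible; callers should treat it as a warning sign.
    """
    if w_mixture <= 0 or w_ice_cream <= 0:
        raise ValidationError("weights must be positive")
    return 100.0 * (w_mixture - w_ice_cream) / w_ice_cream


@dataclass
class SensoryMatrix:
    """Panel scores: judges x attributes, with per-attribute scales and flags.

    scores[j, i] is judge j's score for attribute i; max_scores[i] the top of
    attribute i's hedonic scale; desired[i] True for appreciated attributes
    (appearance, sweetness, ...) and False for defects (sandiness,
    off-flavor).
    """

    scores: np.ndarray
    max_scores: np.ndarray
    desired: np.ndarray
    attributes: tuple[str, ...] = ()

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.max_scores = np.asarray(self.max_scores, dtype=float)
        self.desired = np.asarray(self.desired, dtype=bool)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a judges x attributes matrix")
        n_attr = self.scores.shape[1]
        if self.max_scores.shape != (n_attr,) or self.desired.shape != (n_attr,):
            raise ValidationError("max_scores and desired must have one entry per attribute")
        if not self.attributes:
            self.attributes = tuple(f"attr{i}" for i in range(n_attr))
        if np.any(self.scores < 0) or np.any(self.scores > self.max_scores[None, :]):
            raise ValidationError("scores must lie in [0, max] per attribute")

    @property
    def n_judges(self) -> int:
        return self.scores.shape[0]


def liking_level(m: SensoryMatrix) -> float:
    """Overall liking on a 0-100 scale.

    Per judge: 100 * (sum of desired scores - sum of undesired scores) /
    (sum of the maximum scores of the desired attributes); the panel value
    is the mean over judges.
    """
    des = m.desired
    denom = m.max_scores[des].sum()
    if denom <= 0:
        raise ValidationError("no desired attributes (or zero max scores)")
    per_judge = 100.0 * (m.scores[:, des].sum(axis=1) - m.scores[:, ~des].sum(axis=1)) / denom
    return float(per_judge.mean())


def standardize_scores(m: SensoryMatrix) -> SensoryMatrix:
    """Scale-only standardization: each attribute divided by its own SD.

    No centering is applied, so every attribute ends with unit variance but
    keeps its mean/SD ratio.  A zero-variance attribute is an error.
    """
    sd = m.scores.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        names = [m.attributes[i] for i in zero]
        raise ValidationError(f"zero-variance attribute(s): {names}")
    scaled = m.scores / sd[None, :]
    return SensoryMatrix(
        scores=scaled,
        max_scores=m.max_scores / sd,
        desired=m.desired,
        attributes=m.attributes,
    )
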