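"""Gas-production kinetics and protozoal-activity regression.

Batch-culture gas production is logged as pressure excess on a
transducer; with fixed headspace and temperature the ideal gas law gives
the vented volume per reading as

    V = V_headspace * (P_excess / P_ambient)

and cumulative production is the running sum over vent events.  After
blank correction the cumulative curve Y(t) is fitted to the single-pool
exponential model

    Y = A (1 - exp(-c t))

with asymptotic pool A (mL) and fractional rate c (1/h).  Because the
"rate" a gas-production table reports may be either c itself or the
initial slope, the fit also exposes A*c (mL/h).

Protozoal activity is the slope (%/h) of an ordinary least-squares line
through the percentage of a 14C-labelled bacterial inoculum released
over a 0-4 h incubation: faster release means faster bacterial
breakdown by the protozoa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateFitError, ValidationError

#: Headspace of a 120-mL serum bottle holding 50 mL of culture (mL).
DEFAULT_HEADSPACE_ML = 70.0

#: Standard ambient pressure (kPa).
DEFAULT_AMBIENT_KPA = 101.3


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class PressureSeries:
    """Ordered pressure-excess readings for one bottle."""

    sample_id: str
    times_h: np.ndarray
    pressures_kpa: np.ndarray
    headspace_ml: float = DEFAULT_HEADSPACE_ML
    ambient_kpa: float = DEFAULT_AMBIENT_KPA

    def __post_init__(self):
        t = _as_1d(self.times_h, "times_h")
        p = _as_1d(self.pressures_kpa, "pressures_kpa")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "pressures_kpa", p)
        if t.size != p.size:
            raise ValidationError("times and pressures differ in length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValidationError("times must be >= 0 and strictly increasing")
        if self.headspace_ml <= 0:
            raise ValidationError("headspace must be > 0")
        if self.ambient_kpa <= 0:
            raise ValidationError("ambient pressure must be > 0")


@dataclass(frozen=True)
class GasCurve:
    """Cumulative gas volume (mL) over time for one bottle."""

    sample_id: str
    times_h: np.ndarray
    volumes_ml: np.ndarray

    def __post_init__(self):
        t = _as_1d(self.times_h, "times_h")
        v = _as_1d(self.volumes_ml, "volumes_ml")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "volumes_ml", v)
        if t.size != v.size:
            raise ValidationError("times and volumes differ in length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValidationError("times must be >= 0 and strictly increasing")


@dataclass(frozen=True)
class FranceFit:
    """Fitted single-pool exponential gas model."""

    sample_id: str
    A: float              # asymptotic gas pool, mL
    c: float              # fractional rate, 1/h
    rss: float            # residual sum of squares, mL^2
    converged: bool

    @property
    def initial_rate(self) -> float:
        """Initial production rate A*c (mL/h)."""
        return self.A * self.c

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return self.A * (1.0 - np.exp(-self.c * t))


@dataclass(frozen=True)
class ReleaseSeries:
    """14C release time course for one incubation tube."""

    tube_id: str
    times_h: np.ndarray
    pct_released: np.ndarray
    slope: float = field(init=False, default=np.nan)
    intercept: float = field(init=False, default=np.nan)

    def __post_init__(self):
        t = _as_1d(self.times_h, "times_h")
        y = _as_1d(self.pct_released, "pct_released")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "pct_released", y)
        if t.size != y.size:
            raise ValidationError("times and percentages differ in length")
        if t.size and (np.any(t < 0) or np.any(t > 4.0)):
            raise ValidationError("release assay times must lie in [0, 4] h")


def pressure_to_volume(series: PressureSeries, venting: bool = True) -> GasCurve:
    """Convert pressure excess to cumulative gas volume via the ideal gas law.

    With ``venting=True`` (default) each reading is the increment since
    the previous vent and the cumulative volume is the running sum; with
    ``venting=False`` each reading already reflects total accumulation.
    """
    vols = series.headspace_ml * series.pressures_kpa / series.ambient_kpa
    if venting:
        vols = np.cumsum(vols)
    return GasCurve(series.sample_id, series.times_h.copy(), vols)


def blank_correct(sample: GasCurve, blanks: list[GasCurve],
                  floor_at_zero: bool = False) -> GasCurve:
    """Subtract the time-point-wise mean blank curve from a sample curve."""
    if not blanks:
        return sample
    for b in blanks:
        if b.times_h.size != sample.times_h.size or \
                not np.allclose(b.times_h, sample.times_h):
            raise ValidationError(
                f"blank {b.sample_id!r} not on the sample time grid")
    mean_blank = np.mean([b.volumes_ml for b in blanks], axis=0)
    corrected = sample.volumes_ml - mean_blank
    if floor_at_zero:
        corrected = np.maximum(corrected, 0.0)
    return GasCurve(sample.sample_id, sample.times_h.copy(), corrected)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # A0 slightly above the max; c0 from a log-linear fit of the
    # remaining pool fraction 1 - Y/A0.
    a0 = max(float(np.max(y)), 1e-9) * 1.05
    frac = np.clip(1.0 - y / a0, 1e-9, None)
    slope = stats.linregress(t, np.log(frac)).slope
    c0 = max(-slope, 1e-4)
    return a0, c0


def fit_france(curve: GasCurve, max_nfev: int = 10_000) -> FranceFit:
    """Least-squares fit of Y = A(1 - exp(-c t)) to a cumulative gas curve.

    Requires at least three distinct time points with positive volume.
    Falls back to a coarse multi-start if the first attempt fails; a fit
    that still fails is returned with ``converged=False`` rather than
    raised, so batch runs survive individual pathological bottles.
    """
    t, y = curve.times_h, curve.volumes_ml
    if np.count_nonzero(y > 0) < 3:
        raise DegenerateFitError(
            f"{curve.sample_id!r}: need >= 3 positive volumes to fit")

    def model(tt, a, c):
        return a * (1.0 - np.exp(-c * tt))

    starts = [_initial_guess(t, y)]
    starts += [(float(np.max(y)) * f, c0)
               for f in (1.0, 1.2, 2.0) for c0 in (0.01, 0.05, 0.2)]
    best = None
    for a0, c0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=(a0, c0),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                max_nfev=max_nfev)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
        if rss <= 1e-20 + 1e-12 * float(np.sum(y ** 2)):
            break
    if best is None:
        return FranceFit(curve.sample_id, np.nan, np.nan, np.inf, False)
    return FranceFit(curve.sample_id, best[0], best[1], best[2], True)


def release_rate(series: ReleaseSeries) -> ReleaseSeries:
    """OLS slope (%/h) of percent released vs. time, for one tube."""
    t, y = series.times_h, series.pct_released
    if np.unique(t).size < 2:
        raise ValidationError("need >= 2 distinct time points for a slope")
    res = stats.linregress(t, y)
    out = ReleaseSeries(series.tube_id, t.copy(), y.copy())
    object.__setattr__(out, "slope", float(res.slope))
    object.__setattr__(out, "intercept", float(res.intercept))
    return out
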