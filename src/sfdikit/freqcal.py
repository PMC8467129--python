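"""Fringe-period estimation and two-step spatial-frequency calibration.

The spatial frequency actually realised on the sample plane differs from the
requested one because the projector beam is divergent and the geometry is
only approximately known.  Calibration proceeds through the chain

    Tc (captured pixel period)  --Tr = Tc * Xr / Xc_mean-->  Tr (mm)
    rrp = Tp / Tr  (generation pixels per mm on the plane)
    Tp = rrp * Tre (pixels needed for a requested plane period Tre)

and a two-step refinement: step 1 generates all target periods from a single
initial ratio rrp(0); step 2 re-measures each frequency, updates a
per-frequency ratio rrp(k) = Tp(k)/Tv(k) from the measured period Tv, and
regenerates.  A frequency-independent multiplicative bias is removed exactly
in one update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "CheckerboardScale",
    "PeriodCalibration",
    "TwoStepResult",
    "DEFAULT_FREQUENCIES",
    "estimate_pixel_period",
    "camera_to_actual_period",
    "period_ratio",
    "projection_period_for_target",
    "period_percentage_error",
    "two_step_calibration",
    "calibratable_frequencies",
]

#: The sixteen reference spatial frequencies, mm^-1 (0 is the planar channel).
DEFAULT_FREQUENCIES = (
    0.0, 0.007, 0.0084, 0.0098, 0.0112, 0.0126, 0.014, 0.028,
    0.042, 0.056, 0.070, 0.084, 0.098, 0.112, 0.126, 0.14,
)

#: Generation-period quantisation, pixels (phase-accurate synthesis).
PERIOD_RESOLUTION_PX = 0.1


@dataclass(frozen=True)
class CheckerboardScale:
    """Metric scale of the camera image from a checkerboard of known pitch.

    xr: actual cell length, mm (5 mm in the reference rig);
    xc_mean: average cell length in camera pixels.
    """

    xr: float = 5.0
    xc_mean: float = 78.3

    def __post_init__(self) -> None:
        if self.xr <= 0 or self.xc_mean <= 0:
            raise ValueError("checkerboard scales must be positive")


@dataclass
class PeriodCalibration:
    """One frequency's calibration record."""

    target_fx: float  # mm^-1
    tre: float  # expected plane period, mm
    tp: float  # generation period, px
    tv: float = float("nan")  # measured plane period, mm
    rrp: float = float("nan")  # period ratio Tp/Tr, px per mm
    et: float = float("nan")  # period percentage error, %
    flagged: bool = False
    note: str = ""


@dataclass
class TwoStepResult:
    """Per-frequency records and mean errors of the two calibration steps."""

    step1: list[PeriodCalibration] = field(default_factory=list)
    step2: list[PeriodCalibration] = field(default_factory=list)

    @staticmethod
    def _mean_error(records: list[PeriodCalibration]) -> float:
        errs = [r.et for r in records if not r.flagged and np.isfinite(r.et)]
        return float(np.mean(errs)) if errs else float("nan")

    @property
    def step1_mean_error(self) -> float:
        return self._mean_error(self.step1)

    @property
    def step2_mean_error(self) -> float:
        return self._mean_error(self.step2)


def estimate_pixel_period(
    profile: np.ndarray, smooth_sigma: float = 2.0, min_prominence: float = 0.05
) -> float:
    """Mean fringe period, in pixels, of a 1-D averaged reflectance curve.

    Local minima of the lightly smoothed profile are located, refined to
    sub-pixel positions by a parabolic fit through each minimum and its
    neighbours, and the mean spacing of consecutive minima is returned.

    Raises
    ------
    ValueError
        If fewer than two minima are found (profile must span >= 2 periods).
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("profile must be a 1-D array spanning >= 2 periods")
    span = y.max() - y.min()
    if span == 0:
        raise ValueError("constant profile: no fringes to measure")
    s = gaussian_filter1d(y, smooth_sigma)
    minima, _ = find_peaks(-s, prominence=min_prominence * span)
    minima = minima[(minima > 0) & (minima < y.size - 1)]
    if minima.size < 2:
        raise ValueError(
            f"found {minima.size} minima; need >= 2 full periods in the profile"
        )
    refined = []
    for m in minima:
        y0, y1, y2 = s[m - 1], s[m], s[m + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        refined.append(m + float(np.clip(delta, -0.5, 0.5)))
    return float(np.mean(np.diff(refined)))


def camera_to_actual_period(tc: float, scale: CheckerboardScale) -> float:
    """Plane period Tr (mm) from the captured pixel period: Tr = Tc Xr / Xc_mean."""
    if tc <= 0:
        raise ValueError("captured period must be positive")
    return tc * scale.xr / scale.xc_mean


def period_ratio(tp: float, tr: float) -> float:
    """Period ratio rrp = Tp / Tr, generation pixels per plane mm."""
    if tp <= 0 or tr <= 0:
        raise ValueError("periods must be positive")
    return tp / tr


def projection_period_for_target(
    tre: float, rrp: float, resolution_px: float = PERIOD_RESOLUTION_PX
) -> float:
    """Generation period Tp = rrp * Tre for a requested plane period Tre (mm).

    Quantised to ``resolution_px`` (default 0.1 px, the precision of
    phase-accurate pattern synthesis).  Raises if the result is below 2 px,
    which is not representable as a sampled sinusoid.
    """
    if tre <= 0 or rrp <= 0:
        raise ValueError("period and ratio must be positive")
    tp = rrp * tre
    if resolution_px > 0:
        tp = round(tp / resolution_px) * resolution_px
    if tp < 2:
        raise ValueError(f"generation period {tp:.2f} px < 2 px: frequency unrepresentable")
    return tp


def period_percentage_error(tre: float, tv: float) -> float:
    """Percentage period error et = |Tre - Tv| / Tre * 100."""
    if tre <= 0:
        raise ValueError("expected period must be positive")
    return abs(tre - tv) / tre * 100.0


def calibratable_frequencies(
    frequencies, fov_mm: float = 150.0, min_periods: int = 2
) -> list[float]:
    """Frequencies whose profile spans >= ``min_periods`` full fringes in the field.

    Period estimation needs at least two minima, i.e. two full periods within
    the field of view; lower frequencies are extrapolated instead of measured.
    """
    return [f for f in frequencies if f > 0 and min_periods / f <= fov_mm]


def two_step_calibration(
    initial_rrp: float,
    targets_tre,
    measure,
    resolution_px: float = PERIOD_RESOLUTION_PX,
) -> TwoStepResult:
    """Two-step iterative frequency calibration.

    Parameters
    ----------
    initial_rrp : float
        Initial period ratio rrp(0), px per mm, from the bootstrap pattern.
    targets_tre : sequence of float
        Requested plane periods Tre (mm), one per frequency.
    measure : callable(tp_px) -> tv_mm
        Measurement procedure: project a pattern of generation period
        ``tp_px`` and return the realised plane period in mm (from real
        images or a simulator).  Exceptions flag that frequency; the others
        proceed.
    resolution_px : float
        Quantisation of generated periods.

    Returns
    -------
    TwoStepResult
        Step-1 records (shared rrp(0)) and step-2 records (per-frequency
        updated rrp(k) = Tp(k)/Tv(k)), each with the percentage error et.
    """
    if initial_rrp <= 0:
        raise ValueError("initial rrp must be positive")
    result = TwoStepResult()
    for tre in targets_tre:
        rec = PeriodCalibration(target_fx=1.0 / tre, tre=tre, tp=float("nan"), rrp=initial_rrp)
        try:
            rec.tp = projection_period_for_target(tre, initial_rrp, resolution_px)
            rec.tv = float(measure(rec.tp))
            rec.et = period_percentage_error(tre, rec.tv)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            rec.flagged = True
            rec.note = f"step-1 measurement failed: {exc}"
        result.step1.append(rec)

    for rec1 in result.step1:
        rec = PeriodCalibration(
            target_fx=rec1.target_fx, tre=rec1.tre, tp=float("nan")
        )
        if rec1.flagged or not np.isfinite(rec1.tv) or rec1.tv <= 0:
            rec.flagged = True
            rec.note = "no step-1 measurement to update from"
            result.step2.append(rec)
            continue
        rec.rrp = period_ratio(rec1.tp, rec1.tv)
        try:
            rec.tp = projection_period_for_target(rec1.tre, rec.rrp, resolution_px)
            rec.tv = float(measure(rec.tp))
            rec.et = period_percentage_error(rec1.tre, rec.tv)
        except Exception as exc:  # noqa: BLE001
            rec.flagged = True
            rec.note = f"step-2 measurement failed: {exc}"
        result.step2.append(rec)
    return result


def extrapolate_rrp(
    calibrated_fx, calibrated_rrp, target_fx
) -> np.ndarray:
    """Linear-in-frequency extrapolation of rrp to uncalibrated frequencies.

    Used for frequencies whose full period does not fit the field of view;
    the result is an estimate, not a measurement.
    """
    fx = np.asarray(calibrated_fx, dtype=float)
    rrp = np.asarray(calibrated_rrp, dtype=float)
    if fx.size < 2:
        raise ValueError("need >= 2 calibrated frequencies to extrapolate")
    coeffs = np.polyfit(fx, rrp, 1)
    return np.polyval(coeffs, np.asarray(target_fx, dtype=float))
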