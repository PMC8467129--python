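"""Three-phase amplitude demodulation and whiteboard reflectance calibration.

Sinusoidal illumination is projected at three phase offsets 0, 2pi/3 and
4pi/3.  The per-pixel AC amplitude envelope is recovered as

    Mac = (2/3) sqrt((I1-I2)^2 + (I2-I3)^2 + (I1-I3)^2)

Note on scale: for a pure sinusoid of amplitude ``a`` the sum of squared
pairwise differences equals 4.5 a^2, so this expression returns sqrt(2)*a
rather than ``a`` (the conventional prefactor is sqrt(2)/3).  The constant is
kept as written above because it cancels identically in the whiteboard ratio

    Rd = (Mac / Mac_ref) * Rd_ref

which is the only way Mac is consumed downstream.  Anyone using Mac in
isolation as an absolute amplitude should divide by sqrt(2).

The DC (fx = 0) channel cannot be demodulated this way — three identical
phases give Mac = 0 — and is calibrated directly from the planar ratio
Rac = (Iac / Iref) * Rd_ref.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseStack",
    "ReflectanceImage",
    "three_phase_amplitude",
    "calibrate_reflectance",
    "planar_reflectance",
    "DEFAULT_RD_REF",
    "DEFAULT_MASK_FLOOR",
]

#: Reflectance of the standard whiteboard used for calibration.
DEFAULT_RD_REF = 0.99

#: Reference-amplitude floor, as a fraction of the reference image maximum,
#: below which pixels are masked rather than divided.
DEFAULT_MASK_FLOOR = 1e-6


@dataclass
class PhaseStack:
    """Three co-registered intensity images at phases 0, 2pi/3, 4pi/3.

    Intensities are in arbitrary linear camera units; ``fx`` is the spatial
    frequency of the projected pattern in mm^-1.
    """

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    fx: float = 0.0

    def __post_init__(self) -> None:
        self.i1 = np.asarray(self.i1, dtype=float)
        self.i2 = np.asarray(self.i2, dtype=float)
        self.i3 = np.asarray(self.i3, dtype=float)
        if not (self.i1.shape == self.i2.shape == self.i3.shape):
            raise ValueError(
                "phase images must share one shape, got "
                f"{self.i1.shape}, {self.i2.shape}, {self.i3.shape}"
            )


@dataclass
class ReflectanceImage:
    """Per-pixel calibrated diffuse reflectance at one spatial frequency.

    Masked (invalid) pixels are NaN in ``rd``.
    """

    rd: np.ndarray
    fx: float = 0.0

    def __post_init__(self) -> None:
        self.rd = np.asarray(self.rd, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the pixel is valid."""
        return np.isfinite(self.rd)


def three_phase_amplitude(stack: PhaseStack) -> np.ndarray:
    """AC amplitude envelope of a three-phase stack.

    Returns (2/3) sqrt((I1-I2)^2 + (I2-I3)^2 + (I1-I3)^2) per pixel, which is
    sqrt(2) times the true sinusoid amplitude (see module docstring); the
    factor cancels in :func:`calibrate_reflectance`.
    """
    d12 = stack.i1 - stack.i2
    d23 = stack.i2 - stack.i3
    d13 = stack.i1 - stack.i3
    return (2.0 / 3.0) * np.sqrt(d12**2 + d23**2 + d13**2)


def calibrate_reflectance(
    mac_sample: np.ndarray,
    mac_ref: np.ndarray,
    rd_ref: float = DEFAULT_RD_REF,
    fx: float = 0.0,
    mask_floor: float = DEFAULT_MASK_FLOOR,
) -> ReflectanceImage:
    """Calibrate sample amplitude against the whiteboard amplitude.

    Rd = (Mac / Mac_ref) * Rd_ref per pixel.  Pixels where the reference
    amplitude falls below ``mask_floor`` times its maximum are masked (NaN)
    instead of producing unbounded ratios.
    """
    mac_sample = np.asarray(mac_sample, dtype=float)
    mac_ref = np.asarray(mac_ref, dtype=float)
    if mac_sample.shape != mac_ref.shape:
        raise ValueError(
            f"shape mismatch: sample {mac_sample.shape} vs reference {mac_ref.shape}"
        )
    floor = mask_floor * np.nanmax(mac_ref) if mac_ref.size else 0.0
    valid = mac_ref > floor
    rd = np.full(mac_sample.shape, np.nan)
    np.divide(mac_sample, mac_ref, out=rd, where=valid)
    rd[valid] *= rd_ref
    return ReflectanceImage(rd=rd, fx=fx)


def planar_reflectance(
    i_ac: np.ndarray,
    i_ref: np.ndarray,
    rd_ref: float = DEFAULT_RD_REF,
    mask_floor: float = DEFAULT_MASK_FLOOR,
) -> ReflectanceImage:
    """Planar (DC, fx = 0) reflectance calibration Rac = (Iac / Iref) * Rd_ref.

    ``i_ac`` is the sample image under full-field (unmodulated) illumination
    and ``i_ref`` the whiteboard image under the same illumination.  Dark
    reference pixels are masked.
    """
    i_ac = np.asarray(i_ac, dtype=float)
    i_ref = np.asarray(i_ref, dtype=float)
    if i_ac.shape != i_ref.shape:
        raise ValueError(f"shape mismatch: {i_ac.shape} vs {i_ref.shape}")
    floor = mask_floor * np.nanmax(i_ref) if i_ref.size else 0.0
    valid = i_ref > floor
    rd = np.full(i_ac.shape, np.nan)
    np.divide(i_ac, i_ref, out=rd, where=valid)
    rd[valid] *= rd_ref
    return ReflectanceImage(rd=rd, fx=0.0)


def demodulate_stack(
    sample: PhaseStack,
    reference: PhaseStack,
    rd_ref: float = DEFAULT_RD_REF,
    mask_floor: float = DEFAULT_MASK_FLOOR,
) -> ReflectanceImage:
    """Demodulate a sample/reference stack pair into calibrated reflectance.

    Convenience composition of :func:`three_phase_amplitude` on both stacks
    followed by :func:`calibrate_reflectance`.
    """
    if sample.fx != reference.fx:
        raise ValueError(
            f"sample fx {sample.fx} differs from reference fx {reference.fx}"
        )
    mac_s = three_phase_amplitude(sample)
    mac_r = three_phase_amplitude(reference)
    return calibrate_reflectance(mac_s, mac_r, rd_ref, fx=sample.fx, mask_floor=mask_floor)
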