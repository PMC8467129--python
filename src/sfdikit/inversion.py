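"""Multi-frequency inversion of Rd(fx) to (mua, mus') and linear correction.

The calibrated reflectance spectrum measured at several spatial frequencies
is fit by bounded nonlinear least squares to the diffusion forward model; the
argmin over (mua, mus') is the recovered optical-property pair.  A phantom
series with known reference coefficients supplies a per-wavelength linear
correction ratio k = mean(ref/measured) that removes the residual
multiplicative system bias (TiO2 settling, source drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .forward_model import MediumConstants, OpticalProperties

__all__ = [
    "ReflectanceSpectrum",
    "InversionResult",
    "CorrectionFactors",
    "invert_point",
    "invert_map",
    "linear_correction",
    "apply_correction",
    "MUA_BOUNDS",
    "MUSP_BOUNDS",
]

#: Fit bounds, mm^-1.
MUA_BOUNDS = (1e-6, 5.0)
MUSP_BOUNDS = (1e-3, 10.0)

#: Primary and fallback initial guesses (mua, musp), mm^-1.
_X0_PRIMARY = (0.01, 1.0)
_X0_RETRY = (0.1, 0.5)


@dataclass
class ReflectanceSpectrum:
    """Calibrated diffuse reflectance sampled at several spatial frequencies."""

    fx: np.ndarray
    rd: np.ndarray

    def __post_init__(self) -> None:
        self.fx = np.asarray(self.fx, dtype=float)
        self.rd = np.asarray(self.rd, dtype=float)
        if self.fx.shape != self.rd.shape or self.fx.ndim != 1:
            raise ValueError("fx and rd must be 1-D arrays of equal length")

    def is_well_posed(self) -> bool:
        """At least two distinct frequencies with finite reflectance."""
        ok = np.isfinite(self.rd)
        return np.unique(self.fx[ok]).size >= 2


@dataclass
class InversionResult:
    """Recovered optical properties with fit diagnostics.

    ``converged`` is False for ill-posed spectra or optimiser failure; the
    property values are then the best available iterate, not a trusted
    estimate.
    """

    props: OpticalProperties
    residual_norm: float
    converged: bool
    message: str = ""
    n_frequencies: int = 0


@dataclass
class CorrectionFactors:
    """Per-wavelength multiplicative correction ratios for mua and mus'."""

    k_mua: float
    k_musp: float
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_mua <= 0 or self.k_musp <= 0:
            raise ValueError("correction ratios must be positive")


def _residuals(x: np.ndarray, fx: np.ndarray, rd: np.ndarray, medium: MediumConstants) -> np.ndarray:
    mutr = x[0] + x[1]
    mueff = np.sqrt(3.0 * x[0] * mutr)
    mueff_prime = np.sqrt(mueff**2 + (2.0 * np.pi * fx) ** 2)
    ratio = mueff_prime / mutr
    model = 3.0 * medium.a_const * x[1] / mutr / ((ratio + 1.0) * (ratio + 3.0 * medium.a_const))
    return model - rd


def invert_point(
    spec: ReflectanceSpectrum,
    medium: MediumConstants | None = None,
) -> InversionResult:
    """Fit (mua, mus') to one reflectance spectrum.

    Bounded trust-region least squares initialised at (0.01, 1.0) mm^-1 with
    one multi-start retry at (0.1, 0.5) if the first fit converges poorly.
    Ill-posed spectra (fewer than two distinct finite-frequency samples) are
    flagged rather than raised.
    """
    medium = medium or MediumConstants()
    ok = np.isfinite(spec.rd)
    fx, rd = spec.fx[ok], spec.rd[ok]
    if not spec.is_well_posed():
        return InversionResult(
            props=OpticalProperties(*_X0_PRIMARY),
            residual_norm=float("inf"),
            converged=False,
            message="ill-posed spectrum: need >= 2 distinct frequencies",
            n_frequencies=int(np.unique(fx).size),
        )
    lo = np.array([MUA_BOUNDS[0], MUSP_BOUNDS[0]])
    hi = np.array([MUA_BOUNDS[1], MUSP_BOUNDS[1]])

    def run(x0: tuple[float, float]):
        return least_squares(
            _residuals, x0, bounds=(lo, hi), args=(fx, rd, medium), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )

    sol = run(_X0_PRIMARY)
    # retry from the alternate start if the optimiser stalled high
    if not sol.success or sol.cost > 1e-6 * max(1, fx.size):
        sol2 = run(_X0_RETRY)
        if sol2.cost < sol.cost:
            sol = sol2
    props = OpticalProperties(mua=float(sol.x[0]), musp=float(sol.x[1]))
    return InversionResult(
        props=props,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
        message=str(sol.message),
        n_frequencies=int(np.unique(fx).size),
    )


def invert_map(
    rd_images: Sequence,
    medium: MediumConstants | None = None,
    bin_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (or per-superpixel) inversion of a set of reflectance images.

    Parameters
    ----------
    rd_images : sequence of ReflectanceImage
        One co-registered calibrated reflectance image per spatial frequency.
    medium : MediumConstants, optional
    bin_factor : int
        Optional b x b mean-binning applied before fitting, trading spatial
        resolution for speed; the returned maps are at the binned resolution.

    Returns
    -------
    (mua_map, musp_map) : ndarray pair
        Coefficient maps, mm^-1; pixels masked in any input frequency are NaN.
    """
    medium = medium or MediumConstants()
    if not rd_images:
        raise ValueError("need at least one reflectance image")
    shapes = {im.rd.shape for im in rd_images}
    if len(shapes) != 1:
        raise ValueError(f"reflectance images not co-registered: shapes {shapes}")
    fx = np.array([im.fx for im in rd_images], dtype=float)
    cube = np.stack([im.rd for im in rd_images])  # (nfreq, rows, cols)
    if bin_factor > 1:
        b = bin_factor
        nf, r, c = cube.shape
        cube = cube[:, : r - r % b, : c - c % b]
        cube = cube.reshape(nf, cube.shape[1] // b, b, cube.shape[2] // b, b).mean(axis=(2, 4))
    nf, rows, cols = cube.shape
    mua_map = np.full((rows, cols), np.nan)
    musp_map = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            rd = cube[:, i, j]
            if not np.all(np.isfinite(rd)):
                continue
            res = invert_point(ReflectanceSpectrum(fx=fx, rd=rd), medium)
            if res.converged:
                mua_map[i, j] = res.props.mua
                musp_map[i, j] = res.props.musp
    return mua_map, musp_map


def linear_correction(
    ref_values: Sequence[float], measured_values: Sequence[float]
) -> float:
    """Linear correction ratio k = mean(ref_i / measured_i) over a phantom set.

    The calibrated value is then k * measured (see :func:`apply_correction`).
    """
    ref = np.asarray(ref_values, dtype=float)
    mea = np.asarray(measured_values, dtype=float)
    if ref.shape != mea.shape or ref.ndim != 1 or ref.size < 1:
        raise ValueError("ref and measured must be equal-length 1-D sequences, m >= 1")
    if np.any(mea <= 0):
        raise ValueError("measured values must be positive")
    return float(np.mean(ref / mea))


def apply_correction(measured: float | np.ndarray, k: float) -> float | np.ndarray:
    """Calibrated value = k * measured."""
    return k * np.asarray(measured, dtype=float) if np.ndim(measured) else k * measured
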