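"""Diffusion-approximation forward model of spatially modulated diffuse reflectance.

In the spatial frequency domain, a homogeneous turbid slab illuminated by a
sinusoidal irradiance pattern of spatial frequency ``fx`` returns a diffuse
reflectance ``Rd(fx)`` that acts as the modulation transfer function of the
medium.  Under the standard diffusion approximation with an extrapolated
boundary condition,

    Rd(fx) = 3 A mus' / mutr / ((mueff'/mutr + 1) (mueff'/mutr + 3A))

with mutr = mua + mus' the transport attenuation coefficient,
mueff = sqrt(3 mua mutr) the effective attenuation coefficient,
mueff' = sqrt(mueff^2 + (2 pi fx)^2) its spatial-frequency-domain
generalisation, and A the boundary proportionality constant derived from the
effective internal reflection coefficient Reff of the refractive-index
mismatch.

All coefficients are expressed in mm^-1 and spatial frequencies in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalProperties",
    "MediumConstants",
    "effective_reflection_coefficient",
    "proportionality_constant",
    "diffuse_reflectance",
]

#: Linear coefficient of n in the empirical Reff polynomial.  The standard
#: diffusion-theory value; configurable through MediumConstants.
DEFAULT_REFF_LINEAR_COEFF = 0.0636

#: Default refractive index used for aqueous phantoms and fruit tissue.
DEFAULT_REFRACTIVE_INDEX = 1.35


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficients of a turbid medium.

    Attributes
    ----------
    mua : float
        Absorption coefficient, mm^-1.  Non-negative.
    musp : float
        Reduced scattering coefficient mus' = mus (1 - g), mm^-1.  Positive.
    """

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.musp <= 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")

    @property
    def mutr(self) -> float:
        """Transport (full attenuation) coefficient mua + mus', mm^-1."""
        return self.mua + self.musp

    @property
    def mueff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mua (mua + mus')), mm^-1."""
        return float(np.sqrt(3.0 * self.mua * self.mutr))


@dataclass(frozen=True)
class MediumConstants:
    """Boundary constants of the medium: refractive index and Reff polynomial.

    ``reff_linear_coeff`` is the coefficient of ``n`` in the empirical
    polynomial for the effective reflection coefficient.  The default 0.0636
    is the standard diffusion-theory value; combinations yielding Reff
    outside (0, 1) are rejected as unphysical.
    """

    n: float = DEFAULT_REFRACTIVE_INDEX
    reff_linear_coeff: float = DEFAULT_REFF_LINEAR_COEFF

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ValueError(f"refractive index must exceed 1, got {self.n}")

    @property
    def reff(self) -> float:
        return effective_reflection_coefficient(self.n, self.reff_linear_coeff)

    @property
    def a_const(self) -> float:
        return proportionality_constant(self.reff)


def effective_reflection_coefficient(
    n: float, coeff: float = DEFAULT_REFF_LINEAR_COEFF
) -> float:
    """Effective internal reflection coefficient of the index boundary.

    Reff = coeff*n + 0.668 + 0.71/n - 1.44/n^2

    Parameters
    ----------
    n : float
        Relative refractive index of the medium (> 1).
    coeff : float
        Linear coefficient of n, default 0.0636.

    Returns
    -------
    float
        Reff, dimensionless, validated to lie in (0, 1).

    Raises
    ------
    ValueError
        If n <= 1 or the resulting Reff falls outside (0, 1), which signals
        an unphysical coefficient / index combination.
    """
    if n <= 1:
        raise ValueError(f"refractive index must exceed 1, got {n}")
    reff = coeff * n + 0.668 + 0.71 / n - 1.44 / n**2
    if not 0.0 < reff < 1.0:
        raise ValueError(
            f"Reff = {reff:.5f} outside (0, 1) for n={n}, coeff={coeff}; "
            "unphysical combination"
        )
    return reff


def proportionality_constant(reff: float) -> float:
    """Boundary proportionality constant A = (1 - Reff) / (2 (1 + Reff)).

    A lies in (0, 0.5] for Reff in [0, 1).
    """
    if not 0.0 <= reff < 1.0:
        raise ValueError(f"Reff must lie in [0, 1), got {reff}")
    return (1.0 - reff) / (2.0 * (1.0 + reff))


def diffuse_reflectance(
    props: OpticalProperties,
    fx: float | np.ndarray,
    medium: MediumConstants | None = None,
) -> float | np.ndarray:
    """Diffuse reflectance Rd of a homogeneous medium at spatial frequency fx.

    Parameters
    ----------
    props : OpticalProperties
        (mua, mus') of the medium, mm^-1.
    fx : float or ndarray
        Spatial frequency (or frequencies) of the sinusoidal illumination,
        mm^-1, >= 0.
    medium : MediumConstants, optional
        Boundary constants; defaults to n = 1.35 with the standard Reff
        polynomial.

    Returns
    -------
    float or ndarray
        Rd(fx), dimensionless, in (0, 1]; strictly decreasing in fx and mua,
        increasing in mus'.
    """
    medium = medium or MediumConstants()
    fx_arr = np.asarray(fx, dtype=float)
    if np.any(fx_arr < 0):
        raise ValueError("spatial frequency must be >= 0")
    a = medium.a_const
    mutr = props.mutr
    mueff_prime = np.sqrt(props.mueff**2 + (2.0 * np.pi * fx_arr) ** 2)
    ratio = mueff_prime / mutr
    rd = 3.0 * a * props.musp / mutr / ((ratio + 1.0) * (ratio + 3.0 * a))
    if np.ndim(fx) == 0:
        return float(rd)
    return rd


def diffuse_reflectance_arrays(
    mua: np.ndarray,
    musp: np.ndarray,
    fx: float,
    medium: MediumConstants | None = None,
) -> np.ndarray:
    """Vectorised Rd over per-pixel (mua, mus') maps at one frequency.

    Same model as :func:`diffuse_reflectance` but broadcast over coefficient
    arrays; used by the scene simulator to render ground-truth maps.
    """
    medium = medium or MediumConstants()
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua < 0) or np.any(musp <= 0):
        raise ValueError("require mua >= 0 and musp > 0 everywhere")
    a = medium.a_const
    mutr = mua + musp
    mueff = np.sqrt(3.0 * mua * mutr)
    mueff_prime = np.sqrt(mueff**2 + (2.0 * np.pi * fx) ** 2)
    ratio = mueff_prime / mutr
    return 3.0 * a * musp / mutr / ((ratio + 1.0) * (ratio + 3.0 * a))
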