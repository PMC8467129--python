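"""Reference optical properties of liquid calibration phantoms.

Liquid phantoms are aqueous suspensions of India ink (absorber) and TiO2
particles (scatterer).  Reference absorption comes from the Beer-Lambert law
applied to collimated transmittance of the pure-absorber solution,
mua = -ln(T)/d.  Reference reduced scattering comes from Mie theory: the
scattering efficiency Qsca and asymmetry factor g of a single sphere give

    mus  = Qsca * (pi d^2 / 4) * N,     N = 6 vf / (pi d^3)
    mus' = mus * (1 - g)

under independent scattering (volume fractions <= 0.2%).

Two nine-sample series are used per wavelength: series 1 (#1-#9) fixes TiO2
at 0.1% and sweeps ink 0.004-0.02% (step 0.002%); series 2 (#10-#18) fixes
ink at 0.006% and sweeps TiO2 0.04-0.2% (step 0.02%).

The TiO2 particle diameter (500 nm), particle index (2.49) and the packaged
ink extinction spectrum are synthetic stand-in constants, spectrally
plausible but not measured values; reference coefficients computed from them
are reproducible in structure (exact linearity in the volume fractions), not
in absolute magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "MieInputs",
    "WAVELENGTHS_NM",
    "beer_lambert_mua",
    "mie_efficiencies",
    "mie_reduced_scattering",
    "phantom_series",
    "ink_extinction",
    "reference_table",
]

#: The six measurement wavelengths, nm.
WAVELENGTHS_NM = (460, 503, 527, 630, 658, 675)

#: Synthetic TiO2 particle defaults (see module docstring).
TIO2_DIAMETER_NM = 500.0
TIO2_INDEX = 2.49
WATER_INDEX = 1.33


@dataclass(frozen=True)
class PhantomSpec:
    """One liquid phantom: identifier and constituent volume fractions (%)."""

    label: str
    ink_vf: float  # percent
    tio2_vf: float  # percent

    def __post_init__(self) -> None:
        if self.ink_vf < 0 or self.tio2_vf < 0:
            raise ValueError("volume fractions must be non-negative")


@dataclass(frozen=True)
class MieInputs:
    """Inputs of the single-sphere Mie computation.

    diameter and wavelength in nm; volume_fraction dimensionless (not
    percent) and small enough for independent scattering.
    """

    diameter: float = TIO2_DIAMETER_NM
    n_particle: float = TIO2_INDEX
    n_medium: float = WATER_INDEX
    wavelength: float = 527.0
    volume_fraction: float = 0.001

    def __post_init__(self) -> None:
        if min(self.diameter, self.n_particle, self.n_medium, self.wavelength) <= 0:
            raise ValueError("all Mie inputs must be positive")
        if self.volume_fraction < 0 or self.volume_fraction > 0.05:
            raise ValueError("volume fraction must be in [0, 0.05] (independent scattering)")


def beer_lambert_mua(t: float, d: float) -> float:
    """Absorption coefficient from collimated transmittance: mua = -ln(T)/d.

    Parameters
    ----------
    t : float
        Collimated transmittance, 0 < T <= 1.
    d : float
        Optical path length, mm.

    Returns
    -------
    float
        mua in mm^-1.
    """
    if not 0 < t <= 1:
        raise ValueError(f"transmittance must be in (0, 1], got {t}")
    if d <= 0:
        raise ValueError("path length must be positive")
    return -float(np.log(t)) / d


def _wiscombe_nmax(x: float) -> int:
    """Series truncation order (Wiscombe criterion)."""
    if x < 0.02:
        return 2
    if x <= 8:
        return int(x + 4.0 * x ** (1.0 / 3.0) + 1.0) + 1
    if x < 4200:
        return int(x + 4.05 * x ** (1.0 / 3.0) + 2.0) + 1
    return int(x + 4.0 * x ** (1.0 / 3.0) + 2.0) + 1


def mie_efficiencies(m: complex, x: float) -> tuple[float, float, float]:
    """Mie Qext, Qsca and asymmetry factor g for one sphere.

    Bohren-Huffman formulation: the logarithmic derivative D_n(mx) by
    downward recurrence, Riccati-Bessel functions psi/chi by upward
    recurrence, then the partial-wave coefficients a_n, b_n.

    Parameters
    ----------
    m : complex
        Relative refractive index n_particle / n_medium.
    x : float
        Size parameter pi * d * n_medium / wavelength.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if x > 4200:
        raise ValueError("size parameter too large for this series implementation")
    nmax = _wiscombe_nmax(x)
    nmx = max(nmax, int(abs(m * x))) + 16
    # downward recurrence for D_n(mx)
    d = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    # upward recurrence for psi, chi
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    for n in range(1, nmax + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - (psi[n - 2] if n >= 2 else psi_m1)
        chi[n] = (2 * n - 1) / x * chi[n - 1] - (chi[n - 2] if n >= 2 else chi_m1)
    xi = psi - 1j * chi
    n_arr = np.arange(1, nmax + 1)
    dn = d[1 : nmax + 1]
    fa = dn / m + n_arr / x
    fb = dn * m + n_arr / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    two_n1 = 2 * n_arr + 1
    qext = 2.0 / x**2 * float(np.sum(two_n1 * (a + b).real))
    qsca = 2.0 / x**2 * float(np.sum(two_n1 * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    # asymmetry factor
    g_sum = 0.0
    g_sum += float(
        np.sum(
            n_arr[:-1]
            * (n_arr[:-1] + 2)
            / (n_arr[:-1] + 1)
            * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
        )
    )
    g_sum += float(np.sum(two_n1 / (n_arr * (n_arr + 1)) * (a * np.conj(b)).real))
    g = 4.0 / (x**2 * qsca) * g_sum if qsca > 0 else 0.0
    return qext, qsca, g


def mie_reduced_scattering(inputs: MieInputs) -> float:
    """Reduced scattering coefficient mus' (mm^-1) of a dilute sphere suspension."""
    if inputs.volume_fraction == 0:
        return 0.0
    m = inputs.n_particle / inputs.n_medium
    x = np.pi * inputs.diameter * inputs.n_medium / inputs.wavelength
    _, qsca, g = mie_efficiencies(m, x)
    d_mm = inputs.diameter * 1e-6
    number_density = 6.0 * inputs.volume_fraction / (np.pi * d_mm**3)  # mm^-3
    cross_section = qsca * np.pi * d_mm**2 / 4.0  # mm^2
    return float(number_density * cross_section * (1.0 - g))


def phantom_series() -> list[PhantomSpec]:
    """The eighteen phantom recipes of the two calibration series."""
    series = []
    for i, ink in enumerate(np.arange(0.004, 0.0201, 0.002)):
        series.append(PhantomSpec(label=f"#{i + 1}", ink_vf=round(float(ink), 4), tio2_vf=0.1))
    for j, tio2 in enumerate(np.arange(0.04, 0.201, 0.02)):
        series.append(
            PhantomSpec(label=f"#{j + 10}", ink_vf=0.006, tio2_vf=round(float(tio2), 3))
        )
    return series


def ink_extinction() -> pd.DataFrame:
    """Packaged synthetic ink extinction spectrum (mua per % volume fraction)."""
    with resources.files("sfdikit.data").joinpath("ink_extinction_synthetic.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def reference_table(
    specs: list[PhantomSpec] | None = None,
    wavelengths=WAVELENGTHS_NM,
    diameter_nm: float = TIO2_DIAMETER_NM,
    n_particle: float = TIO2_INDEX,
    n_medium: float = WATER_INDEX,
) -> pd.DataFrame:
    """Reference (mua, mus') for every phantom at every wavelength.

    mua_ref is linear in the ink volume fraction through the packaged
    extinction spectrum; mus'_ref is linear in the TiO2 volume fraction
    through the Mie cross-section.  Columns: label, ink_vf, tio2_vf,
    wavelength, mua_ref, musp_ref.
    """
    specs = specs or phantom_series()
    ext = ink_extinction().set_index("wavelength_nm")["mua_per_pct_vf"]
    rows = []
    for wl in wavelengths:
        if wl not in ext.index:
            raise KeyError(f"no ink extinction tabulated at {wl} nm")
        musp_unit = mie_reduced_scattering(
            MieInputs(
                diameter=diameter_nm,
                n_particle=n_particle,
                n_medium=n_medium,
                wavelength=float(wl),
                volume_fraction=0.01 / 100.0,  # per 0.01 %vf, scaled below
            )
        )
        for spec in specs:
            rows.append(
                {
                    "label": spec.label,
                    "ink_vf": spec.ink_vf,
                    "tio2_vf": spec.tio2_vf,
                    "wavelength": wl,
                    "mua_ref": float(ext.loc[wl]) * spec.ink_vf,
                    "musp_ref": musp_unit * (spec.tio2_vf / 0.01),
                }
            )
    return pd.DataFrame(rows)
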