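"""Acquisition simulator: renders phase stacks the pipeline can process.

The simulator produces exactly the data the demodulation stage assumes: for
each spatial frequency fx and phase offset 2 pi k / 3, a camera image

    Ik(x) = gain * [0.5 + 0.5 * Rd(x, fx) * cos(2 pi fx x_mm + 2 pi k / 3)] + noise

where Rd(x, fx) is the diffusion-model reflectance of the per-pixel
ground-truth (mua, mus') maps, and the whiteboard stack uses the constant
whiteboard reflectance instead.  Additive Gaussian noise is expressed as a
fraction of the camera gain.  The DC (fx = 0) channel is a single planar
image per role.

The illumination model is a pure AC/DC sinusoid: no projector modulation
transfer function, vignetting, gamma, or curvature effects.  This matches
the pipeline's working assumption that whiteboard normalisation removes the
system response; conclusions from simulated data therefore cover the
computational chain, not those physical non-idealities.

All randomness flows through one seeded generator per scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demodulation import DEFAULT_RD_REF, PhaseStack
from .forward_model import MediumConstants, diffuse_reflectance_arrays
from .keystone import THREE_PHASES

__all__ = [
    "SceneSpec",
    "DamageScene",
    "SimulatedAcquisition",
    "DAMAGE_CLASSES",
    "DEFAULT_PX_PER_MM",
    "simulate_stack",
    "make_damage_scene",
    "simulate_fringe_profile",
]

#: Camera pixels per mm on the sample plane (26 mm imaged over 400 px).
DEFAULT_PX_PER_MM = 400.0 / 26.0

#: Damage class labels: normal, bruised, scratched, abraded.
DAMAGE_CLASSES = ("A", "B", "C", "D")

#: Synthetic lesion effect sizes (relative change of mua, musp) per class.
#: Stand-in contrasts: damage raises absorption and lowers scattering.
LESION_EFFECTS = {
    "B": (0.30, -0.20),  # bruise: disc
    "C": (0.15, -0.10),  # scratch: thin stripes
    "D": (0.40, -0.35),  # abrasion: speckled patch
}

#: Lesion footprints as fractions of the scene, chosen from the forward
#: model's DC sensitivity analysis to reproduce the two confusion structures
#: the discrimination study rests on.  (1) Scratch effects are exactly half
#: the bruise effects, so scratch coverage = 2 x bruise coverage makes the
#: two classes' ROI means coincide -- bruise and scratch are the hard pair,
#: resolved only by the three-class regrouping.  (2) At the background
#: operating point dRd(0)/dln(mua) ~ -dRd(0)/dln(mus'), so planar light sees
#: only coverage*(d_mua - d_musp); abrasion coverage = 2/3 bruise coverage
#: makes abrasion and bruise metameric under planar illumination while they
#: remain separated in the (mua, mus') plane, which is what the SFDI feature
#: set adds over the planar one.
BRUISE_RADIUS_FRAC = 0.2115  # disc area fraction ~0.141
ABRASION_RADIUS_FRAC = 0.223  # with 0.6 speckle density: ~2/3 of bruise coverage
ABRASION_SPECKLE_DENSITY = 0.6
SCRATCH_STRIPES = 6
SCRATCH_WIDTH_FRAC = 0.047  # ~3 px (~1.2 mm) at 64-px scenes

#: Background optical properties (mm^-1) the lesions are drawn on.
BACKGROUND_MUA = 0.02
BACKGROUND_MUSP = 1.2


@dataclass
class SceneSpec:
    """Ground truth and acquisition parameters for one simulated scene."""

    mua_map: np.ndarray
    musp_map: np.ndarray
    fx_list: tuple[float, ...] = (0.0, 0.042, 0.084, 0.14)
    n: float = 1.35
    rd_ref: float = DEFAULT_RD_REF
    gain: float = 30000.0
    noise_sigma: float = 0.0
    px_per_mm: float = DEFAULT_PX_PER_MM
    seed: int = 0

    def __post_init__(self) -> None:
        self.mua_map = np.asarray(self.mua_map, dtype=float)
        self.musp_map = np.asarray(self.musp_map, dtype=float)
        if self.mua_map.shape != self.musp_map.shape:
            raise ValueError("coefficient maps must be co-registered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def medium(self) -> MediumConstants:
        return MediumConstants(n=self.n)


@dataclass
class DamageScene:
    """A damage scenario: coefficient maps, lesion mask and class label."""

    mua_map: np.ndarray
    musp_map: np.ndarray
    lesion_mask: np.ndarray
    label: str


@dataclass
class SimulatedAcquisition:
    """Rendered stacks: AC phase stacks plus planar (DC) images per role."""

    sample_stacks: dict = field(default_factory=dict)  # fx -> PhaseStack
    reference_stacks: dict = field(default_factory=dict)  # fx -> PhaseStack
    sample_planar: np.ndarray | None = None
    reference_planar: np.ndarray | None = None
    fx_list: tuple[float, ...] = ()

    @property
    def ac_frequencies(self) -> tuple[float, ...]:
        return tuple(sorted(self.sample_stacks))


def _render_stack(
    rd: np.ndarray, fx: float, gain: float, px_per_mm: float,
    noise_sigma: float, rng: np.random.Generator,
) -> PhaseStack:
    cols = np.arange(rd.shape[1], dtype=float)
    x_mm = cols / px_per_mm
    imgs = []
    for phase in THREE_PHASES:
        carrier = np.cos(2.0 * np.pi * fx * x_mm + phase)[None, :]
        img = gain * (0.5 + 0.5 * rd * carrier)
        if noise_sigma > 0:
            img = img + noise_sigma * gain * rng.standard_normal(rd.shape)
        imgs.append(img)
    return PhaseStack(i1=imgs[0], i2=imgs[1], i3=imgs[2], fx=fx)


def simulate_stack(scene: SceneSpec) -> SimulatedAcquisition:
    """Render sample and whiteboard acquisitions for every scene frequency.

    The DC channel (fx = 0) is rendered as one planar image per role
    (sample: gain * Rd(x, 0); whiteboard: gain * rd_ref); every positive
    frequency yields a three-phase stack per role.  Identical seeds produce
    bit-identical output.
    """
    rng = np.random.default_rng(scene.seed)
    acq = SimulatedAcquisition(fx_list=tuple(scene.fx_list))
    shape = scene.mua_map.shape
    for fx in scene.fx_list:
        rd = diffuse_reflectance_arrays(scene.mua_map, scene.musp_map, fx, scene.medium)
        rd_ref_map = np.full(shape, scene.rd_ref)
        if fx == 0:
            sample = scene.gain * rd
            ref = scene.gain * rd_ref_map
            if scene.noise_sigma > 0:
                sample = sample + scene.noise_sigma * scene.gain * rng.standard_normal(shape)
                ref = ref + scene.noise_sigma * scene.gain * rng.standard_normal(shape)
            acq.sample_planar = sample
            acq.reference_planar = ref
        else:
            acq.sample_stacks[fx] = _render_stack(
                rd, fx, scene.gain, scene.px_per_mm, scene.noise_sigma, rng
            )
            acq.reference_stacks[fx] = _render_stack(
                rd_ref_map, fx, scene.gain, scene.px_per_mm, scene.noise_sigma, rng
            )
    return acq


def make_damage_scene(
    class_label: str,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    background_jitter: float = 0.002,
    effect_jitter: float = 0.05,
) -> DamageScene:
    """Draw a damage scenario with class-specific lesion geometry and contrast.

    Lesion geometries: none (A, normal), centred disc (B, bruise), thin
    vertical stripes (C, scratch), speckled patch (D, abrasion).  Background
    coefficients, lesion footprints and effect sizes carry seeded
    multiplicative jitter, so two seeds give different placements but the
    same class statistics.
    """
    if class_label not in DAMAGE_CLASSES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {DAMAGE_CLASSES}")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    mua_bg = BACKGROUND_MUA * (1.0 + background_jitter * rng.standard_normal())
    musp_bg = BACKGROUND_MUSP * (1.0 + background_jitter * rng.standard_normal())
    mua_map = np.full(shape, mua_bg)
    musp_map = np.full(shape, musp_bg)
    mask = np.zeros(shape, dtype=bool)

    cy = rows / 2 + rng.uniform(-rows * 0.05, rows * 0.05)
    cx = cols / 2 + rng.uniform(-cols * 0.05, cols * 0.05)
    yy, xx = np.mgrid[0:rows, 0:cols]

    if class_label == "B":
        radius = BRUISE_RADIUS_FRAC * min(rows, cols) * rng.uniform(0.97, 1.03)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    elif class_label == "C":
        width = max(1, int(round(SCRATCH_WIDTH_FRAC * cols)))
        starts = rng.choice(
            np.arange(int(0.1 * cols), int(0.9 * cols) - width, width + 1),
            size=SCRATCH_STRIPES,
            replace=False,
        )
        for col0 in starts:
            mask[:, col0 : col0 + width] = True
    elif class_label == "D":
        radius = ABRASION_RADIUS_FRAC * min(rows, cols) * rng.uniform(0.97, 1.03)
        patch = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        speckle = rng.random(shape) < ABRASION_SPECKLE_DENSITY
        mask = patch & speckle

    if class_label != "A":
        d_mua, d_musp = LESION_EFFECTS[class_label]
        d_mua *= rng.uniform(1 - effect_jitter, 1 + effect_jitter)
        d_musp *= rng.uniform(1 - effect_jitter, 1 + effect_jitter)
        mua_map[mask] = mua_bg * (1.0 + d_mua)
        musp_map[mask] = musp_bg * (1.0 + d_musp)
    return DamageScene(mua_map=mua_map, musp_map=musp_map, lesion_mask=mask, label=class_label)


def simulate_fringe_profile(
    period_px: float,
    bias: float = 1.0,
    noise: float = 0.0,
    length: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """1-D fringe profile with an optional multiplicative period bias.

    Fixture for the frequency-calibration stage: a cosine of realised period
    ``period_px * bias`` with optional additive Gaussian noise, seeded.
    """
    if period_px < 2:
        raise ValueError("period must be >= 2 px")
    if length <= 0:
        raise ValueError("length must be positive")
    if bias <= 0:
        raise ValueError("bias must be positive")
    x = np.arange(length, dtype=float)
    profile = 0.5 + 0.5 * np.cos(2.0 * np.pi * x / (period_px * bias))
    if noise > 0:
        profile = profile + noise * np.random.default_rng(seed).standard_normal(length)
    return profile
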