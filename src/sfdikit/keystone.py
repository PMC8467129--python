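"""Projector pattern generation, keystone pre-correction, and fringe-uniformity error.

A tilted projector maps a rectangular pattern to a trapezoid on the sample
plane (keystone distortion), which bends the projected sinusoidal fringes and
perturbs their local frequency.  The geometry is a pinhole projector with
intrinsics (fu, fv, cu, cv), mounted at height ``h`` above the target plane
and rotated by pitch ``alpha`` (about the image x-axis) then yaw ``beta``
(about the image y-axis); roll is assumed zero.

Coordinate conventions
----------------------
Projector pixel (u, v): u along image columns, v along rows, origin top-left.
World frame: origin at the projector optical centre, z up; the target plane
is z = -h.  At zero tilt the principal ray pierces the plane at (0, 0) and a
pixel (u, v) lands at (h (u-cu)/fu, h (v-cv)/fv).

Pre-correction resamples the pattern so that its projection *through the
tilted geometry* lands on the plane as the undistorted sinusoid; the
uniformity of the result is scored by ``keystone_error`` (mean per-column
standard deviation of the min-max normalised fringe image, which is zero for
perfectly vertical straight fringes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ProjectorGeometry",
    "SinusoidSpec",
    "THREE_PHASES",
    "image_to_world",
    "world_to_image",
    "generate_sinusoid",
    "correct_pattern",
    "correct_pattern_image",
    "simulate_projection",
    "plane_window_for",
    "keystone_error",
    "angle_sweep",
]

#: Native projector resolution (rows, cols).
NATIVE_SHAPE = (800, 1280)

#: Phase offsets of a three-phase acquisition, radians.
THREE_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass(frozen=True)
class ProjectorGeometry:
    """Pinhole projector intrinsics and mounting pose.

    fu, fv, cu, cv in pixels; h in mm; alpha (pitch) and beta (yaw) in
    degrees.  Positive pitch tilts the optical axis away from vertical
    (toward the camera in the physical rig).
    """

    fu: float
    fv: float
    cu: float
    cv: float
    h: float
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.fu <= 0 or self.fv <= 0:
            raise ValueError("focal lengths must be positive")
        if self.h <= 0:
            raise ValueError("height must be positive")
        if not (abs(self.alpha) < 90 and abs(self.beta) < 90):
            raise ValueError("|alpha| and |beta| must be < 90 degrees")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-projector rotation Rx(pitch) @ Ry(yaw)."""
        a = np.deg2rad(self.alpha)
        b = np.deg2rad(self.beta)
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        return rx @ ry

    def at_angles(self, alpha: float, beta: float) -> "ProjectorGeometry":
        return replace(self, alpha=alpha, beta=beta)


@dataclass(frozen=True)
class SinusoidSpec:
    """A sinusoidal fringe pattern: 0.5 + 0.5 cos(2 pi u / Tp + phase).

    ``period_px`` is the generation period Tp along the fringe-normal axis
    (image columns); three-phase sets use phases {0, 2pi/3, 4pi/3}.
    """

    period_px: float
    phase: float = 0.0
    size: tuple[int, int] = NATIVE_SHAPE
    orientation: str = "vertical"  # vertical fringes vary along columns

    def __post_init__(self) -> None:
        if self.period_px <= 1:
            raise ValueError(f"period must exceed 1 px, got {self.period_px}")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")

    def value_at(self, u: np.ndarray) -> np.ndarray:
        """Pattern value at (possibly fractional, unclipped) column coordinate."""
        return 0.5 + 0.5 * np.cos(2.0 * np.pi * np.asarray(u) / self.period_px + self.phase)


def image_to_world(
    points: np.ndarray, geom: ProjectorGeometry
) -> np.ndarray:
    """Intersect projector-pixel rays with the target plane z = -h.

    Parameters
    ----------
    points : (..., 2) array
        Pixel coordinates (u, v).
    geom : ProjectorGeometry

    Returns
    -------
    (..., 2) array
        Plane coordinates (x, y) in mm.

    Raises
    ------
    ValueError
        If any ray is parallel to (or points away from) the plane.
    """
    pts = np.asarray(points, dtype=float)
    u, v = pts[..., 0], pts[..., 1]
    # ray direction in projector frame, z pointing down toward the plane
    d = np.stack(
        [(u - geom.cu) / geom.fu, (v - geom.cv) / geom.fv, -np.ones_like(u)], axis=-1
    )
    dw = d @ geom.rotation.T
    dz = dw[..., 2]
    if np.any(dz >= -1e-12):
        raise ValueError("ray parallel to or directed away from the target plane")
    t = -geom.h / dz
    return np.stack([t * dw[..., 0], t * dw[..., 1]], axis=-1)


def world_to_image(
    points: np.ndarray, geom: ProjectorGeometry
) -> np.ndarray:
    """Map plane points (x, y) on z = -h back to projector pixel coordinates.

    Exact inverse of :func:`image_to_world` on its domain.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[..., 0], pts[..., 1]
    vw = np.stack([x, y, -geom.h * np.ones_like(x)], axis=-1)
    dp = vw @ geom.rotation  # R.T applied on the right
    dz = dp[..., 2]
    if np.any(dz >= -1e-12):
        raise ValueError("plane point behind the projector")
    scale = -1.0 / dz
    u = geom.cu + geom.fu * dp[..., 0] * scale
    v = geom.cv + geom.fv * dp[..., 1] * scale
    return np.stack([u, v], axis=-1)


def generate_sinusoid(spec: SinusoidSpec) -> np.ndarray:
    """Render an ideal sinusoidal pattern image with values in [0, 1]."""
    rows, cols = spec.size
    if spec.orientation == "vertical":
        u = np.arange(cols, dtype=float)
        line = spec.value_at(u)
        return np.tile(line, (rows, 1))
    v = np.arange(rows, dtype=float)
    line = spec.value_at(v)
    return np.tile(line[:, None], (1, cols))


def correct_pattern(spec: SinusoidSpec, geom: ProjectorGeometry) -> np.ndarray:
    """Pre-distort a sinusoid so its tilted projection is undistorted.

    For each projector pixel, the ray is traced through the tilted geometry
    to the plane, and the pattern value is evaluated analytically at the
    column coordinate a zero-tilt projector would need for that plane point.
    Projecting the result at the true angles therefore reproduces the ideal
    straight-fringe sinusoid on the plane.  At alpha = beta = 0 the output
    equals :func:`generate_sinusoid` exactly.
    """
    rows, cols = spec.size
    uu, vv = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    pix = np.stack([uu, vv], axis=-1)
    world = image_to_world(pix, geom)
    ref = world_to_image(world, geom.at_angles(0.0, 0.0))
    coord = ref[..., 0] if spec.orientation == "vertical" else ref[..., 1]
    return spec.value_at(coord)


def correct_pattern_image(
    pattern: np.ndarray, geom: ProjectorGeometry
) -> np.ndarray:
    """Image-based variant of :func:`correct_pattern` for arbitrary patterns.

    Bilinear resampling; target pixels whose reference coordinate falls
    outside the pattern frame are set to 0 (with a warning when the clipped
    fraction is substantial).
    """
    pattern = np.asarray(pattern, dtype=float)
    rows, cols = pattern.shape
    uu, vv = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    world = image_to_world(np.stack([uu, vv], axis=-1), geom)
    ref = world_to_image(world, geom.at_angles(0.0, 0.0))
    out = map_coordinates(
        pattern, [ref[..., 1].ravel(), ref[..., 0].ravel()], order=1, cval=0.0
    ).reshape(rows, cols)
    outside = (
        (ref[..., 0] < 0) | (ref[..., 0] > cols - 1)
        | (ref[..., 1] < 0) | (ref[..., 1] > rows - 1)
    )
    if outside.mean() > 0.25:
        warnings.warn(
            f"{outside.mean():.0%} of the corrected pattern falls outside the "
            "projector frame and was cropped to 0",
            stacklevel=2,
        )
    return out


def plane_window_for(
    geom: ProjectorGeometry, shape: tuple[int, int] | None = None, margin: float = 0.1
) -> tuple[float, float, float, float]:
    """Axis-aligned (xmin, xmax, ymin, ymax) mm rectangle inside the footprint.

    Conservative inscribed rectangle of the projector's illuminated
    quadrilateral on the plane, shrunk by ``margin`` on each side.
    """
    from shapely.geometry import Polygon, box

    rows, cols = shape or NATIVE_SHAPE
    corners = np.array(
        [[0, 0], [cols - 1, 0], [cols - 1, rows - 1], [0, rows - 1]], dtype=float
    )
    quad = Polygon(image_to_world(corners, geom))
    cx, cy = quad.centroid.x, quad.centroid.y
    bx_min, by_min, bx_max, by_max = quad.bounds
    hw, hh = (bx_max - bx_min) / 2, (by_max - by_min) / 2
    for scale in np.linspace(1.0 - margin, 0.05, 40):
        rect = box(cx - scale * hw, cy - scale * hh, cx + scale * hw, cy + scale * hh)
        if rect.within(quad):
            return (cx - scale * hw, cx + scale * hw, cy - scale * hh, cy + scale * hh)
    raise ValueError("could not inscribe a plane window in the projector footprint")


def simulate_projection(
    pattern, geom: ProjectorGeometry,
    window: tuple[float, float, float, float],
    shape: tuple[int, int] = (200, 200),
) -> np.ndarray:
    """Render the pattern as seen on the target plane by an ideal nadir camera.

    ``pattern`` may be a 2-D image (bilinear-resampled; out-of-frame plane
    points become NaN) or a callable mapping pixel coordinates ``(..., 2)``
    to intensities (evaluated analytically, no clipping).  ``window`` is the
    (xmin, xmax, ymin, ymax) plane rectangle in mm; ``shape`` the rendered
    (rows, cols) sampling of that rectangle, x along columns.
    """
    xmin, xmax, ymin, ymax = window
    rows, cols = shape
    xs = np.linspace(xmin, xmax, cols)
    ys = np.linspace(ymin, ymax, rows)
    xx, yy = np.meshgrid(xs, ys)
    pix = world_to_image(np.stack([xx, yy], axis=-1), geom)
    if callable(pattern):
        return pattern(pix)
    pattern = np.asarray(pattern, dtype=float)
    prow, pcol = pattern.shape
    out = map_coordinates(
        pattern, [pix[..., 1].ravel(), pix[..., 0].ravel()], order=1, cval=np.nan
    ).reshape(rows, cols)
    outside = (
        (pix[..., 0] < 0) | (pix[..., 0] > pcol - 1)
        | (pix[..., 1] < 0) | (pix[..., 1] > prow - 1)
    )
    out[outside] = np.nan
    return out


def keystone_error(image: np.ndarray, ddof: int = 1) -> float:
    """Fringe-uniformity error: mean per-column std of the normalised image.

    The image (vertical fringes, intensity varying along columns) is min-max
    normalised to [0, 1]; the standard deviation of each column is averaged
    over columns.  Perfectly straight vertical fringes give 0.  ``ddof=1``
    (sample std) by default; configurable.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2 or img.shape[0] < 2:
        raise ValueError("need a 2-D image with at least 2 rows")
    lo, hi = np.nanmin(img), np.nanmax(img)
    norm = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    return float(np.nanmean(np.nanstd(norm, axis=0, ddof=ddof)))


def angle_sweep(
    ep_fn,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Grid-search the fringe-uniformity error over candidate (alpha, beta).

    Parameters
    ----------
    ep_fn : callable(alpha, beta) -> float
        Evaluates the keystone error for one candidate angle pair, e.g. by
        correcting a pattern at the candidate angles and simulating its
        projection through the true geometry.
    alphas, betas : 1-D arrays, degrees
        Candidate grids; defaults are pitch 12..22 step 1 and yaw 0..1
        step 0.1.

    Returns
    -------
    (alpha_best, beta_best, surface)
        Argmin of the error and the full error surface, shape
        (len(alphas), len(betas)).  Ties resolve to the lowest alpha, then
        the lowest beta, with a warning.
    """
    alphas = np.asarray(
        alphas if alphas is not None else np.arange(12.0, 22.0 + 0.5, 1.0)
    )
    betas = np.asarray(
        betas if betas is not None else np.round(np.arange(0.0, 1.0 + 0.05, 0.1), 10)
    )
    surface = np.empty((alphas.size, betas.size))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            surface[i, j] = ep_fn(float(a), float(b))
    flat = np.argmin(surface)  # first occurrence: lowest alpha, then beta
    i, j = np.unravel_index(flat, surface.shape)
    if np.count_nonzero(np.isclose(surface, surface[i, j], rtol=0, atol=0)) > 1:
        warnings.warn("tied error surface minimum; returning lowest (alpha, beta)", stacklevel=2)
    return float(alphas[i]), float(betas[j]), surface


def corrected_projection_error(
    candidate: tuple[float, float],
    true_geom: ProjectorGeometry,
    spec: SinusoidSpec,
    window: tuple[float, float, float, float] | None = None,
    shape: tuple[int, int] = (160, 160),
) -> float:
    """ep of a pattern corrected at candidate angles, projected at the true pose.

    The closed loop used by the angle sweep: pre-correct the sinusoid
    assuming the candidate (alpha, beta), project it through the actual
    geometry, and score the fringe uniformity of the plane image.
    """
    cand_geom = true_geom.at_angles(*candidate)
    window = window or plane_window_for(true_geom, spec.size)

    def projected(pix: np.ndarray) -> np.ndarray:
        world = image_to_world(pix, cand_geom)
        ref = world_to_image(world, cand_geom.at_angles(0.0, 0.0))
        coord = ref[..., 0] if spec.orientation == "vertical" else ref[..., 1]
        return spec.value_at(coord)

    plane = simulate_projection(projected, true_geom, window, shape)
    return keystone_error(plane)
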