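"""ROI feature extraction and LDA discrimination of fruit surface damage.

Two feature models are compared.  The SFDI model inverts the multi-frequency
reflectance into (mua, mus') maps and uses the ROI means of both
coefficients; the planar model uses the ROI mean of the calibrated DC
(fx = 0) reflectance only, since a single planar measurement cannot separate
absorption from scattering.  Class labels: A normal, B bruised, C scratched,
D abraded; the three-class regrouping keeps A as normal, merges {B, C} into
minor damage, and calls D serious damage.

Accuracy is estimated by stratified k-fold cross-validation (default five
folds, seeded fold assignment) of a linear discriminant classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .demodulation import demodulate_stack, planar_reflectance
from .inversion import invert_map
from .synthetic import DAMAGE_CLASSES, SceneSpec, make_damage_scene, simulate_stack

__all__ = [
    "SampleFeatures",
    "extract_features",
    "regroup_classes",
    "lda_crossval",
    "build_cohort",
    "THREE_CLASS_MAP",
]

#: Three-class regrouping: bruise and scratch are both minor damage.
THREE_CLASS_MAP = {"A": "normal", "B": "minor", "C": "minor", "D": "serious"}


@dataclass
class SampleFeatures:
    """Per-sample feature vector with its class label."""

    sample_id: str
    features: np.ndarray
    label: str
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"non-finite features for sample {self.sample_id}")


def _bin2(img: np.ndarray, factor: int) -> np.ndarray:
    r, c = img.shape
    img = img[: r - r % factor, : c - c % factor]
    return img.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


def extract_features(
    maps: dict[str, np.ndarray],
    roi_origin: tuple[int, int] = (0, 0),
    roi_size: int | None = None,
    bin_factor: int = 2,
) -> np.ndarray:
    """Scalar ROI features from coefficient (or reflectance) maps.

    The ROI is cropped at ``roi_origin`` with side ``roi_size`` (whole map by
    default), mean-binned by ``bin_factor`` to cut processing volume, then
    averaged to one scalar per map.  The feature vector follows the sorted
    key order of ``maps`` (e.g. {"mua": ..., "musp": ...} -> [mean mua,
    mean musp]).
    """
    feats = []
    for key in sorted(maps):
        m = np.asarray(maps[key], dtype=float)
        r0, c0 = roi_origin
        size = roi_size or min(m.shape)
        if r0 + size > m.shape[0] or c0 + size > m.shape[1]:
            raise ValueError(
                f"ROI {size}x{size} at {roi_origin} exceeds map shape {m.shape}"
            )
        roi = m[r0 : r0 + size, c0 : c0 + size]
        if bin_factor > 1:
            roi = _bin2(roi, bin_factor)
        feats.append(float(np.nanmean(roi)))
    return np.asarray(feats)


def regroup_classes(labels, scheme: str = "four") -> list[str]:
    """Map four damage labels to the requested grouping scheme.

    ``four`` is the identity on {A, B, C, D}; ``three`` maps A -> normal,
    {B, C} -> minor, D -> serious.
    """
    if scheme not in ("four", "three"):
        raise ValueError(f"unknown scheme {scheme!r}")
    out = []
    for lab in labels:
        if lab not in DAMAGE_CLASSES:
            raise ValueError(f"unknown label {lab!r}")
        out.append(lab if scheme == "four" else THREE_CLASS_MAP[lab])
    return out


def lda_crossval(
    features: list[SampleFeatures],
    k: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray, list[str]]:
    """Stratified k-fold cross-validated LDA accuracy and confusion matrix.

    Returns (accuracy %, confusion matrix with rows = true class, columns =
    predicted class, class order).  Raises if k < 2 or a class is too small
    to appear in every training fold.
    """
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    x = np.stack([f.features for f in features])
    y = np.asarray([f.label for f in features])
    classes = sorted(set(y))
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < k:
        raise ValueError(f"class counts {counts} too small for {k} stratified folds")
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    hits = 0
    for train, test in skf.split(x, y):
        model = LinearDiscriminantAnalysis()
        model.fit(x[train], y[train])
        pred = model.predict(x[test])
        hits += int(np.sum(pred == y[test]))
        for t, p in zip(y[test], pred):
            confusion[idx[t], idx[p]] += 1
    accuracy = 100.0 * hits / y.size
    return accuracy, confusion, classes


def build_cohort(
    n_per_class: int = 20,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    fx_list: tuple[float, ...] = (0.0, 0.042, 0.084, 0.14),
    noise_sigma: float = 0.002,
    bin_factor: int = 16,
) -> tuple[list[SampleFeatures], list[SampleFeatures]]:
    """Simulate a damage cohort and extract SFDI and planar features.

    For each of ``n_per_class`` scenes per class, the full chain runs:
    damage scene -> phase stacks -> demodulation + whiteboard calibration ->
    superpixel inversion -> ROI-mean features.  Returns (sfdi_features,
    planar_features) lists; SFDI features are (mean mua, mean mus'), planar
    features the mean calibrated DC reflectance.
    """
    rng = np.random.default_rng(seed)
    sfdi, planar = [], []
    for label in DAMAGE_CLASSES:
        for i in range(n_per_class):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            scene = make_damage_scene(label, seed=scene_seed, shape=shape)
            spec = SceneSpec(
                mua_map=scene.mua_map,
                musp_map=scene.musp_map,
                fx_list=fx_list,
                noise_sigma=noise_sigma,
                seed=scene_seed,
            )
            acq = simulate_stack(spec)
            rd_images = [
                demodulate_stack(acq.sample_stacks[fx], acq.reference_stacks[fx])
                for fx in acq.ac_frequencies
            ]
            dc = planar_reflectance(acq.sample_planar, acq.reference_planar)
            rd_images.append(dc)
            mua_map, musp_map = invert_map(rd_images, bin_factor=bin_factor)
            sid = f"{label}{i:02d}"
            sfdi.append(
                SampleFeatures(
                    sample_id=sid,
                    features=extract_features({"mua": mua_map, "musp": musp_map}, bin_factor=1),
                    label=label,
                )
            )
            planar.append(
                SampleFeatures(
                    sample_id=sid,
                    features=extract_features({"rd0": dc.rd}, bin_factor=2),
                    label=label,
                )
            )
    return sfdi, planar
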