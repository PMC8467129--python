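"""Acquisition manifests, TIFF stack I/O, and the end-to-end pipeline driver.

Raw stacks are 16-bit unsigned grayscale TIFFs addressed by a YAML manifest:
one record per image with (path, role sample|reference, fx mm^-1, phase
index 0-2), plus run-level configuration (refractive index, whiteboard
reflectance, seed).  Every (role, fx > 0) pair must carry exactly the three
phases {0, 1, 2}; the DC channel (fx = 0) has a single record per role.
Coefficient maps are written as 32-bit float TIFFs with a JSON diagnostics
sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .demodulation import DEFAULT_RD_REF, PhaseStack, demodulate_stack, planar_reflectance
from .forward_model import MediumConstants
from .inversion import invert_map

__all__ = [
    "AcquisitionManifest",
    "ManifestError",
    "load_manifest",
    "write_acquisition",
    "read_stacks",
    "write_maps",
    "run_pipeline",
]

MANIFEST_NAME = "manifest.yaml"


class ManifestError(ValueError):
    """Manifest validation failure; the message lists every violation."""


@dataclass
class AcquisitionManifest:
    """Validated acquisition manifest: image records plus run configuration."""

    root: Path
    records: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def frequencies(self) -> list[float]:
        return sorted({r["fx"] for r in self.records})

    def paths_for(self, role: str, fx: float) -> list[Path]:
        recs = [r for r in self.records if r["role"] == role and r["fx"] == fx]
        return [self.root / r["path"] for r in sorted(recs, key=lambda r: r["phase"])]


def _validate(records: list[dict], root: Path) -> list[str]:
    problems = []
    if not records:
        return ["manifest contains no image records"]
    seen = set()
    for r in records:
        key = (r.get("role"), r.get("fx"), r.get("phase"))
        if key in seen:
            problems.append(f"duplicate record {key}")
        seen.add(key)
        if r.get("role") not in ("sample", "reference"):
            problems.append(f"record {r}: role must be sample|reference")
        if not (root / r.get("path", "")).is_file():
            problems.append(f"missing file {r.get('path')}")
    by_group: dict[tuple, set] = {}
    for r in records:
        by_group.setdefault((r["role"], r["fx"]), set()).add(r["phase"])
    for (role, fx), phases in sorted(by_group.items()):
        want = {0} if fx == 0 else {0, 1, 2}
        if phases != want:
            problems.append(
                f"{role} at fx={fx}: phases {sorted(phases)} != required {sorted(want)}"
            )
    return problems


def load_manifest(path: str | Path) -> AcquisitionManifest:
    """Load and validate a YAML manifest; aggregate every violation found."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ManifestError(f"{path}: manifest must be a mapping")
    records = data.get("records") or []
    root = path.parent
    problems = _validate(records, root)
    if problems:
        raise ManifestError(
            f"{path}: {len(problems)} manifest problem(s):\n  " + "\n  ".join(problems)
        )
    return AcquisitionManifest(root=root, records=records, config=data.get("config", {}))


def write_acquisition(acq, outdir: str | Path, config: dict | None = None) -> Path:
    """Write a simulated acquisition as 16-bit TIFFs plus a YAML manifest.

    Images are scaled-clipped into uint16 range as-is (the simulator's gain
    already places them there).  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []

    def save(img: np.ndarray, name: str) -> None:
        arr = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        tifffile.imwrite(outdir / name, arr)

    for role, stacks in (("sample", acq.sample_stacks), ("reference", acq.reference_stacks)):
        for fx, stack in sorted(stacks.items()):
            for phase, img in enumerate((stack.i1, stack.i2, stack.i3)):
                name = f"{role}_fx{fx:.4f}_p{phase}.tif"
                save(img, name)
                records.append({"path": name, "role": role, "fx": float(fx), "phase": phase})
    for role, img in (("sample", acq.sample_planar), ("reference", acq.reference_planar)):
        if img is not None:
            name = f"{role}_fx0.0000_p0.tif"
            save(img, name)
            records.append({"path": name, "role": role, "fx": 0.0, "phase": 0})
    manifest_path = outdir / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"records": records, "config": config or {}}, fh, sort_keys=False)
    return manifest_path


def read_stacks(manifest: AcquisitionManifest):
    """Read the manifest's TIFFs back into per-frequency stacks.

    Returns (sample_stacks, reference_stacks, sample_planar,
    reference_planar) matching the simulator's in-memory layout.
    """
    sample_stacks, reference_stacks = {}, {}
    sample_planar = reference_planar = None
    for fx in manifest.frequencies:
        for role in ("sample", "reference"):
            imgs = [tifffile.imread(p).astype(float) for p in manifest.paths_for(role, fx)]
            if fx == 0:
                if role == "sample":
                    sample_planar = imgs[0]
                else:
                    reference_planar = imgs[0]
            else:
                stack = PhaseStack(i1=imgs[0], i2=imgs[1], i3=imgs[2], fx=fx)
                (sample_stacks if role == "sample" else reference_stacks)[fx] = stack
    return sample_stacks, reference_stacks, sample_planar, reference_planar


def write_maps(
    mua_map: np.ndarray, musp_map: np.ndarray, outdir: str | Path,
    diagnostics: dict | None = None,
) -> None:
    """Write coefficient maps as float32 TIFFs with a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "mua.tif", np.asarray(mua_map, dtype=np.float32))
    tifffile.imwrite(outdir / "musp.tif", np.asarray(musp_map, dtype=np.float32))
    with open(outdir / "fit_diagnostics.json", "w") as fh:
        json.dump(diagnostics or {}, fh, indent=2)


def run_pipeline(
    manifest: AcquisitionManifest,
    outdir: str | Path | None = None,
    bin_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Demodulate, calibrate and invert a full acquisition.

    Executes the stages in order: three-phase demodulation and whiteboard
    calibration of every AC frequency, planar calibration of the DC channel,
    then per-pixel (or binned) multi-frequency inversion.  Deterministic
    given identical inputs.  Returns (mua_map, musp_map) and optionally
    writes them under ``outdir``.
    """
    cfg = manifest.config
    rd_ref = float(cfg.get("rd_ref", DEFAULT_RD_REF))
    medium = MediumConstants(n=float(cfg.get("n", MediumConstants().n)))
    if not manifest.frequencies:
        raise ManifestError("configuration lists zero frequencies")
    sample_stacks, reference_stacks, sample_planar, reference_planar = read_stacks(manifest)
    rd_images = [
        demodulate_stack(sample_stacks[fx], reference_stacks[fx], rd_ref=rd_ref)
        for fx in sorted(sample_stacks)
    ]
    if sample_planar is not None and reference_planar is not None:
        rd_images.append(planar_reflectance(sample_planar, reference_planar, rd_ref=rd_ref))
    mua_map, musp_map = invert_map(rd_images, medium=medium, bin_factor=bin_factor)
    if outdir is not None:
        write_maps(
            mua_map, musp_map, outdir,
            diagnostics={
                "frequencies": manifest.frequencies,
                "n": medium.n,
                "rd_ref": rd_ref,
                "bin_factor": bin_factor,
            },
        )
    return mua_map, musp_map
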