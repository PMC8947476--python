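"""File I/O (NIfTI, DICOM series), run configuration and orchestration.

Images are kept axis-aligned: the in-memory axes (i, j, k) map to world
(x, y, z) with world = origin + index * spacing.  NIfTI files with oblique
rotation in the affine and DICOM series with non-identity orientation are
rejected at load time rather than silently resampled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import yaml

from .features import FeatureSpec
from .image_model import BinaryMask, SeedPoint, VolumetricImage, mask_volume_ccm, max_diameter_mm
from .segmentation import texture_region_grow, threshold_segment

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "run_segment",
]

_METHOD_FEATURES = {
    "kurtosis": "kurtosis",
    "entropy": "local_entropy",
    "lze": "long_zone_emphasis",
}


def _check_axis_aligned(affine: np.ndarray) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError("invalid or missing voxel spacing")
    direction = rot / spacing
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-3):
        raise ValueError("oblique image orientations are not supported")
    return tuple(float(s) for s in spacing), tuple(float(o) for o in affine[:3, 3])


def _read_nifti(path: Path) -> VolumetricImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError("3D volume required")
    spacing, origin = _check_axis_aligned(img.affine)
    return VolumetricImage(np.asarray(data, dtype=float), spacing, origin)


def _read_dicom_series(path: Path) -> VolumetricImage:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if len(slices) < 2:
        raise ValueError("3D volume required: need at least two DICOM slices")
    series = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(series) != 1:
        raise ValueError("mixed series: directory contains more than one DICOM series")
    first = slices[0]
    orient = np.asarray(getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    if not np.allclose(np.abs(orient), [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise ValueError("oblique image orientations are not supported")
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing spacing: PixelSpacing absent")
    normal = np.cross(orient[:3], orient[3:])
    # sort slices by position along the slice normal
    slices.sort(key=lambda ds: float(np.dot(normal, ds.ImagePositionPatient)))
    zpos = [float(np.dot(normal, ds.ImagePositionPatient)) for ds in slices]
    dz = np.diff(zpos)
    if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError("missing spacing: slice positions are not uniformly spaced")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + inter)
    # pixel_array is (row, col) = (y, x); transpose to (x, y) per slice
    values = np.stack([p.T for p in planes], axis=2)
    spacing = (col_mm, row_mm, float(dz[0]))
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return VolumetricImage(values, spacing, origin)


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a 3D volume from a NIfTI file or a directory of DICOM slices."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def _affine(image: VolumetricImage) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(image.spacing)
    aff[:3, 3] = image.origin
    return aff


def write_volume(image: VolumetricImage, path: str | Path) -> None:
    """Write a volumetric image as NIfTI with its grid geometry."""
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), _affine(image)), str(path))


def write_mask(mask: BinaryMask, reference: VolumetricImage, path: str | Path) -> None:
    """Write a binary mask as a 0/1 NIfTI on the reference image's grid."""
    if mask.shape != reference.shape:
        raise ValueError("geometry mismatch: mask shape differs from reference image")
    nib.save(
        nib.Nifti1Image(mask.membership.astype(np.uint8), _affine(reference)), str(path)
    )


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI back into a binary mask."""
    img = nib.load(str(path))
    return BinaryMask(np.asanyarray(img.dataobj) > 0)


@dataclass
class RunConfig:
    """Configuration of one segmentation run.

    The seed is given either as voxel indices (``seed_voxel``) or as a
    world-mm point (``seed_world``, mapped to the nearest voxel center,
    ties toward the lower index) — exactly one of the two.  With
    ``seed_mode="hottest"`` the seed is moved to the hottest voxel within
    ``search_radius_mm`` of the given location, a standardized alternative
    to the manual click.
    """

    input_path: str
    method: str  # threshold | kurtosis | entropy | lze
    seed_voxel: tuple[int, int, int] | None = None
    seed_world: tuple[float, float, float] | None = None
    seed_mode: str = "fixed"  # fixed | hottest
    search_radius_mm: float = 15.0
    fraction: float = 0.40
    feature_threshold: float | None = None
    accept_direction: str = "below"
    n_gray_levels: int = 64
    binning: str = "fixed-global"
    margin_mm: float = 30.0
    max_iterations: int = 200
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.method not in ("threshold", *_METHOD_FEATURES):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.seed_voxel is None) == (self.seed_world is None):
            raise ValueError("specify exactly one of seed_voxel / seed_world")
        if self.seed_mode not in ("fixed", "hottest"):
            raise ValueError("seed_mode must be 'fixed' or 'hottest'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("seed_voxel", "seed_world"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def resolved(self) -> dict:
        d = dict(self.__dict__)
        for key in ("seed_voxel", "seed_world"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _resolve_seed(image: VolumetricImage, config: RunConfig) -> SeedPoint:
    if config.seed_voxel is not None:
        i, j, k = (int(v) for v in config.seed_voxel)
    else:
        i, j, k = image.world_to_voxel(tuple(config.seed_world))
    if config.seed_mode == "hottest":
        radii = [
            max(int(np.floor(config.search_radius_mm / s)), 0) for s in image.spacing
        ]
        box = tuple(
            slice(max(c - r, 0), min(c + r + 1, n))
            for c, r, n in zip((i, j, k), radii, image.shape)
        )
        sub = image.values[box]
        local = np.unravel_index(int(np.argmax(sub)), sub.shape)
        i, j, k = (s.start + int(l) for s, l in zip(box, local))
    return SeedPoint(int(i), int(j), int(k))


def run_segment(config: RunConfig) -> dict:
    """Run one segmentation and write mask, trace and JSON report.

    Returns the report dict (also written to ``<output_dir>/report.json``);
    the mask goes to ``mask.nii.gz`` and, for texture methods, the per-step
    trace to ``trace.csv``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    image = read_volume(config.input_path)
    seed = _resolve_seed(image, config)

    report: dict = {
        "config": config.resolved(),
        "seed_voxel": list(seed.as_tuple()),
        "method": config.method,
    }
    if config.method == "threshold":
        mask = threshold_segment(image, seed, config.fraction)
        report["fraction"] = config.fraction
        report["iterations"] = None
        report["terminated_at_start"] = None
    else:
        if config.feature_threshold is None:
            raise ValueError("feature_threshold is required for texture methods")
        spec = FeatureSpec(
            _METHOD_FEATURES[config.method],
            config.feature_threshold,
            config.accept_direction,
            config.n_gray_levels,
            config.binning,
        )
        result = texture_region_grow(
            image, seed, spec, config.max_iterations, config.margin_mm
        )
        mask = result.mask
        report["feature_threshold"] = config.feature_threshold
        report["accept_direction"] = config.accept_direction
        report["iterations"] = result.iterations
        report["terminated_at_start"] = result.terminated_at_start
        report["converged"] = result.converged
        trace_path = out / "trace.csv"
        with open(trace_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "direction", "feature_value", "accepted"])
            writer.writerows(result.trace)
        report["trace_path"] = trace_path.name

    report["volume_ccm"] = mask_volume_ccm(mask, image.spacing)
    report["max_diameter_mm"] = max_diameter_mm(mask, image.spacing)
    mask_path = out / "mask.nii.gz"
    write_mask(mask, image, mask_path)
    report["mask_path"] = mask_path.name
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
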