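"""Lesion segmentation: 40%-of-maximum threshold reference and texture region growing.

Two delineation algorithms share the same inputs (a volumetric PET image
and a seed voxel clicked at the lesion center):

* :func:`threshold_segment` — the widely used variable-threshold reference,
  keeping the seed's connected component of voxels at or above a fraction
  (default 40%) of the lesion maximum uptake.
* :func:`texture_region_grow` — iterative region growing from a 27-voxel
  start cube; in each iteration the region is expanded by one voxel layer
  separately along +x, -x, +y, -y, +z, -z, each directional candidate is
  kept only while a texture feature of the candidate region stays on the
  accepted side of a threshold, and the accepted candidates are unioned.
  Growth stops when no direction is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .features import FeatureSpec, compute_feature, global_bin_edges
from .image_model import (
    BinaryMask,
    SeedPoint,
    VolumetricImage,
    mask_volume_ccm,
    max_diameter_mm,
    start_cube,
)

__all__ = [
    "DIRECTIONS",
    "RegionGrowResult",
    "GrowStep",
    "CalibrationResult",
    "threshold_segment",
    "directional_grow",
    "texture_region_grow",
    "calibrate_threshold",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: the six axis-aligned one-voxel grow directions
DIRECTIONS: dict[str, tuple[int, int, int]] = {
    "+x": (1, 0, 0),
    "-x": (-1, 0, 0),
    "+y": (0, 1, 0),
    "-y": (0, -1, 0),
    "+z": (0, 0, 1),
    "-z": (0, 0, -1),
}


class GrowStep(NamedTuple):
    """One directional grow attempt in the trace."""

    iteration: int
    direction: str
    feature_value: float
    accepted: bool


@dataclass(frozen=True)
class RegionGrowResult:
    """Outcome of a texture region grow run."""

    mask: BinaryMask
    volume_ccm: float
    max_diameter_mm: float
    iterations: int
    trace: tuple[GrowStep, ...]
    terminated_at_start: bool
    converged: bool


class CalibrationResult(NamedTuple):
    """Threshold midway between the feature values of two reference tissues."""

    threshold: float
    accept_direction: str
    tumor_value: float
    background_value: float


def _component_of(mask: np.ndarray, anchor: tuple[int, int, int]) -> np.ndarray:
    labeled, _ = ndimage.label(mask, structure=_STRUCT_26)
    return labeled == labeled[anchor]


def threshold_segment(
    image: VolumetricImage,
    seed: SeedPoint,
    fraction: float = 0.40,
    max_rounds: int = 10,
) -> BinaryMask:
    """Variable-threshold segmentation at a fraction of the lesion maximum.

    The lesion maximum is found by fixed-point iteration: starting from the
    hottest voxel in the 3x3x3 cube around the seed, threshold the image at
    ``fraction * max``, keep the 26-connected supra-threshold component
    containing that voxel, and recompute the maximum inside the component
    until it stabilizes.  The component's maximum is non-decreasing and
    bounded, so the iteration converges.  Membership is inclusive
    (``>= fraction * max``).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vals = image.values
    i, j, k = seed.as_tuple()
    if not all(0 <= c < n for c, n in zip((i, j, k), vals.shape)):
        raise ValueError("seed outside the image grid")
    if vals[i, j, k] <= 0:
        raise ValueError("seed outside uptake")
    cube = tuple(
        slice(max(c - 1, 0), min(c + 2, n)) for c, n in zip((i, j, k), vals.shape)
    )
    sub = vals[cube]
    local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    anchor = tuple(s.start + l for s, l in zip(cube, local))
    cur_max = float(vals[anchor])
    comp = None
    for _ in range(max_rounds):
        supra = vals >= fraction * cur_max
        comp = _component_of(supra, anchor)
        new_max = float(vals[comp].max())
        flat = int(np.argmax(np.where(comp, vals, -np.inf)))
        anchor = np.unravel_index(flat, vals.shape)
        if new_max == cur_max:
            break
        cur_max = new_max
    return BinaryMask(comp)


def directional_grow(mask: BinaryMask, direction) -> BinaryMask:
    """Candidate mask grown by one voxel along a single axis direction.

    Every member voxel contributes its neighbor one step along
    ``direction`` (a name like ``"+x"`` or an axis-aligned unit triple);
    growth past the image face is silently clipped, and no voxel is ever
    removed.
    """
    if isinstance(direction, str):
        try:
            off = DIRECTIONS[direction]
        except KeyError:
            raise ValueError(f"unknown direction {direction!r}") from None
    else:
        off = tuple(int(d) for d in direction)
        if off not in DIRECTIONS.values():
            raise ValueError(f"direction must be an axis unit vector, got {off}")
    m = mask.membership
    if not m.any():
        raise ValueError("empty mask")
    out = m.copy()
    shape = m.shape
    src = tuple(slice(max(-o, 0), min(n - o, n)) for o, n in zip(off, shape))
    dst = tuple(slice(max(o, 0), min(n + o, n)) for o, n in zip(off, shape))
    out[dst] |= m[src]
    return BinaryMask(out)


def _accepts(value: float, spec: FeatureSpec) -> bool:
    # strict comparison: a candidate exactly at the threshold is rejected
    if spec.accept_direction == "below":
        return value < spec.threshold
    return value > spec.threshold


def texture_region_grow(
    image: VolumetricImage,
    seed: SeedPoint,
    spec: FeatureSpec,
    max_iterations: int = 200,
    margin_mm: float = 30.0,
    sequential: bool = False,
) -> RegionGrowResult:
    """Region growing from a 27-voxel start cube with a texture stop criterion.

    Each iteration forms six directional candidates by growing the current
    volume one voxel along each axis direction; a candidate is accepted iff
    the feature of the whole candidate region is strictly on the accepted
    side of the threshold, and the iteration's result is the union of the
    accepted candidates (by default each candidate is grown from the same
    parent volume; ``sequential=True`` instead feeds each accepted
    candidate into the next direction, for sensitivity analysis).  If the
    start cube itself violates the criterion the cube is returned
    unchanged with ``terminated_at_start`` set.  Growth stops when an
    iteration changes nothing, or (flagged) at ``max_iterations``.
    """
    if spec.threshold is None:
        raise ValueError("FeatureSpec.threshold must be set for region growing")
    volume = start_cube(seed, image)
    if spec.name == "kurtosis" or spec.binning != "fixed-global":
        edges = None
    elif spec.bin_edges is not None:
        edges = np.asarray(spec.bin_edges)
    else:
        edges = global_bin_edges(image, volume, spec.n_gray_levels, margin_mm)

    trace: list[GrowStep] = []
    f0 = compute_feature(image, volume, spec, edges)
    if not _accepts(f0, spec):
        trace.append(GrowStep(0, "start", f0, False))
        return _result(volume, image, 0, trace, terminated_at_start=True, converged=True)
    trace.append(GrowStep(0, "start", f0, True))

    iterations = 0
    converged = False
    while iterations < max_iterations:
        iterations += 1
        parent = volume
        merged = volume.membership.copy()
        for name in DIRECTIONS:
            base = BinaryMask(merged) if sequential else parent
            candidate = directional_grow(base, name)
            f = compute_feature(image, candidate, spec, edges)
            accepted = _accepts(f, spec)
            trace.append(GrowStep(iterations, name, f, accepted))
            if accepted:
                merged |= candidate.membership
        if np.array_equal(merged, volume.membership):
            converged = True
            break
        volume = BinaryMask(merged)
    return _result(volume, image, iterations, trace, False, converged)


def _result(
    mask: BinaryMask,
    image: VolumetricImage,
    iterations: int,
    trace: list[GrowStep],
    terminated_at_start: bool,
    converged: bool,
) -> RegionGrowResult:
    return RegionGrowResult(
        mask=mask,
        volume_ccm=mask_volume_ccm(mask, image.spacing),
        max_diameter_mm=max_diameter_mm(mask, image.spacing),
        iterations=iterations,
        trace=tuple(trace),
        terminated_at_start=terminated_at_start,
        converged=converged,
    )


def calibrate_threshold(
    image: VolumetricImage,
    tumor_mask: BinaryMask,
    background_mask: BinaryMask,
    spec: FeatureSpec,
    edges: np.ndarray | None = None,
) -> CalibrationResult:
    """Derive a stop threshold from reference tumor and background regions.

    Computes the feature in both masks (matrix features share fixed-global
    bin edges spanning both regions, so the two values are on one gray-level
    scale), places the threshold at the midpoint, and accepts the side of
    the midpoint on which the tumor value lies.
    """
    if tumor_mask.count < 27 or background_mask.count < 27:
        raise ValueError("calibration masks must each contain at least 27 voxels")
    if (tumor_mask.membership & background_mask.membership).any():
        raise ValueError("tumor and background masks must be disjoint")
    if edges is None and spec.name != "kurtosis" and spec.binning == "fixed-global":
        if spec.bin_edges is not None:
            edges = np.asarray(spec.bin_edges)
        else:
            both = tumor_mask.union(background_mask)
            edges = global_bin_edges(image, both, spec.n_gray_levels, margin_mm=0.0)
    f_tumor = compute_feature(image, tumor_mask, spec, edges)
    f_bg = compute_feature(image, background_mask, spec, edges)
    if f_tumor == f_bg:
        raise ValueError("feature not discriminative")
    theta = 0.5 * (f_tumor + f_bg)
    direction = "below" if f_tumor < theta else "above"
    return CalibrationResult(theta, direction, f_tumor, f_bg)
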