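"""Repeated-measurement statistics and difference metrics over segmentations.

The stability of each segmentation method is characterized by repeating the
measurement (fresh noise realization, jittered seed click) and reporting
mean, range, absolute and relative standard deviation of the segmented
volumes, together with the relative difference of the mean to the known
truth and the signed relative change between uncorrected (motion-blurred)
and motion-corrected volumes.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureSpec
from .image_model import BinaryMask, SeedPoint, VolumetricImage, mask_volume_ccm
from .phantom import (
    PhantomSpec,
    add_acquisition_noise,
    noiseless_motion_blurred,
    noiseless_static,
    truth_mask,
)
from .segmentation import calibrate_threshold, texture_region_grow, threshold_segment

__all__ = [
    "RepeatStats",
    "StabilityResult",
    "METHODS",
    "repeat_stats",
    "relative_difference_to_truth",
    "motion_difference",
    "round_reported_percent",
    "stability_experiment",
]

#: method name -> texture feature name ("threshold" is the 40%-of-max reference)
METHODS: dict[str, str | None] = {
    "threshold": None,
    "kurtosis": "kurtosis",
    "entropy": "local_entropy",
    "lze": "long_zone_emphasis",
}


@dataclass(frozen=True)
class RepeatStats:
    """Mean, range, absolute and relative SD of repeated volume measurements."""

    mean_ccm: float
    min_ccm: float
    max_ccm: float
    sd_ccm: float
    relative_sd_percent: float


def repeat_stats(volumes: Sequence[float]) -> RepeatStats:
    """Summary statistics of repeated segmentation volumes.

    Uses the sample (N-1) standard deviation; relative SD is
    ``100 * SD / mean`` in percent.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volumes")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return RepeatStats(
        mean_ccm=mean,
        min_ccm=float(v.min()),
        max_ccm=float(v.max()),
        sd_ccm=sd,
        relative_sd_percent=100.0 * sd / mean,
    )


def round_reported_percent(value: float) -> float:
    """Round a percentage for reporting, to one decimal.

    Matches the tables' convention: half-away-from-zero, applied in two
    stages (two decimals, then one) because the upstream values are carried
    at limited precision (e.g. 3.846 -> 3.85 -> 3.9).
    """
    d = decimal.Decimal(repr(float(value)))
    d = d.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    d = d.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    return float(d)


def relative_difference_to_truth(mean_volume_ccm: float, true_volume_ccm: float) -> float:
    """Unsigned relative difference of a mean volume to the true volume (%)."""
    if true_volume_ccm <= 0:
        raise ValueError("true volume must be positive")
    return round_reported_percent(
        100.0 * abs(mean_volume_ccm - true_volume_ccm) / true_volume_ccm
    )


def motion_difference(v_uncorrected_ccm: float, v_corrected_ccm: float) -> float:
    """Signed relative difference of an uncorrected volume to the corrected one (%).

    Positive when motion blur enlarges the segmented volume.
    """
    if v_uncorrected_ccm <= 0:
        raise ValueError("uncorrected volume must be positive")
    return round_reported_percent(
        100.0 * (v_uncorrected_ccm - v_corrected_ccm) / v_uncorrected_ccm
    )


@dataclass(frozen=True)
class StabilityResult:
    """Output of :func:`stability_experiment`.

    ``table`` has one row per (method, sphere) with the repeated-measurement
    summary; ``volumes`` holds the raw per-repeat volumes (for box-and-whisker
    export); ``failures`` counts excluded repeats per row.
    """

    table: pd.DataFrame
    volumes: dict[tuple[str, str], list[float]]
    failures: dict[tuple[str, str], int]

    def quartile_table(self) -> pd.DataFrame:
        """Five-number summaries of the raw volumes (box-and-whisker export)."""
        rows = []
        for (method, sphere), vols in self.volumes.items():
            q = np.percentile(vols, [0, 25, 50, 75, 100])
            rows.append(
                dict(
                    method=method,
                    sphere=sphere,
                    minimum=q[0],
                    q1=q[1],
                    median=q[2],
                    q3=q[3],
                    maximum=q[4],
                )
            )
        return pd.DataFrame(rows)


def calibration_masks(
    spec: PhantomSpec, sphere_index: int, overreach_vox: int = 1
) -> tuple[BinaryMask, BinaryMask]:
    """Reference regions for threshold calibration on a phantom sphere.

    The tumor reference is the lesion region eroded by one voxel layer —
    the last region state a growing segmentation should fully accept; the
    counter-reference is the lesion dilated by ``overreach_vox`` layers
    (eroded interior carved out to keep the masks disjoint) — an
    overreached state it should refuse.  The midpoint threshold therefore
    sits at the feature's transition across the lesion boundary, computed
    from two region-sized samples rather than small patches.  For spheres
    too small to erode (fewer than 27 interior voxels) the 27-voxel
    central cube is used as the tumor reference.
    """
    from scipy import ndimage

    truth = truth_mask(spec, sphere_index).membership
    struct = ndimage.generate_binary_structure(3, 3)
    eroded = ndimage.binary_erosion(truth, struct, iterations=1)
    if eroded.sum() < 27:
        i, j, k = spec.sphere_center_voxel(sphere_index)
        eroded = np.zeros_like(truth)
        eroded[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2] = True
    dilated = ndimage.binary_dilation(truth, struct, iterations=overreach_vox)
    return BinaryMask(eroded), BinaryMask(dilated & ~eroded)


def _sphere_label(volume_ccm: float, volumes: Sequence[float]) -> str:
    order = sorted(volumes)
    names = {0: "small", len(order) - 1: "large"}
    idx = order.index(volume_ccm)
    return names.get(idx, "medium")


def _jittered_seed(
    spec: PhantomSpec, sphere_index: int, rng: np.random.Generator, jitter: int
) -> SeedPoint:
    i, j, k = spec.sphere_center_voxel(sphere_index)
    if jitter > 0:
        di, dj, dk = rng.integers(-jitter, jitter + 1, size=3)
        i, j, k = i + int(di), j + int(dj), k + int(dk)
    return SeedPoint(i, j, k)


def default_feature_spec(method: str) -> FeatureSpec:
    """Uncalibrated feature configuration for a texture method name.

    Long-zone emphasis uses per-region binning: its zone structure must
    reflect in-region texture at every region size, and the intensity-range
    expansion on crossing the lesion edge is itself part of the stop
    contrast.  Local entropy uses a coarse 8-level scale: a 27-voxel start
    region provides only a few hundred voxel pairs, and entropy estimated
    over many more matrix cells than pairs is dominated by small-sample
    bias.  Kurtosis acts on raw intensities.
    """
    feat = METHODS[method]
    if feat is None:
        raise ValueError("the threshold method has no texture feature")
    if feat == "long_zone_emphasis":
        return FeatureSpec(feat, binning="per-region")
    if feat == "local_entropy":
        return FeatureSpec(feat, binning="fixed-global", n_gray_levels=8)
    return FeatureSpec(feat)


def calibrate_method_specs(
    spec: PhantomSpec,
    calib_image: VolumetricImage,
    methods: Sequence[str] = ("kurtosis", "entropy", "lze"),
    feature_specs: dict[str, FeatureSpec] | None = None,
) -> dict[str, FeatureSpec]:
    """Calibrated stop thresholds per texture method on a phantom.

    Each method's threshold is derived once, on the largest sphere (the
    best boundary statistics), from the inside-state / overreach-state
    reference regions of :func:`calibration_masks`, and then used
    unchanged for every sphere — standing in for the protocol thresholds a
    clinical deployment would take from prior reference data.
    """
    largest = int(np.argmax(spec.sphere_volumes_ccm))
    specs: dict[str, FeatureSpec] = {}
    for m in methods:
        if METHODS.get(m) is None:
            continue
        if feature_specs is not None and m in feature_specs:
            base = feature_specs[m]
        else:
            base = default_feature_spec(m)
        if base.binning == "fixed-global" and base.bin_edges is None:
            # protocol-constant bin edges over the calibration acquisition's
            # intensity range, so feature values are comparable across
            # spheres, repeats and motion states (fixed-bin radiomics style)
            lo = float(calib_image.values.min())
            hi = float(calib_image.values.max())
            base = base.with_bin_edges(np.linspace(lo, hi, base.n_gray_levels + 1))
        if base.threshold is not None:
            specs[m] = base
            continue
        # kurtosis detects the bimodality of a fully overreached region
        # (lesion plus background), so its counter-reference overreaches by
        # several layers; the matrix features detect first boundary contact
        overreach = 3 if base.name == "kurtosis" else 1
        tumor_ref, background_ref = calibration_masks(spec, largest, overreach)
        cal = calibrate_threshold(calib_image, tumor_ref, background_ref, base)
        specs[m] = base.with_threshold(cal.threshold, cal.accept_direction)
    return specs


def stability_experiment(
    spec: PhantomSpec,
    methods: Sequence[str] = ("threshold", "kurtosis", "entropy", "lze"),
    repeats: int = 20,
    seed_jitter_voxels: int = 1,
    motion_blurred: bool = False,
    fraction: float = 0.40,
    feature_specs: dict[str, FeatureSpec] | None = None,
    master_seed: int | None = None,
) -> StabilityResult:
    """Repeated consecutive segmentations of every sphere with every method.

    For each repeat a fresh noise realization of the (static or
    motion-blurred) phantom is drawn and the seed click is jittered
    uniformly within ``seed_jitter_voxels`` (Chebyshev radius) of the
    sphere center; each method then segments each sphere and the volumes
    are summarized with :func:`repeat_stats`.

    Texture thresholds are calibrated per (method, sphere) on a dedicated
    noisy calibration realization of the same acquisition mode (its own
    RNG stream) via :func:`calibrate_method_specs`, unless explicit
    ``feature_specs`` with thresholds are supplied.
    Failed repeats (degenerate regions, non-discriminative calibration)
    are warned about, counted and excluded.
    """
    if repeats < 2:
        raise ValueError("need at least 2 repeats")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected one of {tuple(METHODS)}")
    if master_seed is None:
        master_seed = spec.rng_seed
    ss = np.random.SeedSequence(master_seed)
    calib_ss, jitter_ss, *noise_ss = ss.spawn(repeats + 2)

    clean = noiseless_motion_blurred(spec) if motion_blurred else noiseless_static(spec)
    jitter_rng = np.random.default_rng(jitter_ss)

    n_spheres = len(spec.sphere_volumes_ccm)
    labels = [
        _sphere_label(v, spec.sphere_volumes_ccm) for v in spec.sphere_volumes_ccm
    ]

    # thresholds are protocol constants: always calibrated on the static
    # acquisition and reused unchanged for motion-blurred data
    calib_image = add_acquisition_noise(
        noiseless_static(spec), spec, np.random.default_rng(calib_ss)
    )
    specs = calibrate_method_specs(spec, calib_image, methods, feature_specs)

    volumes: dict[tuple[str, str], list[float]] = {
        (m, labels[s]): [] for m in methods for s in range(n_spheres)
    }
    failures: dict[tuple[str, str], int] = {k: 0 for k in volumes}

    for r in range(repeats):
        image = add_acquisition_noise(clean, spec, np.random.default_rng(noise_ss[r]))
        for s in range(n_spheres):
            seed = _jittered_seed(spec, s, jitter_rng, seed_jitter_voxels)
            for m in methods:
                key = (m, labels[s])
                try:
                    if METHODS[m] is None:
                        mask = threshold_segment(image, seed, fraction)
                        vol = mask_volume_ccm(mask, image.spacing)
                    else:
                        vol = texture_region_grow(image, seed, specs[m]).volume_ccm
                    volumes[key].append(vol)
                except ValueError as exc:
                    warnings.warn(
                        f"repeat {r}: {m}/{key[1]} segmentation failed: {exc}",
                        stacklevel=2,
                    )
                    failures[key] += 1

    rows = []
    for s in range(n_spheres):
        nominal = spec.sphere_volumes_ccm[s]
        for m in methods:
            key = (m, labels[s])
            vols = volumes[key]
            st = repeat_stats(vols)
            rows.append(
                dict(
                    method=m,
                    sphere=labels[s],
                    nominal_ccm=nominal,
                    n=len(vols),
                    mean_ccm=st.mean_ccm,
                    difference_percent=relative_difference_to_truth(st.mean_ccm, nominal),
                    min_ccm=st.min_ccm,
                    max_ccm=st.max_ccm,
                    sd_ccm=st.sd_ccm,
                    relative_sd_percent=st.relative_sd_percent,
                    failures=failures[key],
                )
            )
    return StabilityResult(pd.DataFrame(rows), volumes, failures)
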