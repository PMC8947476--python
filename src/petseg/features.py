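"""Intensity discretization, texture matrices and the three stop-criterion features.

The region-growing stop criterion is a threshold on one of three texture
descriptors computed inside the candidate region:

* **Kurtosis (KU)** — the non-excess fourth standardized moment of the raw
  voxel intensities (a first-order histogram feature; 3 for a Gaussian).
* **Local Entropy (LE)** — Shannon entropy ``-sum p log2 p`` of the 3D
  gray-level co-occurrence matrix (GLCM) of the discretized region.
* **Long-Zone Emphasis (LZE)** — the squared-size-weighted mean zone size of
  the gray-level size-zone matrix (GLSZM); large for regions dominated by
  big homogeneous zones.

Matrix conventions: the GLCM aggregates the 13 unique 3D offsets at
Chebyshev distance 1, symmetrized (each pair counted in both orders) and
normalized to sum 1; the GLSZM uses 26-connected zones of equal gray level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, VolumetricImage

__all__ = [
    "FeatureSpec",
    "DiscretizedRegion",
    "CooccurrenceMatrix",
    "SizeZoneMatrix",
    "FEATURE_NAMES",
    "discretize",
    "cooccurrence",
    "size_zone",
    "kurtosis",
    "local_entropy",
    "long_zone_emphasis",
    "compute_feature",
    "global_bin_edges",
]

FEATURE_NAMES = ("kurtosis", "local_entropy", "long_zone_emphasis")

#: the 13 unique 3D direction vectors at Chebyshev distance 1 (one per axis
#: of symmetry); the opposite directions are covered by symmetrized counting.
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FeatureSpec:
    """Which texture feature stops the region growth, and how.

    Parameters
    ----------
    name : {"kurtosis", "local_entropy", "long_zone_emphasis"}
    threshold : float, optional
        Stop threshold θ.  Not built in: thresholds are scanner- and
        protocol-dependent and must be supplied or calibrated
        (:func:`petseg.segmentation.calibrate_threshold`).
    accept_direction : {"below", "above"}
        A candidate region is accepted iff its feature value is strictly
        on this side of θ.
    n_gray_levels : int
        Number of discretization levels G (GLCM/GLSZM features only).
    binning : {"fixed-global", "per-region"}
        ``fixed-global`` computes bin edges once, from the intensity range
        around the seed, so the feature trajectory is comparable across
        grow steps; ``per-region`` re-bins each candidate from its own
        min/max.
    bin_edges : sequence of float, optional
        Explicit protocol-constant bin edges (G+1 ascending values, e.g.
        fixed bins on a calibrated uptake scale).  When set they override
        the seed-derived range, making feature values comparable across
        images acquired under one protocol.
    """

    name: str
    threshold: float | None = None
    accept_direction: str = "below"
    n_gray_levels: int = 64
    binning: str = "fixed-global"
    bin_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}; expected one of {FEATURE_NAMES}")
        if self.accept_direction not in ("below", "above"):
            raise ValueError("accept_direction must be 'below' or 'above'")
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.binning not in ("fixed-global", "per-region"):
            raise ValueError("binning must be 'fixed-global' or 'per-region'")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.bin_edges is not None:
            edges = tuple(float(e) for e in self.bin_edges)
            if len(edges) != self.n_gray_levels + 1 or any(
                b <= a for a, b in zip(edges, edges[1:])
            ):
                raise ValueError("bin_edges must be G+1 strictly ascending values")
            object.__setattr__(self, "bin_edges", edges)

    def with_threshold(self, threshold: float, accept_direction: str) -> "FeatureSpec":
        return FeatureSpec(
            self.name,
            float(threshold),
            accept_direction,
            self.n_gray_levels,
            self.binning,
            self.bin_edges,
        )

    def with_bin_edges(self, edges) -> "FeatureSpec":
        return FeatureSpec(
            self.name,
            self.threshold,
            self.accept_direction,
            self.n_gray_levels,
            self.binning,
            tuple(float(e) for e in edges),
        )


@dataclass(frozen=True)
class DiscretizedRegion:
    """Gray levels 1..G over the member voxels of a mask.

    ``levels`` is a full-grid integer array holding 0 outside the mask and
    the level 1..G inside; ``edges`` are the G+1 ascending bin edges used.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    edges: np.ndarray

    @property
    def member_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized 3D GLCM: ``probabilities[i-1, j-1]`` = P(level pair (i, j))."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence entries must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class SizeZoneMatrix:
    """GLSZM: ``counts[i-1, j-1]`` = number of zones of level i and size j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("size-zone matrix must be 2D with non-negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())

    @property
    def n_voxels(self) -> int:
        sizes = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts * sizes[np.newaxis, :]).sum())


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def discretize(
    image: VolumetricImage,
    mask: BinaryMask,
    n_levels: int,
    edges: np.ndarray | None = None,
) -> DiscretizedRegion:
    """Bin the masked intensities into gray levels 1..G.

    Levels follow ``clamp(floor(G * (x - lo) / (hi - lo)) + 1, 1, G)`` with
    ``[lo, hi]`` taken from ``edges`` (first/last of G+1 ascending values)
    when given, else from the min/max over the mask.  A constant region
    maps every voxel to level 1.
    """
    m = mask.membership
    if not m.any():
        raise ValueError("empty mask")
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size != n_levels + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be G+1 strictly ascending values")
        lo, hi = float(edges[0]), float(edges[-1])
    else:
        vals = image.values[m]
        lo, hi = float(vals.min()), float(vals.max())
        edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi > lo:
        scaled = np.floor(n_levels * (image.values[m] - lo) / (hi - lo)).astype(np.int64) + 1
        levels[m] = np.clip(scaled, 1, n_levels)
    else:
        levels[m] = 1
    return DiscretizedRegion(levels=levels, mask=m, n_levels=n_levels, edges=edges)


def cooccurrence(
    region: DiscretizedRegion, mask: BinaryMask | None = None
) -> CooccurrenceMatrix:
    """Symmetrized 3D gray-level co-occurrence matrix of a discretized region.

    Counts level pairs over all 13 unique distance-1 offsets, each pair in
    both orders, restricted to voxel pairs with both ends inside the mask,
    and normalizes the counts to probabilities.
    """
    m = region.mask if mask is None else mask.membership
    bbox = _bounding_box(m)
    lev = region.levels[bbox]
    msk = m[bbox]
    G = region.n_levels
    counts = np.zeros((G, G), dtype=np.int64)
    shape = lev.shape
    for off in GLCM_OFFSETS:
        src = tuple(
            slice(max(-o, 0), min(n - o, n)) for o, n in zip(off, shape)
        )
        dst = tuple(
            slice(max(o, 0), min(n + o, n)) for o, n in zip(off, shape)
        )
        pair = msk[src] & msk[dst]
        if not pair.any():
            continue
        a = lev[src][pair] - 1
        b = lev[dst][pair] - 1
        flat = np.bincount(a * G + b, minlength=G * G).reshape(G, G)
        counts += flat + flat.T  # symmetrize: count each pair in both orders
    total = counts.sum()
    if total == 0:
        raise ValueError("no voxel pairs")
    return CooccurrenceMatrix(counts / total)


def size_zone(
    region: DiscretizedRegion, mask: BinaryMask | None = None
) -> SizeZoneMatrix:
    """Gray-level size-zone matrix of a discretized region.

    Zones are maximal 26-connected components of equal gray level inside
    the mask; entry (i, j) counts zones of level i and size j voxels.
    """
    m = region.mask if mask is None else mask.membership
    if not m.any():
        raise ValueError("empty mask")
    bbox = _bounding_box(m)
    lev = region.levels[bbox]
    msk = m[bbox]
    G = region.n_levels
    zones: list[tuple[int, int]] = []
    for g in np.unique(lev[msk]):
        labeled, n = ndimage.label((lev == g) & msk, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    jmax = max(s for _, s in zones)
    counts = np.zeros((G, jmax), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return SizeZoneMatrix(counts)


def kurtosis(values: np.ndarray) -> float:
    """Non-excess kurtosis: mean fourth power of the standardized values.

    Uses the population (1/N) standard deviation; a Gaussian sample tends
    to 3, and 1 is the lower (Pearson) bound for any distribution.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("kurtosis needs at least 2 values")
    mu = x.mean()
    sd = x.std()  # population convention, matching the 1/N normalization
    if sd == 0:
        raise ValueError("degenerate region: zero variance")
    return float(np.mean(((x - mu) / sd) ** 4))


def local_entropy(m1: CooccurrenceMatrix) -> float:
    """Shannon entropy (bits) of the co-occurrence probabilities.

    ``-sum p log2 p`` over nonzero entries; bounded by 2*log2(G) for a
    G-level matrix.
    """
    p = m1.probabilities[m1.probabilities > 0]
    return float(-(p * np.log2(p)).sum())


def long_zone_emphasis(m4: SizeZoneMatrix) -> float:
    """Squared-size-weighted mean zone size; >= 1, large for big zones."""
    if m4.n_zones == 0:
        raise ValueError("size-zone matrix has no zones")
    sizes = np.arange(1, m4.counts.shape[1] + 1, dtype=float)
    return float((m4.counts * sizes[np.newaxis, :] ** 2).sum() / m4.n_zones)


def global_bin_edges(
    image: VolumetricImage,
    mask: BinaryMask,
    n_levels: int,
    margin_mm: float = 30.0,
) -> np.ndarray:
    """Fixed-global bin edges from the intensity range around a start region.

    The range is taken inside the bounding box of ``mask`` dilated by
    ``margin_mm`` on every side, so that lesion and surrounding background
    intensities share one comparable gray-level scale across grow steps.
    """
    bbox = _bounding_box(mask.membership)
    pads = [int(np.ceil(margin_mm / s)) for s in image.spacing]
    grown = tuple(
        slice(max(b.start - p, 0), min(b.stop + p, n))
        for b, p, n in zip(bbox, pads, image.shape)
    )
    sub = image.values[grown]
    lo, hi = float(sub.min()), float(sub.max())
    if hi <= lo:
        hi = lo + 1.0  # constant neighborhood: any single-bin scale works
    return np.linspace(lo, hi, n_levels + 1)


def compute_feature(
    image: VolumetricImage,
    mask: BinaryMask,
    spec: FeatureSpec,
    edges: np.ndarray | None = None,
) -> float:
    """Evaluate the spec's feature on the masked region of the image.

    Kurtosis acts on raw intensities; the matrix features discretize the
    region first (with ``edges`` when given, e.g. the fixed-global edges of
    a region-grow run, else per-region min/max binning).
    """
    m = mask.membership
    if not m.any():
        raise ValueError("empty mask")
    if spec.name == "kurtosis":
        return kurtosis(image.values[m])
    if edges is None and spec.bin_edges is not None:
        edges = np.asarray(spec.bin_edges)
    # crop to the mask bounding box: matrix features only see masked voxels
    bbox = _bounding_box(m)
    sub_img = VolumetricImage(image.values[bbox], image.spacing)
    sub_mask = BinaryMask(m[bbox])
    region = discretize(sub_img, sub_mask, spec.n_gray_levels, edges=edges)
    if spec.name == "local_entropy":
        return local_entropy(cooccurrence(region))
    return long_zone_emphasis(size_zone(region))
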