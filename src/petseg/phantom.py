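"""Synthetic moving-sphere PET phantom.

Emulates a fillable-sphere motion phantom imaged on a clinical PET scanner:
three spheres of 3, 12 and 26 ccm filled with FDG solution at 1.2 MBq/ccm,
reconstructed on a 128 x 128 matrix with 5 mm slices and smoothed with a
5 mm Gaussian post-filter, optionally driven sinusoidally in the
cranio-caudal (z) direction with 15 mm peak-to-peak excursion at 12 cycles
per minute.

The imaging chain is a forward surrogate, not a scanner model: the analytic
activity map is rasterized with supersampled partial-volume fractions,
convolved with a Gaussian point-spread function of the stated FWHM, and
degraded with additive signal-dependent Gaussian noise.  Respiratory motion
is emulated by time-averaging phase-shifted rasterizations over one breathing
cycle before blurring, i.e. an uncorrected (motion-blurred) acquisition;
comparing static and motion-blurred images of the same phantom stands in
for the motion-corrected vs uncorrected comparison.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, VolumetricImage

__all__ = [
    "PhantomSpec",
    "sphere_radius_mm",
    "truth_mask",
    "noiseless_static",
    "noiseless_motion_blurred",
    "add_acquisition_noise",
    "simulate_static",
    "simulate_motion_blurred",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sphere_radius_mm(volume_ccm: float) -> float:
    """Radius in mm of a sphere of the given volume in ccm."""
    return float((3.0 * volume_ccm * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and acquisition parameters of the synthetic phantom.

    Defaults reproduce the physical phantom and protocol this simulator
    emulates; the in-plane pixel size (4 mm, a 128 matrix over a typical
    ~51 cm field of view) and the noise level are free parameters of the
    surrogate.  ``noise_coefficient`` scales the local-intensity-proportional
    noise component; ``noise_floor`` (image units) is the noise SD in cold
    regions.
    """

    sphere_volumes_ccm: tuple[float, ...] = (3.0, 12.0, 26.0)
    sphere_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    activity_mbq_per_ccm: float = 1.2
    background_mbq_per_ccm: float = 0.0
    matrix_size: int = 128
    n_slices: int = 40
    pixel_size_mm: float = 4.0
    slice_thickness_mm: float = 5.0
    psf_fwhm_mm: float = 5.0
    motion_amplitude_mm: float = 15.0
    motion_freq_per_min: float = 12.0
    n_motion_phases: int = 32
    noise_coefficient: float = 0.05
    noise_floor: float = 0.005
    noise_correlation_fwhm_mm: float | None = None
    background_texture_sigma: float = 0.0
    background_texture_fwhm_mm: float = 12.0
    supersample: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sphere_volumes_ccm):
            raise ValueError("sphere volumes must be positive")
        if self.psf_fwhm_mm < 0 or self.motion_amplitude_mm < 0:
            raise ValueError("PSF FWHM and motion amplitude must be >= 0")
        if self.sphere_centers_mm is None:
            object.__setattr__(self, "sphere_centers_mm", self._default_centers())
        if len(self.sphere_centers_mm) != len(self.sphere_volumes_ccm):
            raise ValueError("one center per sphere required")
        radii = [sphere_radius_mm(v) for v in self.sphere_volumes_ccm]
        centers = np.asarray(self.sphere_centers_mm, dtype=float)
        for a in range(len(radii)):
            for b in range(a + 1, len(radii)):
                # phantom moves as a whole, so relative distances are motion-invariant
                if np.linalg.norm(centers[a] - centers[b]) < radii[a] + radii[b]:
                    raise ValueError("spheres overlap")

    def _default_centers(self) -> tuple[tuple[float, float, float], ...]:
        n = len(self.sphere_volumes_ccm)
        span = 80.0
        xs = [span * (i - (n - 1) / 2.0) for i in range(n)]
        return tuple((x, 0.0, 0.0) for x in xs)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.pixel_size_mm, self.pixel_size_mm, self.slice_thickness_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix_size, self.matrix_size, self.n_slices)

    @property
    def origin(self) -> tuple[float, float, float]:
        # grid centered on the world origin
        return tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))

    @property
    def motion_period_s(self) -> float:
        return 60.0 / self.motion_freq_per_min

    def sphere_center_voxel(self, index: int) -> tuple[int, int, int]:
        """Voxel index nearest the center of a sphere (the nominal seed)."""
        c = self.sphere_centers_mm[index]
        return tuple(
            int(np.ceil((w - o) / s - 0.5))
            for w, o, s in zip(c, self.origin, self.spacing)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("sphere_centers_mm") is not None:
            d["sphere_centers_mm"] = tuple(tuple(c) for c in d["sphere_centers_mm"])
        d["sphere_volumes_ccm"] = tuple(d["sphere_volumes_ccm"])
        return cls(**d)


def _axis_coords(spec: PhantomSpec) -> list[np.ndarray]:
    return [
        o + s * np.arange(n)
        for o, s, n in zip(spec.origin, spec.spacing, spec.shape)
    ]


def truth_mask(spec: PhantomSpec, sphere_index: int) -> BinaryMask:
    """Ground-truth mask: voxels whose centers lie inside the analytic sphere."""
    r = sphere_radius_mm(spec.sphere_volumes_ccm[sphere_index])
    cx, cy, cz = spec.sphere_centers_mm[sphere_index]
    x, y, z = _axis_coords(spec)
    d2 = (
        (x - cx)[:, None, None] ** 2
        + (y - cy)[None, :, None] ** 2
        + (z - cz)[None, None, :] ** 2
    )
    return BinaryMask(d2 <= r * r)


def _occupancy(spec: PhantomSpec, center: tuple[float, float, float], r: float) -> tuple[
    tuple[slice, slice, slice], np.ndarray
]:
    """Fractional sphere occupancy per voxel, on the sphere's bounding subgrid."""
    s = spec.supersample
    bbox = []
    for c, o, d, n in zip(center, spec.origin, spec.spacing, spec.shape):
        lo = max(int(np.floor((c - r - o) / d - 0.5)), 0)
        hi = min(int(np.ceil((c + r - o) / d + 0.5)) + 1, n)
        bbox.append(slice(lo, hi))
    frac_axes = []
    for ax, (c, o, d, sl) in enumerate(zip(center, spec.origin, spec.spacing, bbox)):
        n_sub = (sl.stop - sl.start) * s
        # supersample positions: s equally spaced points per voxel
        offs = (np.arange(s) + 0.5) / s - 0.5
        base = o + d * np.arange(sl.start, sl.stop)
        frac_axes.append((base[:, None] + d * offs[None, :]).ravel() - c)
    X, Y, Z = frac_axes
    inside = (
        X[:, None, None] ** 2 + Y[None, :, None] ** 2 + Z[None, None, :] ** 2
        <= r * r
    )
    nx, ny, nz = (sl.stop - sl.start for sl in bbox)
    frac = inside.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))
    return tuple(bbox), frac


def _background_field(spec: PhantomSpec) -> np.ndarray | float:
    """Background concentration, optionally with lumpy (lognormal) texture.

    With ``background_texture_sigma > 0`` the uniform background is
    modulated by a mean-preserving lognormal random field correlated over
    ``background_texture_fwhm_mm`` — a surrogate for the heterogeneous
    uptake of healthy lung tissue (vasculature, parenchymal density) in
    lesion-in-lung scenarios.  The field is anatomy, not noise: it is a
    fixed pattern derived from the spec's RNG seed, identical across
    repeated acquisitions.
    """
    bg = spec.background_mbq_per_ccm
    s = spec.background_texture_sigma
    if bg <= 0 or s <= 0:
        return bg
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0x7E47]))
    field = rng.standard_normal(spec.shape)
    sigma_vox = [
        spec.background_texture_fwhm_mm * _FWHM_TO_SIGMA / d for d in spec.spacing
    ]
    field = ndimage.gaussian_filter(field, sigma_vox, mode="constant")
    field /= field.std()
    return bg * np.exp(s * field - 0.5 * s * s)


def _activity_map(spec: PhantomSpec, z_shift_mm: float = 0.0) -> np.ndarray:
    img = np.zeros(spec.shape, dtype=float)
    occupancy = np.zeros(spec.shape, dtype=float)
    for vol, center in zip(spec.sphere_volumes_ccm, spec.sphere_centers_mm):
        r = sphere_radius_mm(vol)
        c = (center[0], center[1], center[2] + z_shift_mm)
        bbox, frac = _occupancy(spec, c, r)
        img[bbox] += spec.activity_mbq_per_ccm * frac
        occupancy[bbox] += frac
    img += _background_field(spec) * (1.0 - np.clip(occupancy, 0.0, 1.0))
    return img


def _blur(spec: PhantomSpec, img: np.ndarray) -> np.ndarray:
    if spec.psf_fwhm_mm == 0:
        return img
    sigma_vox = [
        spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.spacing
    ]
    return ndimage.gaussian_filter(img, sigma_vox, mode="constant")


def noiseless_static(spec: PhantomSpec) -> VolumetricImage:
    """Blurred static phantom without noise (the clean acquisition surrogate)."""
    return VolumetricImage(_blur(spec, _activity_map(spec)), spec.spacing, spec.origin)


def noiseless_motion_blurred(spec: PhantomSpec) -> VolumetricImage:
    """Blurred time-averaged phantom over one sinusoidal breathing cycle.

    The displacement is ``z(t) = (A/2) * sin(2 pi f t)`` (peak-to-peak
    excursion equal to the stated maximal amplitude A), sampled at
    ``n_motion_phases`` uniform phases of the breathing period.
    """
    if spec.motion_amplitude_mm == 0:
        return noiseless_static(spec)
    phases = np.arange(spec.n_motion_phases) / spec.n_motion_phases
    acc = np.zeros(spec.shape, dtype=float)
    for ph in phases:
        z = 0.5 * spec.motion_amplitude_mm * np.sin(2.0 * np.pi * ph)
        acc += _activity_map(spec, z_shift_mm=z)
    acc /= spec.n_motion_phases
    return VolumetricImage(_blur(spec, acc), spec.spacing, spec.origin)


def add_acquisition_noise(
    image: VolumetricImage, spec: PhantomSpec, rng: np.random.Generator | int | None = None
) -> VolumetricImage:
    """Additive Gaussian noise with SD = coefficient x local intensity + floor.

    The noise field is spatially correlated at the post-filter scale
    (``noise_correlation_fwhm_mm``, defaulting to the PSF FWHM): white
    Gaussian noise is smoothed with that kernel and renormalized to unit
    marginal variance before scaling by the local SD.  Reconstructed and
    post-filtered PET noise is correlated over roughly the resolution
    kernel, and the texture features respond to that correlation, not just
    to the marginal noise amplitude.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    field = rng.standard_normal(image.values.shape)
    corr_fwhm = (
        spec.psf_fwhm_mm
        if spec.noise_correlation_fwhm_mm is None
        else spec.noise_correlation_fwhm_mm
    )
    if corr_fwhm > 0:
        sigma_vox = [corr_fwhm * _FWHM_TO_SIGMA / s for s in image.spacing]
        field = ndimage.gaussian_filter(field, sigma_vox, mode="constant")
        field /= field.std()  # renormalize so the stated per-voxel SD is exact
    sd = spec.noise_coefficient * image.values + spec.noise_floor
    noisy = image.values + field * sd
    return VolumetricImage(noisy, image.spacing, image.origin)


def simulate_static(spec: PhantomSpec) -> VolumetricImage:
    """Static acquisition surrogate: rasterize, blur, add seeded noise."""
    clean = noiseless_static(spec)
    if spec.noise_coefficient == 0 and spec.noise_floor == 0:
        return clean
    return add_acquisition_noise(clean, spec)


def simulate_motion_blurred(spec: PhantomSpec) -> VolumetricImage:
    """Uncorrected (motion-blurred) acquisition surrogate with seeded noise."""
    clean = noiseless_motion_blurred(spec)
    if spec.noise_coefficient == 0 and spec.noise_floor == 0:
        return clean
    return add_acquisition_noise(clean, spec)
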