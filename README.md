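# petseg

Semi-automatic delineation of hypermetabolic lesions in 3D FDG-PET volumes,
built for radiation-therapy target-volume studies.  The package implements
two segmentation algorithms around a user-supplied seed click:

* **Variable-threshold reference** — the widely used rule keeping the seed's
  26-connected component of voxels with intensity ≥ 40% of the lesion
  maximum uptake (the lesion maximum is found by fixed-point iteration from
  the seed neighborhood).
* **Texture-feature region growing** — starting from a 27-voxel (3×3×3)
  cube around the seed, the region is expanded one voxel layer at a time
  separately along ±x, ±y, ±z; a directional candidate is kept only while a
  texture feature of the whole candidate region stays strictly on the
  accepted side of a stop threshold θ, the accepted candidates are unioned,
  and growth stops when no direction is accepted.

The stop criterion is one of three radiomics descriptors of the growing
region:

* **Kurtosis** `KU = (1/N) Σ ((x_i − x̄)/σ)⁴` — fourth standardized moment
  of the raw intensities (population σ; Gaussian → 3),
* **Local Entropy** `LE = −Σ_ij M1_ij log₂ M1_ij` of the 3D gray-level
  co-occurrence matrix `M1` (13 unique distance-1 offsets, symmetrized),
* **Long-Zone Emphasis** `LZE = Σ_ij M4_ij j² / Σ_ij M4_ij` of the
  gray-level size-zone matrix `M4` (26-connected equal-level zones).

Because stop thresholds are scanner- and protocol-dependent, none are built
in: `calibrate_threshold` derives θ and its accept direction as the midpoint
between the feature values of a tumor and a background reference region.

Since clinical PET data cannot ship with the package, a synthetic
**moving-sphere phantom** generator is included: fillable spheres of 3, 12
and 26 ccm at 1.2 MBq/ccm on a 128×128 matrix with 5 mm slices, Gaussian
5 mm post-filter, signal-dependent correlated noise, and optional sinusoidal
cranio-caudal motion (15 mm peak-to-peak, 12 cycles/min) emulated by
time-averaging — the uncorrected counterpart of a motion-corrected
acquisition.  `stability_experiment` repeats the whole measurement (fresh
noise, jittered click) and reports mean, range, absolute and relative
standard deviation per method and sphere.

## Worked example

```bash
python examples/phantom_segmentation.py
```

```
true sphere volume (voxelized): 24.96 ccm
40%-of-max threshold:  volume  24.72 ccm, max diameter  36.6 mm
entropy region grow:   volume  20.72 ccm, max diameter  37.9 mm, 4 iterations
```

The 26 ccm sphere rasterizes to 24.96 ccm on the 4×4×5 mm grid.  The 40%
method recovers 24.72 ccm (−1% of the voxelized truth); the entropy-stopped
region grow, with a threshold calibrated from lesion-interior vs
boundary-overreach reference regions on a separate calibration acquisition,
recovers 20.72 ccm — it stops at the edge of the full-intensity plateau,
inside the blurred skirt.  `examples/stability_analysis.py`,
`examples/motion_comparison.py` and `examples/table_statistics.py`
demonstrate the repeated-measurement statistics, the motion-blur comparison
and the reporting arithmetic.

A thin CLI mirrors the library:

```bash
petseg phantom generate --out ph/ --seed 1
petseg segment ph/phantom.nii.gz --method threshold --seed 64,64,20
petseg evaluate stability --out results/ --repeats 20
petseg evaluate diff --uncorrected 56.4 --corrected 46.6
```

Inputs may be NIfTI files or directories of single-series axis-aligned
DICOM slices; masks and reports are written as NIfTI + JSON, traces and
tables as CSV.

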