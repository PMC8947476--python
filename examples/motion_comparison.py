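"""Effect of respiratory motion blur on segmented volumes.

Simulates the same sphere phantom statically and with 15 mm sinusoidal
cranio-caudal motion (12 cycles/min, time-averaged), segments both with the
40% threshold method, and reports the signed relative volume difference —
the uncorrected-vs-motion-corrected comparison.
"""

from petseg import PhantomSpec, SeedPoint, mask_volume_ccm
from petseg.evaluation import motion_difference
from petseg.phantom import noiseless_motion_blurred, noiseless_static
from petseg.segmentation import threshold_segment

spec = PhantomSpec(rng_seed=0)
static = noiseless_static(spec)
moving = noiseless_motion_blurred(spec)

print("sphere  static(ccm)  motion-blurred(ccm)  difference")
for i, nominal in enumerate(spec.sphere_volumes_ccm):
    seed = SeedPoint(*spec.sphere_center_voxel(i))
    v_static = mask_volume_ccm(threshold_segment(static, seed), spec.spacing)
    v_moving = mask_volume_ccm(threshold_segment(moving, seed), spec.spacing)
    diff = motion_difference(v_moving, v_static)
    print(f"{nominal:4.0f} ccm   {v_static:8.2f}      {v_moving:8.2f}        {diff:+.1f}%")
print()
print("Positive differences: the time-averaged (uncorrected) acquisition smears")
print("activity along z, enlarging the 40% isocontour — the volume error that")
print("motion correction removes.")
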