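"""Repeated-measurement stability of the four segmentation methods.

Runs a reduced version of the phantom stability experiment (5 consecutive
noisy acquisitions instead of the full 20, to keep this demo quick): three
spheres (3/12/26 ccm), jittered seed clicks, four methods.  Prints the
per-(method, sphere) mean volume, difference to truth, range and relative
standard deviation — the quantities used to judge segmentation stability.
"""

import warnings

from petseg import PhantomSpec
from petseg.evaluation import stability_experiment

warnings.simplefilter("ignore")

spec = PhantomSpec(rng_seed=1)
result = stability_experiment(spec, repeats=5)
cols = [
    "method", "sphere", "nominal_ccm", "mean_ccm", "difference_percent",
    "min_ccm", "max_ccm", "relative_sd_percent",
]
print(result.table[cols].round(2).to_string(index=False))
print()
print("relative SD (%) = 100 x sample SD / mean over the repeated volumes.")
print("For the threshold method the small sphere is the least stable: partial-")
print("volume blur leaves it barely larger than the 27-voxel start region, so")
print("repeats vary relatively more.  The texture methods are less accurate and")
print("less stable on this homogeneous phantom, whose only texture contrast is")
print("the lesion edge itself (see docs/methods.md).")
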