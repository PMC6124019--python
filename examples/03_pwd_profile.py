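"""Phase-weighted density: occupancy sub-regions and the SI staircase.

Counts, per voxel, how many of the 10 phase GTVs cover it (k), converts
the occupancy fraction k/10 to a density between the lung (-625 HU) and
target (-50 HU) means, and overrides the free-breathing dataset inside
the ITV.  The profile along the motion axis is a symmetric staircase:
the center is occupied 8/10ths of the cycle, the extremes only briefly.
"""

import numpy as np

from lungphan4d import MotionModel, PhantomSpec, render_fb_volume, si_profile
from lungphan4d.pwd_override import build_pwd_dataset, pwd_density
from lungphan4d.structures import build_itv_ptv

# odd voxel counts so a voxel center sits exactly on the rest position
spec = PhantomSpec(grid_spacing=(1.0, 1.0, 1.0), grid_extent=(101.0, 101.0, 141.0),
                   texture_sd=0.0, seed=0)
motion = MotionModel(amplitude_mm=15.0)

gtvs, itv, _ = build_itv_ptv(spec, motion)
fb = render_fb_volume(spec, motion)
pwd, occ = build_pwd_dataset(fb, gtvs)

print(f"occupancy levels present: {sorted(int(k) for k in np.unique(occ.counts))}")
prof = si_profile(pwd, *spec.target_rest_center[:2])
sel = prof[np.abs(prof["si_mm"]) <= 32]
for _, row in sel.iloc[::4].iterrows():
    bar = "#" * int((row.hu + 650) / 12)
    print(f"z = {row.si_mm:+6.1f} mm   {row.hu:7.1f} HU  {bar}")
print("Each plateau is one occupancy sub-region: rho = (k/10)(-50) + (1-k/10)(-625).")
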