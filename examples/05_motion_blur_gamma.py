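"""Dose smearing on a moving detector and gamma comparison.

Computes an AP/PA plan on the static phantom, extracts the coronal plane
through the target (the film plane), convolves it with the arcsine
position kernel of ±1.5 cm sinusoidal motion, and gamma-compares the
blurred (delivered-like) plane against the static (planned) plane at the
conventional 3%/3 mm and the stricter SBRT 3%/1 mm criteria.
"""

from lungphan4d import MotionModel, PhantomSpec, render_phase_volume, shm_pdf_kernel
from lungphan4d.dose_engine import ap_pa_plan, extract_coronal_plane
from lungphan4d.gamma_analysis import gamma_map
from lungphan4d.motion_blur import convolve_dose_plane
from lungphan4d.structures import build_itv_ptv

spec = PhantomSpec(grid_spacing=(2.0, 2.0, 2.0), seed=0)
motion = MotionModel(amplitude_mm=15.0)
volume = render_phase_volume(spec, motion, 0)
_, _, ptv = build_itv_ptv(spec, motion)

plan = ap_pa_plan(volume, ptv)
plane = extract_coronal_plane(plan, spec.target_rest_center[1])
kernel = shm_pdf_kernel(motion.amplitude_mm, plane.spacing[1])
blurred = convolve_dose_plane(plane, kernel, axis=1)
print(f"arcsine kernel: {kernel.size} bins, sum {kernel.sum():.12f}, "
      f"edge bins carry the most mass ({kernel[0]:.3f} vs center {kernel[kernel.size // 2]:.3f})")

for dose_pct, dta in [(3.0, 3.0), (3.0, 1.0)]:
    res = gamma_map(blurred, plane, dose_pct=dose_pct, dta_mm=dta)
    print(f"gamma {dose_pct:g}%/{dta:g}mm: pass rate {res.pass_rate:.1f}% "
          f"(max gamma {res.max_gamma:.2f}, n={res.n_evaluated})")
print("Motion smears the field edges; the tight 3%/1 mm criterion punishes "
      "that smearing far more than 3%/3 mm does.")
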