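"""Point-dose sensitivity to target density (single AP field).

Overrides the target structure's CT value from -200 to +200 HU in 25 HU
steps and reports the percent dose change at four central-axis points:
P1 (3 cm upstream of the target), P2 (isocenter), P3 (3 cm downstream),
P4 (past the lung cavity).  The toy attenuation engine reproduces the
qualitative physics: upstream dose ignores the target density entirely;
downstream dose falls monotonically as the target gets denser.
"""

from lungphan4d import MotionModel, PhantomSpec, gtv_mask_at_phase, render_phase_volume
from lungphan4d.dose_engine import hu_sweep_experiment

spec = PhantomSpec(grid_spacing=(2.0, 2.0, 2.0), seed=0)
still = MotionModel(amplitude_mm=0.0)
volume = render_phase_volume(spec, still, 0)
gtv = gtv_mask_at_phase(spec, still, 0)

table = hu_sweep_experiment(volume, gtv)
pivot = table.pivot(index="override_hu", columns="point", values="pct_change")
print(pivot.round(3).to_string())
print("\nP1 is exactly flat (upstream of the target); P3/P4 swing by a few "
      "percent over the 400 HU sweep, the attenuation signature of target density.")
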