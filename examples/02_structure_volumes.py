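"""ITV/PTV construction across motion ranges (plan-parameter table).

For each motion amplitude the 10 phase GTV spheres are unioned into the
internal target volume (ITV) and expanded by the 5 mm RTOG 0915 setup
margin into the planning target volume (PTV), on the default 1 mm grid.
The volumes grow with the motion range — the price of covering a moving
3 cm target with a static aperture.
"""

from lungphan4d import MotionModel, PhantomSpec
from lungphan4d.structures import build_itv_ptv, volume_table

spec = PhantomSpec(seed=0)  # default 1 mm grid
rows = []
for amplitude in (5.0, 10.0, 15.0):
    _, itv, ptv = build_itv_ptv(spec, MotionModel(amplitude_mm=amplitude))
    rows.append((amplitude, itv, ptv))

print(volume_table(rows).to_string(index=False))
print("\nA static 3 cm sphere alone is 14.1 cc; the rest is motion and margin.")
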