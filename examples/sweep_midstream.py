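"""Structural-parameter calibration by sensitivity sweep.

The midstream diameter of the filling pipe is not measurable directly; it
is calibrated by sweeping candidate values and scoring each simulated
tablet-weight series against a reference with the mean absolute relative
error f. Here the reference is itself simulator output at 33 mm, so the
sweep must (and does) return f = 0 at 33 mm and grow away from it.
"""

from tabletpress import build_case_study, sweep_midstream_diameter
from tabletpress.scenarios import generate_reference_series

scenario = build_case_study()
reference = generate_reference_series(scenario)  # weight series at 33 mm

diameters = (6.0, 12.0, 18.0, 24.0, 30.0, 33.0, 36.0, 42.0)
results = sweep_midstream_diameter(scenario, diameters, reference)

print("midstream diameter sweep against the 33 mm reference series:")
print(" d (mm)   f (%)")
for r in results:
    print(f"  {r.parameter:5.0f}   {100*r.f:6.3f}")
best = min(results, key=lambda r: r.f)
print()
print(f"minimum at {best.parameter:.0f} mm (f = {best.f:.4f}): the sweep recovers")
print("the generating geometry. Small midstreams delay the fast-lane")
print("breakthrough and distort the whole transition, hence the rising f.")
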