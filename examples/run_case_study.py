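"""The material-changeover case study: coarse -> fine DCPA and back.

Runs the full 25-minute changeover (A150 for 1 min, A60 for 12 min, then
A150 again) and prints how each critical quality attribute responds as the
new material flows through the filling pipe and feed frame. Every tablet
carries lot-level provenance, so the fraction of each feed lot is known
per tablet.
"""

from tabletpress import build_case_study

scenario = build_case_study()
result = scenario.run()
frame = result.to_frame()

print(f"tablets produced: {len(frame)}  (80 per minute for 25 minutes)")
print(f"mass-ledger max relative error: {result.ledger_max_rel_error:.2e}")
print()
print(" time   x_A60   weight   stress  porosity  strength")
print(" (min)    (-)     (mg)    (MPa)      (-)      (MPa)")
for minute in (1, 5, 8, 10, 12, 14, 16, 18, 20, 22, 25):
    row = frame.iloc[(frame.time_min - minute).abs().argmin()]
    print(
        f"{minute:5d}  {row.x_A60:6.3f}  {row.mass_g*1000:7.1f}  "
        f"{row.compression_stress_MPa:7.1f}   {row.out_die_porosity:6.4f}   "
        f"{row.tensile_strength_MPa:7.3f}"
    )

peak = frame.iloc[frame.x_A60.idxmax()]
print()
print(f"A60 fraction peaks at {peak.x_A60:.4f} at minute {peak.time_min:.1f} —")
print("about 4.4 min after the feed reversal at minute 13, the transit time")
print("of the fast pipe midstream. Weight and stress rise with the denser")
print("fine grade; strength first dips slightly (the zero-porosity strength")
print("of blends collapses exponentially with A150 content) before the much")
print("lower porosity wins out.")
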