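"""Layer-thickness morphometry on a synthetic histology mask.

Builds a labeled section phantom with known layer thicknesses and an
undulating boundary, profiles it strip by strip, and prints the
mean ± sd thickness table.  The mean should land on the generator's
setting and the sd should reflect the undulation amplitude (A/sqrt(2)
for a sinusoid).
"""

from fiberweave import PhantomTruth, SampleMeta, gen_layer_image
from fiberweave import strip_thickness, thickness_table

truth = PhantomTruth(
    layer_thickness_mm={"SC": 0.39, "VE": 0.05, "D": 0.8},  # a distal dorsal site
    boundary_undulation_mm=0.05,
    seed=11,
)
mask = gen_layer_image(
    truth, width_px=1000, pixel_size_mm=0.01,
    meta=SampleMeta(surface="dorsal", distance_from_tip_cm=3.0),
)
profile = strip_thickness(mask)
table = thickness_table([profile])

print(table.formatted.to_string(index=False))
print()
for layer, (mean, sd) in profile.summary.items():
    print(f"{layer}: requested {truth.layer_thickness_mm[layer]:.2f} mm, "
          f"measured {mean:.3f} ± {sd:.3f} mm over 1000 strips")
print("\nThe sd comes almost entirely from the planted 0.05 mm boundary "
      "undulation (expected ≈ 0.035 mm for a sinusoid).")
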