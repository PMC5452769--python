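"""Build a bone-thickness map from a synthetic temporal-bone phantom.

Generates a curved bone plate (3-9 mm thick, with sealed air cells, an open
middle-ear-like cavity and a sinus-like groove), runs segmentation ->
surface split -> closest-point thickness, and prints how the outer surface
area distributes over the clinical <5 / 5-6 / 6-7 / >7 mm bands.
"""

from pathlib import Path

import bonemap as bm

spec = bm.PhantomSpec(seed=1, spacing=0.5)
mask, truth, frame = bm.make_temporal_phantom(spec)

config = bm.RunConfig(output_dir="example_map", seed=1,
                      exterior_faces=truth.exterior_faces)
report, partition, field = bm.run_generate_map(config, mask=mask, frame=frame)

print(f"external surface vertices: {report['n_external_vertices']}")
for b, frac in enumerate(report["band_area_fraction"]):
    label = ["< 5 mm (white, do not implant)", "5-6 mm (blue)",
             "6-7 mm (green)", "> 7 mm (pink)"][b]
    print(f"  band {b} {label}: {100 * frac:.1f}% of surface area")
print("thickness percentiles (mm):", {k: round(v, 2) for k, v in
                                      report["thickness_percentiles_mm"].items()})
print(f"outputs in {Path(config.output_dir).resolve()}")
# The band fractions tell the surgeon at a glance how much of this bone can
# host the 6 mm-deep cavity; the exported PLY carries the same data per vertex.
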