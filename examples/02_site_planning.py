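"""Evaluate implant sites against the drilling-safety rule.

The port cavity is 10 mm x 5 mm and at most 6 mm deep; its deepest point
must sit in bone strictly thicker than 6 mm.  A uniformly 5 mm shell shows
the exclusion behaviour: no site anywhere passes, which is exactly the
criterion for excluding a patient from the implantation.
"""

import bonemap as bm

for outer, inner in [(40.0, 33.0), (40.0, 35.0)]:
    nominal = outer - inner
    mask, truth = bm.make_shell_phantom(outer, inner, spacing=0.5)
    part = bm.partition_surfaces(bm.extract_surface(mask), mask)
    field = bm.compute_thickness(part)
    sites = bm.scan_candidate_sites(part, field, bm.PortFootprint(), stride=150)
    print(f"{nominal:.0f} mm shell: {len(sites)} passing sites", end="")
    if sites:
        best = sites[0]
        print(f"; best margin {best.min_margin_mm:.2f} mm, "
              f"flatness RMS {best.flatness_rms_mm:.2f} mm")
    else:
        print("  -> bone thinner than 6 mm everywhere: exclude from implantation")
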