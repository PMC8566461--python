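"""How much cargo has reached a marker compartment, and how fast?

Computes Manders coefficients between a cargo channel and a Golgi-like
marker, then a time course in which the generated cargo→marker overlap rises
from 10% to 70% — emulating retrograde cargo arriving at the Golgi — and
shows the pixel-level colocalization fraction recovering that rise.
"""

import numpy as np

import traffiq as tq
from traffiq.geometry import rasterize_polygon
from traffiq.scene_sim import simulate_coloc_timecourse

times = [0, 10, 30]  # minutes after cargo uptake
overlaps = [0.1, 0.4, 0.7]  # generated fraction of cargo on the marker
cargo, marker, roi, truth = simulate_coloc_timecourse(overlaps, times, seed=2)
mask = rasterize_polygon(roi.cell_polygon, cargo[0].shape)

res = tq.manders(cargo[-1], marker[-1], mask)  # final time point
print(f"t = {times[-1]} min: M1 (cargo on marker) = {res.m1:.2f}, "
      f"M2 (marker on cargo) = {res.m2:.2f}")
print("   M1 is the fraction of cargo-positive pixels that are also")
print("   marker-positive (Otsu thresholds within the cell mask).")

tc = tq.fraction_colocalized_over_time(cargo, marker, mask, times, marker="GM130")
print("\ntime course (fraction of cargo colocalized with the marker):")
for _, row in tc.fraction_colocalized.iterrows():
    t = row["time_min"]
    gen = truth["overlaps_realized"][times.index(t)]
    print(f"  t={t:>4.0f} min  measured={row['fraction']:.2f}  generated={gen:.2f}")
print("-> the measured fraction tracks the generated overlap within ~0.1,")
print("   the resolution the point-spread function allows at pixel level.")
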