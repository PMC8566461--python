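"""Focal-adhesion morphometrics and front-rear polarity on the wound front.

Simulates cells carrying 40 edge-localized focal adhesions of mean area
60 px², recovers count and size by particle analysis, then scores polarity:
the fraction of FA intensity inside a 120-degree sector pointing along the
migration direction (apex at the nucleus centroid). A cell is polarized when
that sector holds the strict majority of the signal.
"""

import numpy as np

import traffiq as tq
from traffiq.geometry import front_sector, rasterize_polygon
from traffiq.scene_sim import SceneConfig, simulate_scene

# unbiased FA placement: the calibration case
cfg = SceneConfig(n_cells=5, n_fa=40, n_puncta=0, cell_radius_range=(80, 90),
                  image_size=220, fa_front_bias=None, seed=3)
counts, areas, fracs = [], [], []
for scene in simulate_scene(cfg):
    mask = rasterize_polygon(scene.roi.cell_polygon, scene.images["fa"].shape)
    table = tq.segment_puncta(scene.images["fa"], mask, min_size=4)
    counts.append(table.count)
    areas.append(table.mean_area_px2)
    sector = front_sector(scene.roi, direction=0.0, half_width=np.deg2rad(60))
    res = tq.polarity_score(scene.images["fa"], sector, basis="intensity", cell_mask=mask)
    fracs.append(res.in_sector_fraction)
    golgi = tq.golgi_area(scene.images["golgi"], mask)
    print(f"{scene.cell_id}: FA count={table.count}, mean area="
          f"{table.mean_area_px2:.0f} px², golgi area={golgi['area_px2']} px², "
          f"in-sector fraction={res.in_sector_fraction:.2f}")

print(f"\nmean FA count {np.mean(counts):.1f} (generated: 40), "
      f"mean FA area {np.mean(areas):.0f} px² (generated: 60)")
print(f"mean in-sector fraction {np.mean(fracs):.2f} "
      "(uniform placement -> expected 120/360 = 0.33)")
print("-> unbiased cells sit at the 1/3 null; polarized wound-front cells")
print("   (front bias -> 1) push the fraction past 0.5 and are scored polarized.")
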