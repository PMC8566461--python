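"""Where does endocytosed cargo sit along the cell's radial axis?

Simulates cells whose cargo puncta are drawn mostly from the perinuclear
band (fast-trafficking, mesenchymal-like state), builds compartment masks,
scores each cell by its maximal perinuclear vs peripheral intensity, and
reports the % of cells classified perinuclear — the per-condition statistic
used to compare trafficking speeds.
"""

import numpy as np

import traffiq as tq
from traffiq.geometry import build_compartment_masks, radial_lines
from traffiq.scene_sim import SceneConfig, simulate_scene

cfg = SceneConfig(n_cells=10, perinuclear_weight=0.8, seed=1)
scenes = simulate_scene(cfg)

labels = []
for scene in scenes:
    masks = build_compartment_masks(scene.roi, perinuclear_band=0.25,
                                    peripheral_band=0.15,
                                    shape=scene.images["cargo"].shape)
    score = tq.compartment_max(scene.images["cargo"], masks)
    labels.append(tq.classify_cell(score, tie_margin=0.1))

frac, table = tq.percent_perinuclear(labels)
print(f"generator perinuclear mixing weight: {cfg.perinuclear_weight}")
print(f"% cells classified perinuclear:      {100 * frac:.0f}%")
print(table.to_string(index=False))
print("-> with 80% of puncta drawn perinuclear, most cells score perinuclear;")
print("   epithelial-like scenes (weight ~0.2) score mostly peripheral.")

# a linescan profile from the plasma membrane inward for the first cell
scene = scenes[0]
segs = radial_lines(scene.roi, n_lines=3, length=40)
profile = tq.linescan_profile(scene.images["cargo"], segs, channel="cargo")
peak = profile.distances[np.argmax(profile.mean_intensity)]
print(f"\ncell {scene.cell_id}: cargo profile peaks {peak:.0f} px from the membrane")
print("   (deep peaks = perinuclear cargo; shallow peaks = cargo still at the PM)")
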