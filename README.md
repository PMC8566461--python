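# traffiq

Quantification of subcellular trafficking from multi-channel fluorescence
micrographs, time-lapse movies, and plate/densitometry tables — with a
ground-truth scene simulator so every measurement can be validated
end-to-end.

## The problem

Cells on the epithelial–mesenchymal spectrum differ in how fast they move
endocytosed cargo: in slow-trafficking (epithelial-like) cells, internalized
cargo such as fluorescent transferrin lingers near the plasma membrane,
while in fast-trafficking (mesenchymal-like) cells it reaches a perinuclear
compartment within minutes, is recycled, degraded, or routed retrogradely to
the Golgi, and the cell builds a front–rear polarity axis with Golgi and
focal adhesions oriented toward the leading edge. Comparing these states
quantitatively requires a consistent battery of per-cell measurements. This
package implements that battery for researchers analyzing single-cell
trafficking experiments:

- **Radial profiling** — linescan intensity profiles on fixed-length,
  fixed-width lines from the plasma membrane (PM) inward; perinuclear and
  peripheral compartment masks; per-cell maximal compartment intensities;
  classification into perinuclear/peripheral cells and the per-condition
  "% perinuclear cells" statistic.
- **Colocalization** — Manders coefficients M1/M2 within a cell mask.
  M1 = Σᵢ I₁ᵢ·[I₂ᵢ > t₂] / Σᵢ I₁ᵢ over channel-1 foreground (intensity
  mode), or the same with indicator weights (pixel-count mode, default);
  cargo-vs-marker fractions over time.
- **Morphometrics** — focal-adhesion (FA) particle analysis (count, area)
  via thresholding + 8-connected labeling; Golgi suprathreshold area;
  front–rear polarity scored as the fraction of structure signal inside an
  angular sector rooted at the nucleus centroid (polarized ⇔ fraction > ½).
- **Dynamics** — per-track speed (path length / elapsed time), net
  displacement, and directionality (net / path ∈ [0, 1]); pH-sensor
  maturation time series; in-cell-ELISA internalized % and recycled
  fraction (BCA-protein normalized); densitometric degradation curves with
  single-exponential half-life fits (t½ = ln 2 / k).
- **Statistics** — unpaired two-tailed Student's t, one-way ANOVA, and
  Spearman rank correlation, with per-group n, mean, and SEM.
- **Simulator** — synthetic cells (perturbed ellipses), cargo puncta drawn
  from a perinuclear/peripheral radial mixture with mixing weight p, Golgi
  blobs, edge-localized FAs with controllable front bias, directed/Brownian
  tracks, intensity ramps, plates, and decay tables — all with recorded
  ground truth and bit-reproducible from (config, seed).

ROIs (cell and nucleus outlines) are inputs, as polygons in JSON or CSV;
the package does not segment whole cells, link tracks, or deconvolve.

## Worked example

`examples/05_two_condition_pipeline.py` simulates 30 epithelial-like cells
(perinuclear mixing weight 0.2) and 30 mesenchymal-like cells (weight 0.8),
scores each cell's maximal background-subtracted intensity in the
perinuclear and peripheral compartment masks, and compares conditions:

```
         metric            group  n  mean  sem  p_value
perinuclear_max  epithelial_like 30 251.1 15.7 1.54e-14
perinuclear_max mesenchymal_like 30 501.1 18.9 1.54e-14
 peripheral_max  epithelial_like 30 428.6 16.9 1.46e-15
 peripheral_max mesenchymal_like 30 223.5  8.4 1.46e-15
```

Perinuclear maxima are ~2× higher in mesenchymal-like cells and peripheral
maxima ~2× higher in epithelial-like cells — the two trafficking states
separate cleanly on both axes with 30 cells per condition. The other
examples each exercise one capability (radial profiling, colocalization
time courses, FA morphometrics and polarity, tracks and kinetics) the same
way: generate a scene with known truth, measure, print both.

A thin CLI mirrors the pipeline verbs:

```bash
traffiq simulate --n-cells 10 --seed 1 --outdir out/sim
traffiq demo --seed 1 --outdir out/demo
traffiq stats values.csv --test t
```

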