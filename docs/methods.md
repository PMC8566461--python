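# Methods

This note documents the measurement model behind `traffiq`, the parameters
that matter, what the synthetic-scene generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Geometry: compartments, linescans, sectors

A cell is a pair of simple closed polygons (cell outline, nucleus outline)
in pixel coordinates, convention `(x, y) = (column, row)`, 0-based.
Rasterization is half-open: a pixel belongs to a mask iff its center lies
strictly inside the polygon; pixel–boundary distances are computed exactly
against the polygon exterior (shapely), not on a rasterized approximation.

**Compartment masks.** There is no universally agreed numeric definition of
"perinuclear" vs "peripheral". We define, for every cytoplasmic pixel, the
normalized radial coordinate

u = d_nuc / (d_nuc + d_cell),

where `d_nuc` and `d_cell` are distances to the nucleus and cell
boundaries. u runs from 0 at the nuclear envelope to 1 at the plasma
membrane (PM). The perinuclear compartment is `u ≤ perinuclear_band`
(default 0.25) and the peripheral compartment `u ≥ 1 − peripheral_band`
(default 0.15). Expressing the bands as fractions makes the definition
scale-free across cell sizes; on concentric circles it coincides exactly
with "within band × R of each boundary", with R the mean
nucleus-to-membrane distance (reported in `band_params`). The two masks are
disjoint for *any* cell shape — including a nucleus touching the PM, where
the bands pinch to zero width locally — whenever the fractions sum to less
than 1; violating that raises `bands-overlap` rather than silently
intersecting.

**Linescans.** Sampling segments run from the cell boundary toward the
nucleus centroid, by default 3 per cell evenly spaced in angle (matching
the common practice of averaging 3 linescans per cell), length and width in
pixels configurable with no claim of matching any particular acquisition
(defaults: length 40–50 px, width 3 px). Intensity at distance d is the
bilinear interpolation averaged over the width-px perpendicular slab, then
averaged across lines at equal distance (averaging, not max). Distance 0 is
at the PM. Segments longer than the boundary-to-centroid distance truncate
at the centroid and are flagged; truncated segments contribute to the mean
profile only up to their own length.

**Sectors.** A front sector is an apex (nucleus centroid), direction, and
angular half-width; given two front edge points instead, the sector spans
the smaller arc between them. Membership is a pure angle test, so sector
partitions of [0, 2π) tile the cytoplasm up to pixels lying exactly on a
boundary ray.

## Scoring and classification

Compartment scores are maximal background-subtracted intensities per
compartment (background default: median intensity outside the cell mask —
robust and parameter-free; floored at 0). Cells are labeled perinuclear
when the perinuclear maximum exceeds the peripheral maximum by a relative
tie margin (default 10%), peripheral in the mirrored case, otherwise
ambiguous; two zero maxima are ambiguous, not an error. The margin rule is
our operationalization of a call usually made by eye; it is deliberately
scale-invariant (multiplying the image by c > 0 changes no label). The
per-condition statistic "% perinuclear cells" counts ambiguous cells in the
denominator.

## Colocalization

Manders coefficients are computed within the cell mask after per-channel
thresholding (Otsu within the mask by default; fixed cutoffs accepted).
With foregrounds F₁ = {I₁ > t₁}, F₂ = {I₂ > t₂}:

- pixel-count mode (default): M1 = |F₁ ∩ F₂| / |F₁|,
- intensity mode: M1 = Σ_{F₁∩F₂} I₁ / Σ_{F₁} I₁,

and M2 symmetrically. The numerator is restricted to channel-1 foreground
in both modes — the standard thresholded form, which guarantees M ∈ [0, 1]
and the exact swap symmetry M1(A,B) = M2(B,A). Both modes are provided
because commercial packages differ; pixel-count is the default since the
"fraction of red or green pixels overlapping" phrasing describes pixels,
not intensity. A channel with no suprathreshold pixels yields NaN plus an
`empty-channel` flag. Cargo-vs-marker time courses apply M1 frame by frame.
Costes randomization and object-matching colocalization are out of scope.

## Morphometrics and polarity

FA segmentation thresholds within the cell mask, labels 8-connected
components, and discards components below `min_size` (default 4 px²) —
standard particle-analyzer defaults. Reported per particle: centroid, area
(px², µm² when a pixel size is given), mean intensity; per cell: count and
mean area. FA "size" is area. Golgi compactness is summarized as total
suprathreshold area. Polarity is the fraction of suprathreshold structure
intensity (default) or of particle centroids inside the front sector;
"majority" is strict (> 0.5, ties not polarized). Intensity is the default
basis because it is robust to fragmented segmentation of large adhesions.
The front direction is an input (wound geometry or simulator truth); the
package does not infer it from images.

## Dynamics and kinetics

Track statistics take tracks as tables (tracking/linking is upstream):
speed = path length / elapsed time (per-step semantics; net displacement is
reported separately), directionality = net displacement / path length,
defined 0 for a degenerate zero-length path. For Brownian tracks the mean
directionality decays roughly as n^(−1/2) with track length — used as a
behavioral sanity check.

Maturation series report mean vesicle intensity per frame. By default the
vesicle pixel set is fixed on the first frame and the per-frame background
(median outside the cell) subtracted: a brightening spot's suprathreshold
footprint grows with amplitude, so re-thresholding per frame would
systematically understate the intensity ramp; fixing the pixel set makes a
linear amplitude ramp recover exactly. Per-frame re-thresholding remains
available (`fixed_mask=False`); frames without vesicle pixels are recorded
missing and dropped pairwise, not imputed.

Plate kinetics BCA-normalize each well's signal before any ratio, so a
common positive rescaling of all raw signals cancels. Internalized % is
100 × (sample/BCA) / (surface-total/BCA); the recycled fraction is
(internalized − remaining-after-strip) / internalized, clamped to [0, 1]
with an explicit flag when measurement noise forces clamping. Degradation
curves normalize band/loading-control ratios to 100% at t = 0 and
optionally fit A·exp(−kt) by unweighted least squares on the normalized
scale (t = 0 included; simplest defensible default), reporting
t½ = ln 2 / k.

## Statistics

`compare_groups` wraps scipy: unpaired two-tailed Student's t (paired
optional), one-way ANOVA (post-hoc comparisons out of scope), Spearman rank
correlation on paired vectors; per-group n, mean, SEM are always reported.
The analysis unit is the cell (dots pooled across replicates); no multiple
testing correction is applied by default. Two-way ANOVA (condition × time)
is not implemented. Zero-variance degenerate inputs are flagged rather than
erroring.

## The scene simulator

The generator produces the data every measurement is validated against,
emulating the geometry of single-cell trafficking micrographs:

- **Cells**: ellipses (radius default 45–60 px, aspect 0.8–1.0) with
  low-order Fourier boundary perturbation (amplitude 6% of radius), chosen
  over arbitrary polygons so radial bands stay analytically checkable. One
  cell per image tile; `n_cells` controls the number of tiles, which keeps
  ground truth keyed per cell with no occlusion handling.
- **Cargo**: by default 30 puncta of amplitude 200 rendered as isotropic
  Gaussians (PSF σ = 2 px; no optics simulation), radial position drawn
  from the perinuclear band u ∈ [0.03, 0.25] with probability p
  (`perinuclear_weight`) and from the peripheral band u ∈ [0.85, 0.97]
  otherwise. p is the biological knob: ~0.2 emulates slow epithelial-like
  and ~0.8 fast mesenchymal-like trafficking.
- **Markers**: DAPI = filled nucleus; Golgi = a 400 px² disk abutting the
  nucleus, doubling as the colocalization marker; in overlap-driven mode
  each cargo punctum lands inside the marker with a set probability (the
  time-course generator raises that probability over frames while the
  marker stays fixed).
- **FAs**: hard disks (area ~ N(60, 6²) px²) placed in the outer band
  u ∈ [0.45, 0.9] by rejection sampling with a >2 px gap so 8-connected
  labeling can separate them; angular placement uniform or biased into the
  front sector with probability q. Dense configurations that cannot be
  packed raise `bad-config` instead of silently overlapping.
- **Noise**: additive Gaussian read noise (σ = 2) over a flat background
  (10), optional Poisson shot noise, floored at 0. Tracks: directed steps
  v·dt along a fixed per-track direction plus per-axis N(0, jitter²), or
  per-axis N(0, σ²) Brownian steps — so the expected step length has a
  closed form (Rice mean for directed, Rayleigh mean σ√(π/2) for
  Brownian). Plates/decays: multiplicative lognormal noise with unit mean
  and specified CV; decay noise sits on the measured band, with a separate
  knob for loading-control noise.

Everything is driven by one `numpy` Generator seeded from the config, so
identical (config, seed) gives bit-identical images, tables, and files.

**What the simulator does not emulate** — and hence what passing recovery
tests do not show about real data: touching/overlapping cells, organelle
texture, depth (3-D) structure, chromatic shift, photobleaching,
camera-specific noise, segmentation error in hand-drawn outlines, and
motion more complex than directed-plus-jitter or pure diffusion. Recovery
results bound algorithmic error under a known forward model, not
end-to-end error on micrographs.

## Problem sizes and defaults used in validation

The validation suite and the acceptance script use: 100 random 32×32 image
pairs against a brute-force per-pixel Manders oracle; 50 cells per mixing
weight across p ∈ {0.1, …, 0.9}; 100 cells per condition for the
two-condition contrast; 100 directed + 100 Brownian tracks of 50 frames;
10 cells × 40 FAs for morphometric recovery; 200 cells for the polarity
null calibration; 6-replicate plates at 5% CV; 9-point decay series; and
10,000 simulated null repetitions for t-test calibration. These sizes give
the recovery estimates comfortable margins relative to their tolerances
while keeping a full run in tens of seconds.

## Known limitations

- ROIs are trusted inputs; no whole-cell segmentation or QC beyond polygon
  validity checks.
- Otsu thresholds assume a roughly bimodal intensity distribution inside
  the mask; very sparse or very dense signal can shift them (fixed
  thresholds are accepted everywhere for that reason).
- The exponential degradation fit assumes a single decay compartment and
  is unweighted; heteroscedastic densitometry would call for weighting.
- Pixel-level colocalization saturates when the PSF is large relative to
  structure spacing; at σ = 2 px the recovered overlap fraction carries a
  small (+0.02-ish) tail bias relative to punctum-level truth.
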