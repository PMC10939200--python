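# Methods

## Coordinate and angle conventions

Voxel arrays are indexed `(z, y, x)` with channels on a separate leading
axis. Pixel coordinates are 0-based with pixel centres at integer
coordinates; physical position (µm) = index × voxel size. The y coordinate
equals row index × pixel size (no row flip on load); angles are degrees,
counter-clockwise from +x toward +y, so "trailing edge at +90°" means the
rear of the cell points along +y. Because the synthetic generator, the mask
construction and the vector measurements all share this one convention, no
orientation ambiguity can arise between stages; real images whose y axis is
conventionally drawn downward simply have their angles mirrored, which the
`orient_to_migration` / oriented-vector step absorbs (the migration angle is
supplied in the same frame as the image).

After basal alignment, `z_origin` marks the basal plane and z increases
toward the cell interior; "slices beyond the basal surface" are the planes
at z < `z_origin`.

Mask rasterization uses strict pixel-centre-in-region containment (a centre
exactly on a region boundary is excluded). This event has measure zero for
generic geometry; all brute-force cross-checks use the same rule.

## Single-cell secretion quantification

A cell is outlined per plane on the F-actin cortex over nine planes
(z-step 0.15 µm) from the basal surface. The basal plane is the one
maximizing the summed tubeness (Sato ridge) response at the stress-fibre
scale (0.3–0.5 µm); the score is built from second derivatives, so it is
invariant to intensity offset and positive rescaling, and ties break toward
smaller z. Basal-plane selection is usually done by eye — the plane where
stress fibres look sharpest; the ridge score is this package's
operationalization of that judgement and is validated against generator
labels only.

The automated cortex tracer (a convenience for synthetic data — hand-drawn
outlines are first-class inputs and were the original method's mode of
operation) resamples each smoothed plane into polar coordinates around the
seed and finds a minimum-cost closed contour along the ridge by dynamic
programming with a ±1-bin radial step; the angular axis is tiled three
times and the middle copy kept, a deterministic approximation to the cyclic
optimum.

Measurement masks:

* **Hollow cylinder** (lateral): pixels whose centres lie within
  thickness/2 = 0.75 µm of the outline polygon's boundary, on each outline
  plane. The band straddles the cortex symmetrically because the
  surface-stained secreted protein is apposed to the cortex on its outside;
  a symmetric band is robust to ±1 px segmentation bias. Thickness below
  one pixel falls back to a one-pixel ring with a warning.
* **Full cylinder** (basal): the basal outline eroded inward by 0.75 µm and
  replicated on the three planes beyond the basal surface. "Shrunk to
  0.75 µm in diameter" in the source protocol is ambiguous; it is read here
  as an inward erosion of 0.75 µm, which exactly clears the half of the
  hollow band that hangs inside the cortex, guaranteeing the two masks are
  disjoint (also asserted at run time). Likewise "three slices beyond the
  cell surface" is read as the three planes outside (below) the basal
  surface, where basal secretion foci sit at the cell–BM interface; both
  choices are configurable.

Background: the mean voxel intensity of a user-drawn background region,
computed separately on the lateral plane set and the basal plane set, is
subtracted (count × mean) from each cylinder sum. Negative post-subtraction
sums clamp to zero and set a QC flag; whether the original macro clamped is
unstated, and clamping keeps the fraction in [0, 100]. L + B = 0 yields a
null (not zero) fraction. The fraction is exactly invariant to a global
positive rescaling, and invariant to a uniform additive offset because the
offset is absorbed by the background term.

The polarization vector is centre-of-mass minus isobarycenter of the hollow
cylinder voxels (xy only, physical µm; anisotropic voxels are never
resampled so sums stay exact), with background-subtracted, negative-clamped
intensities as weights, then rotated so the trailing edge maps to +90°.
Circular summary: mean = atan2(Σsin, Σcos), R = |Σe^{iθ}|/n; vectors with
zero weight or zero magnitude are excluded with a count.

The suprabasal band height is the smallest contiguous window of lateral
planes containing ≥ 80 % of the background-subtracted hollow-cylinder
signal, converted to µm by the z-step.

## Fibril fraction

FF = 100 × Σ(raw intensity on fibril mask) / Σ(raw intensity on analysis
region) — raw, not background-subtracted, because FF is defined against
total BM fluorescence. The segmenter: grey-opening flat-field removal at
5 µm (≫ fibril width, level-preserving), homogeneous level = median with
one refinement step excluding pixels > 2σ above it (fibril flanks bias a
plain median upward at high coverage), robust σ = one-sided (lower-tail)
MAD scaled to the normal distribution — fibrils only add signal, so the
lower tail is noise-dominated even at 20–25 % fibril coverage. Threshold
level + k·σ with k = 4, binary closing with a 1-px disk, and removal of
components whose skeleton is shorter than 1.5 µm. The original macro is
unpublished, so this operator is the package's own definition; absolute FF
values are comparable within it, and it is validated purely by synthetic
parameter recovery (±5 points at FF 10–40 %, SNR 10) and by monotonicity in
fibril amplitude.

## Sections and edge ratios

Thick polylines rasterize as a stroked band of the stated width with flat
end caps (the band ends at the line endpoints), mirroring a thick
segmented-line selection closely enough for ratio statistics. Apical
fraction is computed without background subtraction by default (the source
protocol used none); an optional background ROI restores exact offset
invariance. The suprabasal projection for edge ratios means the three
planes covering [0.15, 0.60) µm from the basal surface; the direction
defaults to the cell interior, where the suprabasal cortex lives, and is
configurable.

## Synthetic generator

`gen_single_cell` emulates a columnar follicle cell: an irregular 12-gon
cortex (radius 5 µm ± 12 %) constant across 12 planes (9 lateral + 3
sub-basal, z-step 0.15 µm, 0.1 µm pixels), an F-actin ridge (Gaussian
cross-section, σ 0.12 µm) on every plane plus 1 µm-spaced stress fibres on
the basal plane, and a secreted channel that splits a fixed photon total
(2×10⁵) between (a) a lateral cortical band — radial Gaussian σ 0.15 µm on
the cortex, exponential decay in height truncated at 0.8 µm, azimuthal von
Mises concentration equivalent to a 35° wrapped-normal spread around the
rear direction, with a 12° per-cell jitter of that direction — and (b)
rear-biased basal foci (σ 0.18 µm) on the sub-basal planes, with the split
set by the true lateral fraction (70 % in the control preset, matching the
wild-type phenotype it emulates; the band height matches the < 1 µm
suprabasal observation). Foci centres stay ≥ 3σ inside the eroded basal
cylinder so the measurement geometry captures them. Noise is applied last:
scaled-Poisson shot noise on signal + a uniform 8-photon offset, plus
Gaussian read noise (σ 2); `noise_scale=0` disables noise entirely, and the
default amplitudes put the lateral-band peak near SNR 10.

`gen_bm_surface` lays oriented fibrils (length 6–18 µm, FWHM 0.7 µm,
orientation spread 15°) over a flat matrix (level 100) and *solves* the
fibril amplitude so the noiseless fluorescence share on the truth mask
(distance < width/2 from a fibril axis) equals the requested FF exactly;
Gaussian noise with σ = amplitude/SNR (default SNR 10). Requested FF above
95 % or unreachable for the drawn geometry raises.

`gen_sagittal` draws apical and basal walls (Gaussian cross-section,
σ 0.4 µm) whose amplitude split realises the apical fraction, and emits
three ROI pairs. `gen_edge_stack` draws a hexagonal cortex whose rear edge
carries ratio × the front amplitude and emits the three measurement
polylines; the hexagon carries a 10° phase so no edge aligns with the pixel
grid, which would otherwise quantize the thick-line pixel coverage.

Identical (params, seed) pairs are bit-identical. Per-item seeds in
multi-cell studies derive from `SeedSequence([base, index])`.

### What the generator does and does not emulate

It reproduces the *geometry and statistics* the pipeline measures —
cortical ridges, secretion band placement, fibril texture, wall splits,
noise levels — with idealized optics: no PSF blur or AiryScan artifacts, no
z-attenuation, no neighbouring cells, no cortex curvature along z, and
arbitrary intensity units (the real data's absolute scales are
unpublished). Passing recovery tests therefore demonstrates that the
measurement definitions are implemented correctly and are robust to
shot/read noise at realistic SNR — not that segmentation would succeed on
arbitrary real tissue; for real data the pipeline is designed around
hand-drawn outlines.

## Study sizes and numerical choices

Validation studies use 30 cells per condition (secretion phenotype), 20
cells per point of the lateral-fraction ladder, and 10 images/stacks per
point for FF, edge-ratio and apical-fraction recovery, at the image sizes
above (180² × 12 voxel cells, 200² BM images) — sizes at which every
summary statistic is stable to well under its validation tolerance.
Tie-breaks and degenerate inputs: basal-plane ties go to smaller z; empty
eroded polygons, all-zero channels, seeds on background, unclosable ridges
and zero-signal fractions raise typed errors rather than returning
sentinel numbers; undefined circular means (R < 1e-12) and undefined
ratios are null, never 0.
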