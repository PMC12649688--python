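# Methods

This note documents the models implemented in `fluorotrack`, the choices
made where the design was genuinely open, and what the synthetic test
conditions do and do not establish about real data.

## Coordinate conventions

Room coordinates are millimeters with the origin at the machine
isocenter: X = left–right (LR), Y = superior–inferior (SI),
Z = anterior–posterior (AP). Volumes are arrays indexed (x, y, z) with z
the slice axis; voxel (i, j, k) has world position
`origin + (i, j, k) · spacing`. Image pixels are 0-based, x = column,
y = row, origin top-left; the detector center maps to pixel
((W−1)/2, (H−1)/2).

## DRR rendering

Each detector pixel casts a ray from the point source through the pixel
center. Linear attenuation is `μ(HU) = μ_water · (1 + HU/1000)` clamped
at ≥ 0, with `μ_water = 0.02 /mm` (a 100 kV-range effective value; only
relative attenuation survives the final rescaling). HU is sampled by
trilinear interpolation at midpoints of fixed steps of half the minimum
voxel spacing (the trailing partial step is weighted by its true
length), and intensity is `255 · exp(−∫μ dl)` — transmission-bright, so
air renders bright and dense material dark. Rays that miss the volume
render at full brightness. Halving the step changes smooth-phantom
pixels by less than one intensity level (tested).

**Slice interpolation.** Planning-CT stacks are densified by inserting
the arithmetic mean of each adjacent slice pair midway, taking n slices
at spacing s to 2n−1 slices at s/2 (2 mm → 1 mm in the clinical
workflow). The operation is exact for volumes linear in z.

**Label projection.** A label pixel is positive when its ray visits at
least `min_voxels = 7` *distinct* mask voxels. "Visited" is defined by
the sampled walk itself: each midpoint sample is assigned to its nearest
voxel index, and distinct indices are counted (a straight ray never
re-enters a voxel, so counting index-change events is exact). This
sampled definition is the contract; corner voxels whose chord is shorter
than the step may be missed, identically so in the independent
exhaustive-walk oracle used by the tests. Labels are then cleaned by
morphological opening followed by closing with a 10×10 elliptical
structuring element (built directly from the inscribed-ellipse equation,
since standard footprint helpers only produce odd sizes).

**Standard background.** The SB mask is 1 inside the largest centered
inscribed circle, radius ⌊min(W, H)/2⌋ — the circular imaging field of
an image intensifier. The radius is a convention, not a measurement.

**Triangulation.** Stereo rays rarely intersect; the reported 3-D point
is the midpoint of the common-perpendicular segment, the residual half
its length. Rays closer than 0.1° to parallel raise a degenerate-
geometry error. The project → triangulate round trip is identity to
< 1e−6 mm over random geometries (tested).

## Noise characterization

From N frames of a static phantom, the temporal average `I_avg` serves
as the clean reference. Per pixel:

* probability `P_N = (1/N) Σ 1(|I_k − I_avg| > τ)`, default τ = 2 gray
  levels (appropriate when the reference is averaged from enough frames
  that its own residual noise is negligible);
* amplitude `A_N = (1/N) Σ |I_k − I_avg|` (mean absolute deviation).

Intensity–noise curves bin pixels by the *rounded average-image value*
(the clean-content proxy) inside the SB mask; background pixels never
enter a bin. Curves are smoothed with a centered moving average (window
9 bins; the window is a choice — only that smoothing happens is part of
the procedure) and fitted with a degree-10 least-squares polynomial in
the scaled variable u = V/255 (a raw-intensity Vandermonde of degree 10
is numerically singular; coefficients are documented as ascending powers
of u).

The beam center is estimated as the intensity-weighted centroid of
in-mask pixels at or above the 90th brightness percentile — the beam
axis appears as the brightness peak of the average image. A perfectly
flat image returns the geometric center with a `flat` flag.

Spatial calibration radially bins each observed map about the beam
center and grid-searches `B + (Max − B)(1 − exp(−d²/2σ_d²))` over
(σ_d, B), solving Max in closed form per grid point. A map whose radial
profile varies by less than 5% (relative) is flagged *spatially
insensitive* and reported at the grid's largest σ_d — the regime in
which the spatial factor is flat across the field of view, as seen on
newer detectors with uniform collimation.

## Degradation model

Noise maps for a clean frame (intensities V from the clean image, radial
distances d from the beam center at the image center plus offset X_c):

    Np = scale(Pmax, Bp, f_vp(V) · f_sp(d)),   f_s(d) = B + (1 − e^{−d²/2σ_d²})
    Na = scale(Mmax, Ba, f_va(V) · f_sa(d))

`scale(Max, B, ·)` maps the raw product's per-image minimum to B and
maximum to Max (a constant raw map collapses to B). The amplitude
content curve is multiplied by a fixed factor 2 before scaling; because
`scale` is min–max affine this leaves the final map unchanged, so the
factor is applied where the curve is evaluated (factor-then-scale) for
fidelity to the calibration procedure. Defaults: Pmax = 0.92, Mmax = 16
intensity levels.

The shipped default content curves are degree-10 fits to a smoothed
piecewise-linear template honoring the empirically observed four-phase
structure — rapid ascent (0–85), plateau (85–190; probability ≈ 0.81,
amplitude ≈ 6.5), sharp decline (190–225), recovery (225–255 averaging
≈ 0.56 / ≈ 2.75). Device-specific curves from `characterize_stack`
replace them in real use (measured curves carry their own amplitude
scale, so their `amp_factor` is 1).

One degradation draw (fully determined by an integer seed; draw order is
fixed: uniform matrix, then primary values in row-major masked order,
then secondary values):

1. uniform matrix R ~ U(0,1); mask M = [R < Np];
2. sparse primary noise ~ N(μ, σ = Na(p)) at masked pixels;
3. Gaussian diffusion of the sparse array, σ = 2.0 px (reflect
   boundary, kernel truncated at 4σ) — the scatter/detector blur;
4. blend with the clean image; fresh secondary noise at the same masked
   locations (per-pixel σ = Na(p), same law as the primary draw);
5. clip to [0, 255], 8-bit output.

μ (the global noise mean) defaults to 0 and can be overridden from a
characterization result. For exact statistical verification the
secondary draw, the diffusion and the clipping can each be disabled;
with a single unclipped Gaussian event per pixel the outputs obey the
closed forms `P_N = Np · 2(1 − Φ(τ/Na))` and `A_N = Na · Np · √(2/π)`,
which the test suite checks within three standard errors per radial
pixel bin over 5000 frames.

Dataset synthesis resamples per generated image: X_c components
~ N(0, 30 px) (independent per component, 30 interpreted as the standard
deviation), σ_d ~ U(103, 113) px, Bp ~ U(0.35, 0.37),
Ba ~ U(1.8, 2.0). The manifest records every drawn parameter per pair.

## Trajectory analysis

The tumor center per frame is the mask centroid (mean member-pixel
column/row index); sequences sample at 30 fps so t = frame/30 s. Frames
with an empty mask carry the previous centroid forward and are flagged;
an empty first frame is an error.

**Filtering.** A digital 4th-order Butterworth low-pass (bilinear
transform, normalized cutoff f_c/(f_s/2); defaults f_c = 8 Hz,
f_s = 30 Hz) applied forward–backward (zero phase). Respiratory and
cardiac energy sits below ~2 Hz, while segmentation jitter is broadband;
8 Hz retains physiology with margin. Forward–backward application
squares the designed magnitude response — verified against `freqz` at
14 Hz by synchronous demodulation, since plain RMS at −150 dB
attenuation is dominated by residual edge transients. Edges are handled
by reflective padding of 3× the filter order; trajectories must be
longer than that padding.

**Alignment and grading.** Trajectories are aligned by shifting to the
reference's mean position (tumor centroid and fiducial marker are
different anatomical points; only relative motion is comparable — which
also means constant localization biases are invisible to these metrics).
Accuracy is RMSE per axis; the final error E = max(RMSE_x, RMSE_y) in
pixels, graded E < 3 Excellent, 3 ≤ E < 8 High, 8 ≤ E < 13 Moderate,
E ≥ 13 Low. 3-D statistics (after frame-wise triangulation, residual
> 2 mm flags a frame) are per-axis mean ± SD of absolute errors plus the
per-frame Euclidean series with median and IQR, in millimeters.

Whether to filter before or after triangulation is not fixed by the
procedure; the pipeline filters the 2-D trajectories and then
triangulates.

**Marker tracking.** The reference marker tracker is a plain normalized
cross-correlation template search in a window around the previous
position with separable quadratic sub-pixel refinement — deliberately
simple plumbing for generating reference trajectories, not an optical-
flow method. Frames whose peak correlation falls below threshold keep
the previous position and are flagged.

## Synthetic phantoms and motion

Respiratory displacement per axis is the per-axis amplitude times
`sin(ωt + φ) + Σ r_k sin(k(ωt + φ))` with defaults of a 2nd harmonic at
relative amplitude 0.3 and a 3rd at 0.1 — chosen to reproduce the
typical measured harmonic structure of respiratory motion (a dominant
fundamental near 0.33 Hz at 20 breaths/min with decaying integer
harmonics); no standard closed-form waveform exists, so the form is a
documented choice. Amplitudes default to (2, 8, 3) mm LR/SI/AP, SI-
dominant as for lower-lobe tumors. An optional cardiac sinusoid can be
superimposed. Motion is rigid whole-volume translation; deformation,
hysteresis and drift are *not* modeled, so passing tests bound only the
geometric fidelity of the projection/trajectory chain, not segmentation
difficulty on deforming anatomy.

Phantom materials use fixed plausible HU defaults (gelatin 0, aluminum
2000, lung −800, tumor 40, marker 3000), all configurable. The thorax
stand-in is an ellipsoidal tumor in a uniform lung background with
single-voxel markers — no realistic CT texture, vasculature or ribs.
Noise injection for statistical tests is Bernoulli(q) × N(μ, a) per
pixel with an option to disable 8-bit clipping, because the closed-form
laws used as oracles hold only unclipped. All generators derive
per-frame substreams from (seed, frame) so any frame is reproducible in
isolation, and outputs are byte-identical across runs at a fixed seed.

## End-to-end verification conditions

The full-fidelity tracking check renders an 80 mm lung cube (1 mm
voxels) with a 10 mm spherical tumor and one marker, viewed by ±45°
stereo chains (source–axis 1000 mm, source–detector 1500 mm, 144×144
detectors at 0.4 mm pitch), breathing at 30 breaths/min with (2, 5, 2) mm
amplitude over exactly one period (60 frames at 30 fps). The field of
view is sized so the tumor silhouette never touches the detector edge —
silhouette clipping biases the centroid, the dominant failure mode at
small fields. With ground-truth masks the recovered 3-D path stays
within 0.1 mm of the motion model per frame; this isolates label
pixelation + triangulation error and says nothing about segmentation
accuracy. Smaller problem sizes (48 px detectors, 2 mm voxels, 16
frames) are used for behavioral tests where sub-0.1 mm fidelity is not
the property under test.

## Known limitations

* The degradation model is statistical: no polyenergetic spectra,
  detector MTF, or physically derived scatter kernels.
* The empirical non-monotonic decline of noise beyond roughly one field
  radius (visible on older devices) is not represented by the monotone
  spatial factor; calibration absorbs it into base/max levels.
* A spatial shape parameter beyond σ_d (steepness of the radial rise) is
  not exposed; calibration fits σ_d and base/max levels only.
* Bit-exact reproduction across RNG implementations is not promised —
  the draw order is documented so other implementations can be
  statistically equivalent.
* The toy segmenter is a placeholder for a learned model; its accuracy
  on realistic contrast is not a claim of this package.
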