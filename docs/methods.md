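# Methods

`cbct4d` simulates respiratory-resolved thoracic cone-beam CT (CBCT)
acquisitions from a synthetic breathing phantom and compares three
reconstruction strategies for *rapid* (16.6 s, 491-projection) scans against
the conventional (240 s, 1320-projection) respiratory-correlated baseline.
This note documents the models, the numerical choices, and what the synthetic
study can and cannot say about real data.

## The breathing thorax phantom

Anatomy is a nest of analytic shapes inside an elliptical body: two
low-attenuation lung ellipsoids, a liver whose superior boundary (the
diaphragm dome, a shallow spherical cap inside the right lung) moves
superior-inferiorly with respiration, and a spherical tumor in the left lung.
Attenuation is linear attenuation in mm^-1 (soft tissue/liver 0.020, lung
0.004, tumor 0.024); a HU map is provided for display only.

Respiration is regular with waveform `s(phase) = (1 - cos 2*pi*phase)/2`:
smooth, cyclic, one extremum per cycle. Phase 0 is peak inhale (diaphragm
most inferior, maximum lung volume); it is auto-detected by counting aerated
lung voxels, and serves as the motion-compensation reference phase.

Motion is a *single global deformation*: the anatomy at phase p is the
reference anatomy sampled at `x - s(p) * m(x)`, where `m` is a smooth
full-exhale displacement field composed of a flat-topped diaphragm term
(exactly the configured SI amplitude across the lung-liver interface, wide
cosine falloffs chosen so `|grad m| <~ 0.4` and the field stays
diffeomorphic-scale) and a flat-topped bump rigidly carrying the tumor.
Defining phases as deformations of one reference has two consequences we
rely on:

* `analytic_dvf` recovers the *exact* phase-to-reference mapping by a
  fixed-point solution of the implicit warp equation, so motion-compensation
  error in the pipeline comes only from the deliberately mismatched planning
  model, never from an inconsistency internal to the phantom (an earlier
  formulation with structures sliding inside static shells put an
  irreducible, unphysical error floor under motion compensation);
* interface and tumor displacements are exactly `s(p)` times the configured
  amplitudes inside the plateaus, giving closed-form oracle values for tests.

Voxelization is centre-point membership (no partial volume) so voxel values
are exactly predictable; a 2x supersampling flag provides smoother edges when
wanted. Grids are axis-aligned with `(x, y, z) = (left-right,
anterior-posterior, inferior-superior)` in mm.

Default motion: 15 mm diaphragm SI amplitude, (1, 2, 8) mm tumor amplitude.
Cohort mode draws per-patient anatomy and motion uniformly around the
defaults (diaphragm amplitude 10-20 mm, tumor centre +-8 mm, radius
9.5-14.5 mm), values typical of lung-cancer 4DCT cohorts.

### Planning-vs-truth mismatch

The deformable registration that derives planning deformation fields in a
clinical workflow is deliberately externalized: planning DVFs are analytic,
and `mismatch(phantom, amplitude_scale, drift_mm)` produces the planning
phantom whose motion amplitudes are scaled and whose anatomy is rigidly
offset, emulating a different-day planning 4DCT. The cohort draws the scale
from U[0.70, 0.95] and each drift component from U[-4, 4] mm - inter-session
amplitude changes of 5-30% and residual setup offsets of a few millimetres
are routinely reported for thoracic 4DCT. User-supplied DVF files are
accepted through the same interface for real registration output.

## Acquisition simulation

Full-fan circular geometry: 1000 mm source-isocenter, 1536 mm
source-detector, flat detector centred on the beam axis, 200 degree arc.
Protocols: conventional (1320 projections / 240 s / 16.5 breaths per minute)
and rapid (491 projections / 16.6 s / 16.1 bpm); the breathing rates make the
conventional scan allocate exactly 132 projections to each of the 10 phase
bins. Projection i is taken at `t_i = i * duration / n` through the phase
volume whose bin (`floor(10 * phase)`, with a 1e-9 rounding guard so
exact-rational schedules bin exactly) matches the respiratory phase at `t_i`;
there is no intra-bin interpolation, matching how a 10-phase 4DCT represents
motion. Projections are noiseless line integrals; ray-driven fixed-step
sampling (step = half the smallest voxel spacing) with trilinear
interpolation, validated against analytic cube and sphere chord lengths to
<1%.

Presets share the protocols and physical geometry and change only sampling:
`full` (1 mm voxels, 500x400 detector at 1 mm) and `desk` (4 mm voxels,
80x56x64 grid, 125x100 detector at 4 mm), which preserves the angular and
respiratory sampling structure - the scientific variable - at desktop
compute cost. A coarser `small` preset exists for fast end-to-end tests.
All study numbers quoted here are desk-preset.

## Reconstruction

FDK filtered backprojection: cosine pre-weighting
`sdd/sqrt(sdd^2+u^2+v^2)`, Parker short-scan redundancy weights
(parameterized by the scan arc, effective half-fan `(arc-180deg)/2`;
conjugate rays sum to 1; full circles use 1/2), row-wise Ram-Lak ramp
(spatial-domain taps, FFT convolution, zero-padded to the next power of two
>= twice the row length, no apodization by default, Hann optional), then
voxel-driven backprojection with the `(sid/U)^2` distance factor. The
normalization reconstructs absolute attenuation: a static-phantom short scan
recovers homogeneous-ROI values within 0.5% at desk scale.

**4DFDK bin weighting.** Respiratory-correlated FDK reconstructs each phase
from its own projections. Each projection in a bin carries the uniform
angular weight `arc / n_bin` rather than its Voronoi gap. For the evenly
interleaved conventional scan the two are identical; for the clustered
rapid-scan bins, gap weighting would hand cluster-edge projections ~50x
weight and its streaks dominate everything downstream, while uniform
weighting keeps every bin normalized to absolute attenuation and makes the
phase-mean of the bins algebraically equal to the 3DFDK of the same data -
so motion-compensated FDK becomes exactly a warped 3DFDK decomposition, the
form used in the motion-compensated FDK literature. Rapid bins remain
limited-angle (spans down to ~139 degrees, gaps > 30 degrees) and their
reconstructions streak-dominated; a warning is logged whenever a bin's
coverage falls below 180 degrees plus the fan angle, and the pipeline flags
the rapid 4DFDK arm "insufficient".

## Motion-compensated FDK

Pipeline: 4DFDK; rigid translation registration of the 3DFDK reconstruction
to the planning 3DCT (FFT cross-correlation of mean-subtracted images with
parabolic sub-voxel refinement - invariant to global intensity scaling);
transport of the planning DVFs into the treatment frame; pull-warp of every
phase volume to the peak-inhale reference; equal-weight voxel average; and
inverse warps of the averaged volume back to the ten phases.

Numerical choices:

* **Translation handling.** Displacement vectors are invariant under rigid
  translation, so the pipeline resamples each field at the offset location
  with vectors unchanged (`apply_translation_to_dvf(..., fold_in=False)`),
  the exact frame composition. The fold-in variant
  (`d'(x) = d(x-t) - t`), which makes warping also re-align the frames, is
  provided for callers that want one-step behaviour; folding the constant
  into the field leaves an O(|drift| * |grad d|) residual that measurably
  blurred outputs at 4 mm drift scale, which is why it is not the pipeline
  default.
* **DVF inversion** is a damped fixed-point iteration
  `e <- e + 0.5 * (-d(x+e) - e)`, convergent for field gradients well beyond
  the plain iteration's limit; composition residuals on the phantom fields
  are < 0.05 voxel (tolerance 0.01 voxel, max 200 sweeps, error on
  non-convergence).
* **Warp interpolation.** `warp` defaults to trilinear with clamp-to-edge
  (no zero halos inside the body). The MCFDK pipeline warps with cubic
  B-splines (`interp_order=3`): at 4 mm voxels the smoothing of two
  successive trilinear resamplings is comparable to the motion blur being
  compensated - a discretization artifact that would not exist at 1 mm - and
  cubic interpolation restores scale-consistent behaviour.
* **Averaging** uses equal phase weights; bin populations differ by at most
  ~12% (rapid) so data-mass weighting would change the average negligibly.
* The reference output phase is the averaged volume itself (its translated
  DVF is zero); `translation` can be passed explicitly to bypass
  registration, which the algebraic tests use since the exact
  "MCFDK = phase-mean of 4DFDK" identity presumes exactly zero alignment.

## Image-quality metrics

Computed per phase over automatically placed subvolumes (liver cube 21 mm,
upper-lung cube 11 mm, 5x5 mm diaphragm column of run length 60 mm, large
thoracic similarity box; sizes defined at 1 mm voxels and converted to the
working spacing, reproducing the literature voxel counts at full scale):

* CNR `(mu_FG - mu_BG)/sigma_BG`, sample (n-1) SD;
* TIS: the 25 SI runs of the diaphragm column are min-max normalized,
  polarity-flipped to lung-to-tissue increasing, and fit with a logistic
  `1/(1+exp(-k(z-z0)))` (k bounded to (0, 10] per voxel, initial k from the
  10-90% crossing distance, deterministic initialization; runs with no
  fittable edge - R^2 < 0.5 - are excluded, > 50% exclusions is an error);
  TIS is the mean fitted *rate* k, the only convention consistent with the
  width formula below;
* TIW `= 2 w ln(9) / TIS` (mm, w = voxel length): the 10-90% rise distance
  of the average sigmoid;
* RMSE and global (single-statistic, not sliding-window) SSIM over the
  similarity box, after least-squares affine windowing of the reconstruction
  onto the ground truth over that box; SSIM constants `c1=(0.01 L)^2`,
  `c2=(0.03 L)^2` with L the joint dynamic range of the two subvolumes;
* phase averages over computable phases; two-sided paired-samples t-tests
  between arms across the cohort.

Phases whose CNR/TIW boxes leave the reconstructed field of view are flagged
non-computable and omitted from phase averages.

## What the study shows (and does not)

On the seeded 10-patient desk cohort the package reproduces the qualitative
orderings that motivate motion-compensated reconstruction of rapid scans:
RMSE and SSIM order conventional 4DFDK > MCFDK > rapid 3DFDK (better to
worse) for every patient; median TIW orders the same way (4.47 < 5.38 <
16.02 mm); the rapid 4DFDK arm is flagged insufficient and is worst by a
wide margin. The mismatch mechanism is demonstrated directly: MCFDK TIW
falls from 11.4 mm at amplitude scale 0.25 to 5.5 mm at scale 0.75 as the
planning motion model approaches the true motion.

Three caveats are inherent to the synthetic conditions and are reported
rather than papered over:

* **Per-patient TIW overlap.** When a patient's drawn mismatch scale is near
  1, MCFDK's sharpness floor (the 491-view PSF plus cubic warps) can fall
  marginally below conventional 4DFDK's 132-view PSF, so the strict
  per-patient TIW ordering conv < MCFDK holds for 9/10 patients, not 10/10.
  Two effects push this way: the discrete-phase projector removes the
  intra-bin residual blur a real conventional 4DFDK would carry, and a
  near-perfect motion model removes MCFDK's. Clinical cohorts show the same
  overlap (conv-vs-MCFDK TIW differences are small and not always
  significant).
* **CNR is not comparable across arms here.** With noiseless projections
  and texture-free organs (both deliberate: no noise model is part of the
  simulation, and realistic CT texture is out of the phantom's scope), the
  CNR denominator is purely reconstruction artifact, which scales with view
  count - median CNR spans 63 (conv 4DFDK, 132 views/phase) to 156 (rapid
  3DFDK, 491 views). The near-equality of CNR across arms reported on real
  data relies on patient noise/texture common to all arms dominating
  sigma_BG; a noiseless phantom cannot reproduce it, and the acceptance
  test for that property is expected to fail by construction. CNR *within*
  an arm remains meaningful (e.g. the streak-dominated rapid 4DFDK arm has
  ~6x lower CNR than every other arm).
* **The mismatch sweep saturates at the voxel size.** At 4 mm desk voxels a
  residual diaphragm amplitude of 3.75 mm (scale 0.75 of the 15 mm default)
  is already unresolvable: a control with clean ground-truth phases puts
  scales 0.75 and 1.0 both at the minimum measurable TIW, and the measured
  difference between them (about +-1 mm) is sigmoid-fit noise on
  sparse-view ringing. The sweep is therefore monotone only down to the
  resolution floor; at 1 mm voxels the final step would be resolvable.

Other known limitations: no scatter, beam hardening, detector blur/lag or
bowtie filtration; no bones; full-fan only (no offset-detector half-fan);
breathing is perfectly regular (rate is a config knob, but irregularity and
baseline drift are not modelled); the cone-angle truncation of superior and
inferior slices is unavoidable with a 400 mm-tall detector and is handled by
keeping evaluation subvolumes away from the outer slices.

## Problem sizes and determinism

The bundled tests and the acceptance script run the desk preset: 10-patient
cohort, all four arms per patient, full protocol projection counts. All
randomness (anatomy jitter, mismatch draws) derives from explicit integer
seeds through `numpy.random.default_rng`; identical configuration and seeds
reproduce volumes bit-exactly and report CSVs to float tolerance.
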