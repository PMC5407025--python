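# Methods

This note documents the model implemented by `vsoptrack`, the default
parameters, the numerical choices that are not obvious from the code, and
the known limitations.

## Imaging model and phantom

A session consists of two co-localized 3-D volumes on the same grid:

- **T2-weighted**: tissue intensity 1000, lesion × 1.5 (hyperintense),
  background 0.
- **T2\*-weighted**: tissue 1000, no lesion contrast, planted speckles
  × (1 − contrast) (hypointense) or × (1 + contrast) (hyperintense).

Default grid: 128 × 104 × 20 voxels at 14/128 × 11/104 × 1.0 mm
(axes: sagittal x, coronal y, through-plane z). Slices are 0.8 mm thick
with a 0.2 mm gap (the 1.0 mm z-spacing is thickness + gap). Brain and
lesion are ellipsoids (semi-axes 6 × 4.8 × 8.5 mm and 2.5 × 2 × 3 mm; the
lesion centre sits 3 mm right of the midline). The analytic lesion volume
(4/3·π·abc) is the volumetry ground truth.

Corruptions, each independently seeded and recorded in `GroundTruth`:

- **Speckles** (`n_speckles`, `speckle_contrast`, default 300 at 0.5):
  single voxels (optionally a 6-connected cross) drawn uniformly from the
  affected-hemisphere lesion neighbourhood intersected with a 2-iteration
  erosion of the brain mask. The erosion matters: a dark speckle on the
  brain surface punches a notch in the automatically extracted mask that
  hole-filling cannot repair, silently removing the voxel from the
  hemisphere ROI (and making detection sensitivity non-monotone in
  contrast). Parenchymal placement is also the physically faithful choice
  for intra-arterially delivered cells.
- **Bias field** (`bias_amplitude` 0.1, `bias_smoothness_mm` 6): smoothed
  Gaussian noise rescaled to mean exactly 1 over the brain and peak
  deviation exactly equal to the amplitude; applied multiplicatively.
- **Noise** (`noise_sigma` 0.02 of tissue intensity; `gaussian` or
  `rician`): added inside the brain only, so the background stays exactly
  zero (air in a magnitude image is Rician, but the pipeline never reads
  background voxels; keeping it clean makes tests sharper).
- **Rigid misalignment** (`rigid_transform`): applied to the second
  (9-day) session of a longitudinal pair.

`migrate_speckles` relocates k speckles by a fixed mm displacement
(re-drawing any that would exit the eroded brain interior, or raising if
`on_outside="error"`); `plant_cluster` inserts a contiguous deposit.
`render_session` re-renders any ground truth with fresh noise and bias —
that is how the 9-day session of `generate_longitudinal` is produced.

## Preprocessing

- **Bias correction**: least-squares fit of a total-degree ≤ 3 polynomial
  to log-intensities inside the mask; the exponential, normalized to mean
  1 over the mask, divides the image. The corrected mask mean is preserved
  exactly; voxels outside the mask are untouched. (A polynomial in the log
  domain is the classical parametric alternative to N4 and is exactly
  testable: a planted smooth field is removed to < 2 % tissue CV.)
- **Brain extraction**: Otsu threshold, largest connected component, one
  iteration of 6-connected binary closing, hole filling. A single closing
  iteration recovers a noise-free voxelized ellipsoid exactly; more
  iterations inflate convex boundaries. The midline is the rounded mask
  centroid along the sagittal axis; voxels exactly on the midline plane
  are assigned to the contralateral hemisphere (fixed tie-break).
- **Normalization**: rescale so the brain-mask mean is exactly 1000.
  Every downstream statistic of interest is scale-invariant; the absolute
  level only standardizes reported thresholds.
- **Rigid registration** (`register_rigid`): 6-DOF (intrinsic xyz Euler
  about the volume centre in mm space + voxel translation), maximizing
  normalized cross-correlation over the dilated fixed-image foreground
  with a coarse-to-fine Powell search. Decimation is anisotropy-aware —
  per-axis factors target isotropic resolution, so the thick-slice
  direction is never decimated away — and the translation is initialized
  by aligning foreground centres of mass. If no candidate beats the
  identity, the identity is returned with a warning.

## ΔCSI

Per analysed slice, sample moments (SD with ddof = 1) over each
hemisphere's brain voxels give CVs, combined as
`sqrt(CV_affected² + CV_contralateral²)`; the animal value is the mean
over 7 slices centred on the brain (or lesion) centroid. Slices with an
empty hemisphere ROI are skipped with a warning. Group comparisons use a
two-sided Mann-Whitney U: exact by full enumeration of midrank assignments
for n_a + n_b ≤ 12 (extremeness `min(U, n_a·n_b − U)`), scipy's
continuity-corrected normal approximation otherwise.

## Infarct volumetry

The lesion is segmented on normalized T2 as affected-hemisphere voxels
above mean + 2·SD of the contralateral hemisphere (largest component,
hole-filled; an empty result is valid). Per-slice areas are integrated as

    V = Σ areaᵢ·thickness + Σ gap·(areaᵢ + areaᵢ₊₁)/2,

i.e. slabs plus trapezoidal gap interpolation. Brain volume uses the same
bookkeeping so the infarct percentage is internally consistent. Residual
infarct = 100 · V(9 d) / V(48 h).

## Speckle re-analysis

On the normalized T2\* volume, background voxels are first replaced by the
brain-mean intensity — otherwise the median window of voxels at the brain
edge straddles the dark background and every boundary voxel scores a huge
residual. Then:

1. `|img − median₃(img)|` (3³ median filter, reflective edges);
2. Wiener-type adaptive smoothing: `out = μ + max(σ²−ν, 0)/max(σ², ν)·(x−μ)`
   with ν the volume-mean local variance (flat regions collapse, strong
   outliers pass);
3. strict threshold at mean + 2·SD of the filtered affected hemisphere →
   `speckled_mask`;
4. histogram classification of the *original* intensities of speckled
   voxels: an Otsu split keeps the class(es) whose class mean is below the
   brain mean, plus a strict per-voxel < brain-mean guard → `hypo_mask`.
   Keeping whole classes (rather than splitting at the threshold
   unconditionally) prevents halving a pure hypointense population.

Clusters are 26-connected components. `compare_timepoints` counts voxels
in each session's native frame and maps only the 9-day cluster *centroids*
through the registration transform (resampling a 1-voxel mask would erode
it), then matches clusters greedily by nearest centroid within 3 voxels;
unmatched clusters are reported as appeared/disappeared.

**Noise floor**: with the self-referenced mean + 2·SD rule, a speckle-free
hemisphere keeps roughly the upper ~2 % tail of the noise distribution, so
control phantoms report a nonzero count (as real control animals do). The
count is only meaningful relative to controls; ΔCSI and group comparisons
are unaffected.

## Problem sizes and runtimes

Unit tests run mostly on a 64 × 52 × 14 grid (~10 s total); acceptance
tests use the default 128 × 104 × 20 grid (~80 s total). The acceptance
script takes ~1 minute. Registration of one default-grid pair takes ~10 s.

## Limitations

- The phantom is a single-compartment ellipsoid: no ventricles, cortex, or
  partial-volume texture, so brain extraction and bias correction face
  easier problems than on real data.
- Registration accuracy is assessed on an isotropic grid. On the default
  anisotropic grid (1 mm slices), a moving image *produced by resampling*
  carries asymmetric interpolation blur that displaces the NCC optimum
  itself by up to ~0.7 voxel / ~1.7° for large three-axis rotations — a
  property of simulate-by-resampling, not of the optimizer (it persists
  when the search starts at the true parameters). Real acquisitions are
  not resamples of one another, but sub-voxel accuracy claims on
  thick-slice data should be treated with caution.
- Lesion segmentation is a threshold surrogate for the manual tracing used
  in practice; it assumes a single dominant hyperintense component in the
  affected hemisphere.
- The exact Mann-Whitney branch enumerates C(n, n_a) assignments and is
  limited to n_a + n_b ≤ 12; larger samples use the asymptotic
  approximation.
- Speckle counting reports *voxels*, not cells; with 300 speckles on the
  default grid, deposits are mostly single voxels, and clusters merge as
  density grows.
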