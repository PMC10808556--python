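# Methods

## Model and procedure

`slicemapper` localizes a 2D experimental brain slice along the cutting
axis of a 3D atlas by exhaustive comparison: every candidate template slice
is registered onto the experimental slice and the pair is scored by
normalized mutual information (NMI). The split between the registration
criterion and the selection criterion is deliberate: block matching
optimises local Pearson cross-correlation, which is robust to affine
intensity changes within a block, while NMI — evaluated once on the
registered pair — is invariant to any monotone (indeed any bijective)
intensity mapping and therefore works across imaging modalities. NMI values
are never interpreted absolutely; only their ranking across candidate
slices matters.

Registration runs with increasing degrees of freedom: rigid (initialised by
automated centering) and then affine (initialised by the rigid result).
The two NMI scores are blended as `s_w = (1-w)*s_rig + w*s_aff`. The two
stages are complementary: rigid registration cannot force inappropriate
tissue overlaps, so it separates neighbouring candidates; affine
registration compensates the in-plane linear distortions induced by small
cutting-angle deviations and tissue stretch, so it rewards the truly
matching slice. `w` trades these off; 0.5 is the robust default, and the
`sweep_w` utility re-blends cached profiles over a 1% grid to pick a
modality-specific weighting without re-registering.

Assumptions: tilting angles of the cut relative to the atlas incidence are
zero or negligible (a few degrees at most — their first-order in-plane
effect is absorbed by the affine stage); the slice lies within the template
span; tissue foreground is distinguishable from the background by
thresholding.

## Coordinate and transform conventions

All geometry is in physical micrometres with a pixel-centre convention.
Transforms are pull-back maps (reference point → test sampling point):
warping a template slice through a transform lays it out on the
experimental slice's grid, so propagated labels land in the slice's native
geometry. Slice numbers are 1-based externally. Composition
`compose(theta_rig, theta_aff)` applies the affine increment first, then
the rigid map, matching the order in which the stages were estimated.
Background fill is 0, and images are min-max normalised to [0, 1] at load
time.

## Block matching

Defaults: block size 4 px, spacing 4 px, exhaustive search ±5 px per
pyramid level, top 50% of blocks by intensity variance retained (after
excluding blocks that are >75% exact background), least-trimmed-squares fit
keeping the best 60% of pairs, 3 pyramid levels (finest at the working
resolution) with 2 match/fit rounds per level. The rigid fit is the
orthogonal Procrustes solution; the affine fit is linear least squares;
both iterate the trimmed refit until the inlier set stabilises (capped at 8
rounds). CC peak ties break toward the smallest displacement magnitude,
then lexicographically, which together with stable sorts makes the engine
bit-deterministic. Levels too coarse to hold a block plus its search margin
are skipped; a level whose matching fails leaves the current transform
untouched rather than aborting, except at the finest level with no prior
progress.

Working resolution is 25 µm: fine enough to retain the anatomical detail
the block matcher needs, coarse enough that an exhaustive sweep over ~100
candidates remains interactive.

## Similarity

NMI uses a 64x64 joint histogram over each image's own min-max range,
excluding pixels where *both* images are exactly background (registered
template slices carry large zero-filled borders that would otherwise
inflate similarity). Entropies use the natural log; the ratio is log-base
invariant. Degenerate inputs (constant images, empty masks) raise a
dedicated error rather than returning a number.

## Multi-slice pooling

The template-space counterpart of the experimental inter-slice distance is
`d_t = d_r / gamma`; the whole-slice step rounds `d_t / e_t` half away from
zero. Heterogeneous spacings are supported by rounding the cumulative
template distance at each slice. Candidate windows share a common length by
construction, so the per-slice `s_w` curves align after shifting by each
slice's offset; the pooled score at a candidate first-slice position is the
π-weighted mean of the aligned scores. When a slice's registration failed
at some candidate, its π mass is renormalised onto the remaining slices at
that candidate; a candidate where every slice failed is excluded. The
pooled argmax breaks ties toward the smallest position, and propagated
positions are clamped to the template span with an explicit flag.

γ can be estimated ("auto") by ordinary least squares on the tool's own
independent per-slice estimates against the slice index; the regression's
R² is reported and a warning is emitted below 0.97, the level below which
the series should not be trusted. This requires at least three slices and
constant spacing.

## Synthetic phantom

The generator emulates the properties the method actually relies on in a
real atlas: a smooth super-ellipse "brain" outline growing monotonically
along the slice axis; a cortex-like shell, a deep-nucleus blob (both ≥500
px at working resolution mid-stack), and a deliberately tiny region (<1% of
tissue pixels) to exercise small-structure behaviour; per-region base
intensities overlaid with a smooth drifting modulation and a seeded,
z-correlated 3D texture field whose amplitude (default 0.16 of the dynamic
range) sets how distinguishable neighbouring slices are. Experimental
slices are derived by a monotone intensity remap (emulating a different
modality, including contrast inversion), a known linear transform, Gaussian
noise, and optional artifacts: a locally mirrored band (tissue fold), a
zeroed wedge removing 5-25% of the foreground (missing tissue), or a
salt-speckle patch (external noise).

What the phantom does *not* emulate: real anatomical texture statistics,
staining variability, nonlinear tissue distortions, lighting gradients, or
tilting angles. Passing batteries on the phantom therefore demonstrate the
correctness and internal consistency of the machinery — registration
recovery, peak identifiability, pooling arithmetic, artifact exclusion —
not the absolute accuracy attainable on any particular histological
dataset.

Standard study conditions used by the test batteries and the acceptance
script: a 60-slice template of 96x96 px at 25 µm in-plane and 100 µm
thickness; perturbations with 2-5° rotation, translations up to ~500 µm,
mild anisotropic scales (0.95-1.10); 3% Gaussian noise; a gamma-curve
cross-modal remap. Battery sizes (20 single slices; 10-20 five-slice
protocols; γ ∈ {0.85, 1.0, 1.15}) were chosen to give stable rates while
keeping a full run on a single core in the minutes range.

## Numerical choices and degenerate inputs

- Rounding of slice counts is half-away-from-zero everywhere a distance
  becomes a slice number.
- Argmax ties (candidate sweep and pooled curve) break toward the smallest
  slice number, for determinism.
- Failed candidate registrations are recorded and excluded from the argmax,
  never silently dropped; a sweep with >50% failures logs a warning, and a
  sweep with no successes raises with the per-candidate statuses.
- Rigid compositions are re-orthogonalised after the pyramid loop to remove
  floating-point drift.
- Label images only ever travel through nearest-neighbour interpolation;
  requesting linear interpolation for labels is a contract error.
- The zero-contribution (π = 0) slice still receives transforms and a
  mapped segmentation at its propagated position, re-registering only if
  its cached candidate record failed.

## Known limitations

- Tilting angles are not estimated; strongly tilted sections violate the
  model.
- No nonlinear refinement: local tissue distortions limit achievable Dice,
  particularly for small regions.
- π weights are user-supplied; artifact detection is not automated.
- γ="auto" inherits the quality of the independent per-slice estimates; on
  short or artifact-heavy series the regression can be unreliable (watch
  the reported R²).
- The similarity profile is only as peaked as the template is distinctive;
  templates with near-duplicate neighbouring slices bound the attainable
  precision to about one slice.
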