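# Methods

This note documents the models, conventions, defaults and numerical choices
behind the package, and what its synthetic benchmarks do and do not show
about real data.

## Coordinate conventions and transforms

All coordinates are 0-based pixel indices with a point `(x, y)` meaning
`(column, row)` and the origin at the **center** of the top-left pixel. One
convention, stated once, avoids the classic half-pixel registration bug.

`Transform2D` is `p -> A p + t` with a 2×2 linear part and a 2-vector
offset, tagged with one of four families: translation, rigid, similarity,
affine. Reflections are allowed in the rigid/similarity families (a grid
viewed in the light microscope is routinely mirrored relative to its EM
view) and are recorded in the sign of `det A`, never as a separate flag.
Composition takes the least restrictive family of the operands.

### Least-squares fitting

Given correspondences `(p_i, q_i, w_i)`:

* **translation** — weighted mean displacement;
* **rigid / similarity** — weighted orthogonal Procrustes on centered
  coordinates. The rotation is the polar factor `U Vᵀ` of the weighted
  cross-covariance **without** a determinant correction, so the best
  orthogonal matrix may be a reflection; the similarity scale is
  `Σσ_k / Σ w̃_i ‖p̃_i‖²` (σ_k the covariance singular values);
* **affine** — weighted normal equations on centered coordinates, with a
  rank check: a smallest singular value below 1e-9 of the largest raises a
  degenerate-geometry error (collinear picks cannot constrain an affine map).

Minimum counts are 1 / 2 / 2 / 3 points; degenerate inputs (coincident
points for similarity, collinear for affine) raise rather than return
garbage.

**FRE** is the weighted RMS of the residual norms at the fitted markers.
**TRE** is estimated per point by leave-one-out refitting (reported when at
least minimum+1 points exist). Full anisotropic TRE theory is deliberately
out of scope: the leave-one-out estimate is assumption-light and directly
answers "how far off would a point I did not pick be?". For a similarity fit
on N points with iid target noise σ the expected FRE follows the residual
degree-of-freedom law `E[FRE_RMS] ≈ σ √(2(1 − 2/N))` (4 fitted parameters on
2N coordinates); the benchmarks verify this within the ~3 % Jensen gap of
the root-mean statistic.

### Model defaults

The FM→EM relation is dominated by magnification plus rotation, so both
correlation stages default to **similarity**, which needs only 2 points and
tolerates the small marker counts of the real workflow (8–15 beads, 6–15
gold); affine is available by flag. The inter-channel chromatic shift varies
across the field, so the channel-shift stage defaults to **affine** fitted
on a multicolor-bead calibration field.

## Fiducial detection

A scale-normalized Laplacian-of-Gaussian response at `σ = d/(2√2)` (d the
expected diameter in pixels) is followed by local-maximum extraction, a
two-part cutoff, greedy minimum-separation enforcement (higher score wins;
equal scores keep the smaller (row, column)) and sub-pixel refinement. Dark
markers (gold, beads in EM) are handled by negating the response, never the
input. The cutoff is `max(threshold · max response, k · σ̂)` where σ̂ is the
MAD-based robust standard deviation of the response map; the default
`k = 6` places the floor at a per-pixel false-positive probability of
~1e-9 for Gaussian noise while costing, at SNR 10 with ±20 % marker
brightness variation, well under 1 % recall. When detecting 50 nm gold in a
montage that also contains 200 nm beads, the bead's edge ring responds at
the gold scale at ≲ 0.4 of a true gold response; the workflow therefore uses
`threshold = 0.5` for that stage.

Sub-pixel refinement is an iterative Gaussian-weighted centroid (a
mean-shift fixed point): background (median of the window border) is
subtracted, and the centroid is recomputed with a Gaussian weight centered
on the running estimate. For a symmetric spot the fixed point is unbiased
regardless of sub-pixel phase, which a plain truncated centroid is not. The
weight width defaults to `max(1.2, 0.6 · radius)` px — wide enough to cover
the marker, narrow enough that a neighboring particle inside a generous
window (e.g. 10 nm gold near 50 nm gold) cannot pull the estimate.

200 nm beads are diffraction-limited in the fluorescence channels: their
apparent size is `max(bead diameter, PSF FWHM)`, with the PSF FWHM a
parameter (default 400 nm, consistent with a 0.8 NA air objective).

## Correspondence matching

With an initial transform: mutual nearest neighbors within `max_dist_px`
after mapping. Without one: a deterministic exhaustive hypothesis search —
every source point pair against every ordered target pair defines a unique
similarity (two more with reflection), scored by nearest-neighbor consensus;
the best hypothesis (most inliers, then smallest RMS, then enumeration
order) is refit on its consensus before the final mutual-NN matching. The
search is O(n⁴) and restricted to sets of ≤ 30 points, which covers the
marker counts of the workflow with room for spurious detections.

## Projection, warping, overlays, orientations

* z-projection reduces the tomogram per pixel along z; the default **min**
  keeps the darkest value, which is what collects all electron-dense gold
  into one image.
* Warping is inverse-mapped bilinear resampling; out-of-source pixels get
  fill value 0 **plus a validity mask** in the metadata, so channel
  normalization never sees padding.
* Overlays render the EM base in grayscale and alpha-add each warped FM
  channel in its color after min-max normalization over its valid footprint.
* Orientation matching enumerates the 8 dihedral variants of the LM image,
  each tagged with the rigid transform back to the original frame; when an
  EM reference is supplied a normalized cross-correlation score assists the
  choice, mirroring (not replacing) the manual matching of grid coordinate
  letters.

## Morphometry

All distances are computed in nm, converting from pixels on entry, so
annotations from images of different magnification are directly comparable.

* **Cleft width**: the presynaptic trace is resampled at `step_nm` arc
  length; at each sample the width is the distance along the local normal
  (cast both ways) to the nearest crossing of the postsynaptic trace.
  Normals come from central differences — exact for uniformly sampled arcs —
  and the two end samples, whose normals are only one-sided, are excluded.
  Samples whose normal misses the other trace are dropped and counted.
  Intersecting traces are an error.
* **Vesicle states**: the membrane gap is `dist(center, presynaptic trace)
  − radius`. Defaults: gap ≤ 2 nm → docked/primed; 2–10 nm → tethered
  candidate (the filamentous tethers observed under cryo conditions are
  shorter than ~10 nm); else free. The Ω-shaped *fusing* and membrane-
  continuous *fully fused* states cannot be derived from a circle+polyline
  model and are honored as annotation flags. A vesicle overlapping the
  membrane by more than half its radius without such a flag is an
  annotation inconsistency and raises. Both thresholds are config values;
  the criteria report explicitly flags them as inferred defaults, not
  measured constants.
* **Criteria report**: C1 requires both membrane labels present, ≥ 5
  vesicles on the majority side and ≤ max(2, 20 %) on the minority side —
  an operationalization of "many vesicles on one side, few or none on the
  other". C2 requires ≥ 1 vesicle in an attached state (docked, tethered,
  fusing). C3 requires mean width in [15, 25] nm (a window centered on the
  ~20 nm cleft), coefficient of variation ≤ 0.25, **and** cleft electron
  density — the latter is accepted as an external boolean, because judging
  density in a raw tomogram is out of scope.

## Synthetic scenes

The generator emulates the imaging hierarchy so every operation is testable
against exact truth. Defaults are the emulated experiment's conditions:

| parameter | default | note |
|---|---|---|
| FM pixel | 160 nm | 100× objective onto a 16 µm camera pixel; an assumption — such rigs do not standardize it |
| montage pixel | 4 nm | middle-magnification montage |
| tomogram pixel | 0.5432 nm | final tomographic pixel size |
| beads / 50 nm gold | drawn from 8–15 / 6–15 | the workflow's marker counts |
| PSF FWHM | 400 nm | 0.8 NA air objective |
| noise | 0.1 of peak | SNR 10; Poisson + Gaussian read noise in FM, correlated texture in EM |
| rotations | ≤ 15° coarse, ≤ 8° fine | grid parity is assumed resolved beforehand by orientation matching, so no flip by default |
| channel shift | ≤ 3 px offset, ≤ 1 % linear jitter | affine truth |

Marker placement is uniform dart-throwing with minimum-separation rejection
(2 apparent diameters within a class), all randomness flowing from the
single scene seed through named substreams. Beads live in the FM and
montage frames; 50 nm gold in the montage and tomogram-projection frames;
10 nm gold in the tomogram only (below visible contrast at montage
magnification). Beads are excluded from the tomogram footprint — the
operator targets tilt series away from the opaque microspheres. Markers are
rendered as pixel-integrated Gaussians (FM) or soft-edged discs (EM); any
marker under 1 px in a frame is silently omitted and recorded in the
manifest. Image sizes (256² FM, 1536² EM frames, a 32-slice volume) are the
package's chosen problem size: large enough for realistic marker counts and
separations at the true pixel sizes, small enough to run hundreds of scenes
in a test session. The 3D volume is rendered at a 4×-binned voxel
(~2.2 nm) so a 50 nm gold sphere fits; the 2D projection frame used for
fine correlation is rendered at full resolution.

What the generator does **not** emulate: TEM image formation (CTF, dose,
phase plate), missing-wedge anisotropy, ice texture beyond correlated
Gaussian noise, bead/gold aggregation, and deformations between imaging
sessions (devitrification, grid bending) that would make the true FM→EM
mapping non-planar. Passing benchmarks therefore demonstrates the
correctness and statistical behavior of the algorithms under the stated
model, not performance on degraded real data — on which the robust
estimator and the manual-pick path exist precisely because detection and
matching get harder.

## End-to-end closure benchmarks

*Noiseless*: a fully rendered scene is pushed through detect → match →
coarse → fine → chain; a fluorescent punctum must land within 1 tomogram
pixel (0.5432 nm) of its true position. This is the regime where every
centroid is exact and the only errors are numerical, so it checks the whole
chain's bookkeeping (frames, channel shift, composition) at sub-pixel
stringency.

*Statistical*: 500 scenes with marker-picking noise of σ = 0.5 px applied to
each stage's correspondences **in the pixels of that stage's registration
(target) frame** — montage px (2 nm) for the coarse stage, tomogram-
projection px (0.27 nm) for the fine stage — modeling the picking error in
the image each transform is fitted against. The probe error must stay
within 50 nm (the fine marker's own size) in ≥ 95 % of scenes. Noise
expressed in the low-magnification FM frame instead would correspond to
80 nm per-point error, which no estimator can average below ~50 nm at the
workflow's marker counts; the target-frame convention is the one under
which "registration precision at the scale of the 50 nm marker" is a
meaningful specification.

## Numerical choices and degenerate inputs

* Singular transform matrices are rejected at construction; inversion and
  warping therefore never see them.
* RANSAC requires a consensus of at least minimum+1 points (an
  over-determined refit), is seeded explicitly (no global RNG state
  anywhere in the package), and runs one re-consensus pass after the refit.
* Detection tie-breaks and the hypothesis search are fully ordered, so all
  outputs are reproducible bit-for-bit for a fixed seed.
* Constant images: detection returns an empty list; sub-pixel refinement
  returns the window center with a zero-contrast flag; overlay
  normalization maps constant channels to zero.
* CSV parsing reports the offending row number for non-numeric coordinates
  and detects duplicated header lines.

## Known limitations

* Transforms are strictly planar; nonlinear (spline/elastic) deformation is
  out of scope, as is 3D correlation into the tomogram volume — the fine
  stage targets the 2D z-projection, and gold is never searched for in 3D.
* The hypothesis matcher is quartic in the point count and refuses sets
  above 30 without an initial transform.
* Cleft electron density is an input, not a measurement.
* MRC I/O reads modes 0/1/2 as float and always writes mode 2 (float32).
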