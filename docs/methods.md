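# Methods

This note records the models, conventions and numerical choices behind
`annovox`, in the order a reader meets them: the annotation data model,
the editing operators, agreement metrics, storage formats, the multiuser
workflow, the model-plugin harness, attention maps, and the iterative
model-assisted annotation loop with its synthetic test bed.

## Annotation data model

A project fixes its annotation schema once for the whole dataset so that a
given ROI has the same name, RadLex ID and mask value in every series.
Mask values are powers of two assigned lowest-first and **never recycled**,
even after an ROI is deleted: a stale bit in an old label grid or exported
mask can then never be silently reinterpreted as a new ROI. The budget is
64 bits — the width of one exported mask word; a 65th ROI raises a
capacity error rather than spilling into a second encoding. Renaming or
recoloring an ROI touches only the schema row, never a label grid.

Text annotation fields may carry a closed vocabulary; writes outside the
vocabulary are rejected at the API boundary, which is what makes the
resulting columns usable as classification targets.

ROI names are treated as case-sensitive (the conservative choice: no two
distinct strings are ever conflated). The one-ROI-per-voxel switch is
project-level, and enabling it is refused while any voxel holds two
labels — collapsing would lose data silently.

Coordinates everywhere are 0-based `(x, y, z)` indices into the NIfTI data
array; world coordinates exist only through the affine, which is copied
from the source volume and never modified.

## Editing operators

Paint/erase strokes carry an in-slice footprint, a symmetric cross-slice
extent `z ± k` (clamped at the volume; the symmetric choice treats both
scroll directions alike), and an optional closed intensity window `[lo,
hi]` which the touched voxel set is intersected with. In exclusive mode a
manual paint **replaces** whatever label a voxel had (last-write-wins,
matching interactive expectations), while dilation **refuses** to grow
over another ROI's voxels — growth is not an intentional per-voxel gesture,
so it must not silently eat a neighboring organ.

Morphology defaults to the smallest standard structuring elements: the
in-plane 3×3 cross (slice scope, applied independently per slice) and the
3-D 6-neighborhood (volume scope); both are overridable per call. Erosion
uses `border_value=1` (voxels outside the grid count as foreground), which
keeps erosion exactly dual to dilation on the finite grid so the textbook
bounds `opening(X) ⊆ X ⊆ closing(X)` hold without padding tricks. The
practical consequence — a region touching the volume edge is not eroded
from the edge side — is the standard convention.

Flood fill is in-slice: with a window, the connected component of the seed
among in-window voxels (4- or 8-connectivity); without one, the connected
unlabeled region around the seed (hole filling). A seed outside the window
is a no-op notice, not an error.

Undo/redo stores full label-state snapshots (labels, provenance, points)
per series, 100 deep by default; snapshots make restoration trivially
bit-exact at negligible memory for annotation-scale grids. Stacks are
in-memory and cleared on version commit, so undo never crosses a version
boundary.

### Semi-automated contour refinement

Snap-contour replaces a slice's rough region with a refiner's output. The
default refiner thresholds the slice to the `[p2, p98]` percentile band of
the currently labeled intensities and keeps the 4-connected component
containing the region centroid (falling back to the in-band labeled voxel
nearest the centroid when the centroid is out of band). A component more
than 8× the seed region is treated as a leak into background and returns
empty. This is a deliberately simple percentile-band region grower; the
refiner is a plain callable `(image_slice, region) -> region` so a
dedicated minimal-interaction organ-segmentation algorithm can be swapped
in.

Auto-contour sweeps the refinement across a slice range: seeded slices are
refined first, then each unlabeled neighbor is seeded with the nearest
refined region and refined in turn. Before refining a propagated slice, a
contrast gate compares the seeded region's mean intensity to a 2-voxel
ring around it; when the difference falls below the local intensity spread
the object is considered to have vanished and propagation stops in that
direction. Slices whose ROI content was wholly machine-generated carry
`auto` provenance (rendered downstream in a lighter ROI color); any slice
the user ever edited stays `manual`.

## Agreement metrics and ROI statistics

Dice and Jaccard are computed per slice on one ROI's bit plane and pooled
over the selected slices for the volume summary. **Pooled**, not the mean
of per-slice values: the mean would weight a 3-voxel slice equally with a
3,000-voxel slice, and the pooled definition is the one that agrees with
computing the metric on the concatenated arrays. Slices where both masks
are empty report 1.0 (agreement is vacuously perfect) with an explicit
`both_empty` flag so downstream summaries can exclude them.

ROI statistics report count, physical volume (count × |det| of the
affine's 3×3 block, i.e. mm³ for standard NIfTI affines), intensity
moments, and a 64-bin equal-width histogram over the observed range; an
empty ROI reports count 0 with moments flagged undefined rather than NaN
arithmetic.

## Storage and versioning

Source imaging is read-only, always. Annotations live in a separate store
whose layout mirrors the dataset hierarchy:
`<store>/<patient>/<study>/<series>/annotations.yaml` (points, provenance,
text values, affine) plus a compressed label blob. Mask export writes
NIfTI volumes carrying the source affine verbatim, either one OR-combined
file or one binary file per ROI, with a sidecar CSV
(`roi_name,radlex_id,mask_value`) chosen over a bespoke format for
interoperability. Mask voxel dtype is the smallest unsigned integer that
holds the highest present bit. Import is the exact inverse of export;
bits not covered by the mapping raise an unknown-label error instead of
being dropped.

Version history is append-only: a commit snapshots the full annotation
state (content-addressed with SHA-256), rollback *re-commits* an old
snapshot as a new version, and nothing is ever rewritten. The CLI commits
one version per mutating invocation — the batch analogue of per-stroke
auto-save, which is a GUI concern. The storage backend is the filesystem;
the store interface (save/load annotations, custody records) is the seam
where a content-management backend would plug in.

## Multiuser workflow

The workflow YAML declares users with roles, pools (queues), per-role
rights (`may_acquire_from` pools, `may_assign_to` pools and/or specific
users, with optional per-user overrides), and the pool where unannotated
series start. Custody is exclusive — a series is in exactly one pool or
owned by exactly one user — and only the owner can mutate annotations;
every editing operator consults this gate. Releasing custody (to a pool or
a named user) is the ownership-change event and commits exactly one
annotation version automatically, so each hand-off is recoverable.
Custody mutations carry a ticket; a mutation attempted against a stale
ticket raises contention, which is the backend-agnostic statement of "no
two mutations observe the same prior state".

## Model-plugin harness

A model bundle is an HDF5 weights file plus a YAML metadata descriptor
that fully determines execution: input mode (`2d` per-slice along a chosen
anatomical axis, or `3d_patch` sliding window), an ordered list of affine
input ops (`flip_x`, `flip_y`, `rot90×k`, `scale_to_shape`), intensity
normalization (`minmax`, `zscore`, `fixed_window [lo,hi]` → clip then
scale to [0,1]; degenerate inputs normalize to zeros with a warning), and
the output contract — segmentation classes mapped to ROI names or
classification classes mapped to (text field, value), decided by argmax
(class 0 = background) or per-class thresholds.

Execution needs only `predict(section) -> scores`; the bundled loader
reconstructs a small numpy network (conv/ReLU/GAP/dense with exact
forward and reverse-mode gradients) from the HDF5 file, and named custom
loader hooks admit any other backend. 3-D volumes are tiled with stride =
patch/2 per axis plus a flush window at each far edge; per-class scores
are blended with a strictly positive separable Hann window and divided by
the accumulated weight, so blend weights sum to exactly 1 at every voxel
by construction. Classification over a volume averages per-slice class
scores before the decision rule. All (slice, ROI) pairs produced by
inference carry `auto` provenance. The registry keeps every imported
version and activates the newest; directory discovery imports any bundle
that is new or strictly newer, skips the rest (idempotent re-scan), and
reports malformed bundles without aborting.

## Attention maps

Saliency is the absolute input gradient of the class score, reduced over
input channels by max (the common convention). Grad-CAM at a spatial
layer uses channel weights `α_k = spatial mean(∂y_c/∂A^k)` and clips the
combination at zero; coarse maps are upsampled bilinearly to the input
grid. CAM requires the GAP-followed-by-one-linear-layer architecture and
raises an architecture error otherwise. On exactly that architecture CAM
and final-layer Grad-CAM agree up to the positive factor `1/(H·W)`
(Grad-CAM's α is the dense weight divided by the pooled area), so the two
are compared after min-max normalization, where agreement is exact. The
combined saliency-activation map is implemented as the elementwise product
of the min-max-normalized saliency and Grad-CAM maps, renormalized to
[0, 1]; this is a documented stand-in definition behind a pluggable
function, chosen because it inherits both components' supports and is
zero wherever either is. Display thresholding hides values below
`fraction × max` (default fraction 0.2, adjustable); original values are
retained so re-thresholding is lossless, and thresholding at a fixed
fraction is idempotent.

## Phantoms and the iterative annotation loop

The phantom generator emulates a high-contrast organ on a homogeneous
background: random ellipsoids at foreground intensity 100 on background 0
with additive Gaussian noise of SD 10 (contrast-to-noise 10), in 32³
volumes by default. The truth labels are the exact noiseless interiors,
and identical seed + configuration reproduce the volume bit for bit.
What phantoms do **not** emulate: anatomical texture, partial-volume
boundaries, intensity inhomogeneity, or inter-annotator disagreement —
passing tests demonstrate the *machinery* (operators, metrics, I/O,
workflow, harness) is exact, not that any particular model segments real
anatomy.

The iterative loop labels its first batch from scratch, then repeatedly
trains on everything corrected so far, drafts the next batch through the
same inference path a real model would use, and corrects the drafts.
Human correction time is not reproducible at desk scale, so the harness
reports **edit cost**, the (voxel, label-bit) count of the symmetric
difference between draft and truth — precisely the voxels a corrector
would flip — and correction is perfect (corrected = truth), modeling the
reviewed-and-approved end state of the multiuser workflow. Iteration 0's
cost is exactly the de-novo cost |truth|. Two degenerate trainers bound
the harness: an oracle trainer (cost 0 after bootstrap) and a null trainer
(cost stuck at de-novo). The default practical trainer is per-voxel
logistic regression on three features (raw slice intensity and Gaussian
smoothings at σ = 1 and 2 voxels), subsampled to ≤ 10k foreground plus an
equal background sample per volume — it trains in well under a second,
needs no deep-learning runtime, and its drafts sharpen as the training
set grows, which is the behavior the loop exists to measure.

Problem sizes used by the test suite and the acceptance script — 32³
phantoms, 20-phantom suites, 4 loop iterations at 3 seeds, 100 round-trip
projects, 1,000 metric pairs — were chosen as the smallest scales at which
every property is exercised meaningfully; all complete in seconds on one
CPU.

## Known limitations

- DICOM is not read or written; imaging enters as NIfTI.
- No network content-management backend; the storage seam is filesystem-only.
- Whole-volume 3-D models are not supported (2-D and 3-D patch-wise only).
- The contour refiner is a percentile-band grower, not a tuned organ
  segmenter; it is the pluggable default, not a claim.
- No surface-distance metrics (Hausdorff etc.); overlap metrics only.
- Workflow models custody only; review verdicts beyond custody transitions
  (approve/reject metadata) are not recorded.
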