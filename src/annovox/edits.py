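"""Manual and semi-automated voxel annotation operators.

All operators mutate a :class:`~annovox.core.LabelVolume` in place and push
a reversible snapshot onto the series' undo stack first, so ``undo`` after
any edit restores the grid, provenance and points bit-exactly.

Paint/erase requests carry an in-slice footprint (brush disc, polygon fill
or explicit voxel set), an optional symmetric cross-slice extent (the edit
is replayed on slices ``z-k .. z+k``, clamped to the volume) and an optional
closed intensity window ``[lo, hi]``: only voxels whose image intensity lies
inside the window are touched.  Threshold-constrained painting is the main
manual tool for tissues whose intensities separate them from surroundings.

Semi-automated edge refinement ("snap contour") replaces a slice's rough
region with the output of a pluggable *refiner*.  The default refiner grows
the 4-connected component around the region centroid among voxels inside
the [p2, p98] percentile band of the currently labeled intensities — a
simple stand-in for dedicated minimal-interaction organ segmentation
algorithms, which can be substituted via the ``refiner`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import LabelVolume, Project, ROIDefinition
from .errors import (
    EmptyRegionError,
    LockedROIError,
    PermissionDeniedError,
    PointNotFoundError,
    ValidationError,
    WrongToolError,
)

__all__ = [
    "EditRequest",
    "EditHistory",
    "apply_edit",
    "flood_fill",
    "morph",
    "add_point",
    "remove_point",
    "undo",
    "redo",
    "snap_contour",
    "auto_contour",
    "percentile_band_refiner",
    "disc_footprint",
]

Refiner = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class EditRequest:
    """One paint or erase stroke."""

    roi: ROIDefinition
    mode: str  # "paint" | "erase"
    footprint: Sequence[tuple[int, int]]  # in-slice (x, y) voxel coordinates
    slice: int
    slice_extent: int = 0  # extend to z +/- k, clamped
    threshold_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("paint", "erase"):
            raise ValidationError(f"mode must be 'paint' or 'erase', got {self.mode!r}")
        if not len(self.footprint):
            raise ValidationError("footprint must be nonempty")
        if self.slice_extent < 0:
            raise ValidationError("slice_extent must be nonnegative")
        if self.threshold_range is not None:
            lo, hi = self.threshold_range
            if lo > hi:
                raise ValidationError(f"threshold range requires lo <= hi, got [{lo}, {hi}]")


def disc_footprint(center: tuple[int, int], radius: int) -> list[tuple[int, int]]:
    """In-slice brush disc: voxels within Euclidean ``radius`` of ``center``."""
    cx, cy = center
    pts = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                pts.append((cx + dx, cy + dy))
    return pts


class EditHistory:
    """Per-series undo/redo stacks of full label-state snapshots.

    Snapshots are cheap at annotation scale (a 256^3 uint64 grid is a few
    MB) and make undo trivially exact.  ``capacity`` bounds the undo depth;
    the stacks live in memory and are cleared on version commit.
    """

    def __init__(self, capacity: int = 100):
        if capacity < 1:
            raise ValidationError("history capacity must be >= 1")
        self.capacity = capacity
        self.undo_stack: list[LabelVolume] = []
        self.redo_stack: list[LabelVolume] = []

    def record(self, volume: LabelVolume) -> None:
        """Push the pre-edit state; called by every mutating operator."""
        self.undo_stack.append(volume.copy())
        if len(self.undo_stack) > self.capacity:
            self.undo_stack.pop(0)
        self.redo_stack.clear()

    def clear(self) -> None:
        self.undo_stack.clear()
        self.redo_stack.clear()


def _history(project: Project, series_id: Optional[str]) -> Optional[EditHistory]:
    if project is None or series_id is None:
        return None
    hist = project.histories.get(series_id)
    if hist is None:
        hist = EditHistory()
        project.histories[series_id] = hist
    return hist


def _restore(volume: LabelVolume, snapshot: LabelVolume) -> None:
    volume.labels[...] = snapshot.labels
    volume.provenance = dict(snapshot.provenance)
    volume.points = list(snapshot.points)


def _check_gate(project: Optional[Project], series_id: Optional[str], user: Optional[str]) -> None:
    """Workflow edit gate: when the project runs a multiuser workflow, only
    the series' current owner may mutate its annotations."""
    if project is None or project.workflow is None or series_id is None:
        return
    from . import workflow as _wf

    if not _wf.can_edit(project.workflow, _wf.get_custody(project, series_id), user):
        raise PermissionDeniedError(
            f"user {user!r} does not hold series {series_id!r}; acquire it first"
        )


def _paint_bit(volume: LabelVolume, sel: np.ndarray, bit: int, exclusive: bool) -> None:
    b = np.uint64(bit)
    if exclusive:
        volume.labels[sel] = b  # last write wins: replace any other label
    else:
        volume.labels[sel] |= b


def apply_edit(
    image: np.ndarray,
    volume: LabelVolume,
    request: EditRequest,
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """Apply a paint/erase stroke with threshold and cross-slice extension.

    Voxels touched are the footprint replicated on slices
    ``request.slice - k .. request.slice + k`` (clamped), intersected with
    the intensity window when one is given.  Painting in exclusive mode
    replaces any other ROI's label on the touched voxels.
    """
    roi = request.roi
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    if roi.kind != "area":
        raise WrongToolError(f"ROI {roi.name!r} is a point ROI; use add_point/remove_point")
    _check_gate(project, series_id, user)
    if image.shape != volume.shape:
        raise ValidationError(f"image shape {image.shape} != label shape {volume.shape}")

    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)

    X, Y, Z = volume.shape
    z0 = max(0, request.slice - request.slice_extent)
    z1 = min(Z - 1, request.slice + request.slice_extent)
    exclusive = bool(project.exclusive_mode) if project is not None else False
    fp = [(x, y) for x, y in request.footprint if 0 <= x < X and 0 <= y < Y]
    for z in range(z0, z1 + 1):
        sel = np.zeros((X, Y), dtype=bool)
        for x, y in fp:
            sel[x, y] = True
        if request.threshold_range is not None:
            lo, hi = request.threshold_range
            sel &= (image[:, :, z] >= lo) & (image[:, :, z] <= hi)
        if not sel.any():
            continue
        plane = volume.labels[:, :, z]
        if request.mode == "paint":
            if exclusive:
                plane[sel] = np.uint64(roi.mask_value)
            else:
                plane[sel] |= np.uint64(roi.mask_value)
        else:
            plane[sel] &= ~np.uint64(roi.mask_value)
        volume.provenance[(z, roi.mask_value)] = "manual"
    return volume


def flood_fill(
    image: np.ndarray,
    volume: LabelVolume,
    roi: ROIDefinition,
    seed: tuple[int, int, int],
    threshold_range: Optional[tuple[float, float]] = None,
    connectivity: int = 4,
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """In-slice flood fill from a seed voxel.

    With a threshold window, the fill covers the connected component of the
    seed among in-window voxels of the seed's slice.  Without one, it fills
    the connected unlabeled region (voxels lacking this ROI's bit) around
    the seed — the interior of a drawn boundary.  A seed outside the window
    is a silent no-op, not an error.
    """
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    if roi.kind != "area":
        raise WrongToolError("flood fill applies to area ROIs")
    _check_gate(project, series_id, user)
    x, y, z = seed
    X, Y, Z = volume.shape
    if not (0 <= x < X and 0 <= y < Y and 0 <= z < Z):
        raise ValidationError(f"seed {seed} out of bounds for shape {volume.shape}")
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")

    plane_img = image[:, :, z]
    if threshold_range is not None:
        lo, hi = threshold_range
        candidates = (plane_img >= lo) & (plane_img <= hi)
    else:
        candidates = ~volume.roi_mask(roi.mask_value)[:, :, z]
    if not candidates[x, y]:
        return volume  # empty-fill notice: seed not fillable

    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    comp, _ = ndimage.label(candidates, structure=structure)
    sel = comp == comp[x, y]
    exclusive = bool(project.exclusive_mode) if project is not None else False
    plane = volume.labels[:, :, z]
    if exclusive:
        plane[sel] = np.uint64(roi.mask_value)
    else:
        plane[sel] |= np.uint64(roi.mask_value)
    volume.provenance[(z, roi.mask_value)] = "manual"
    return volume


# smallest standard structuring elements; both configurable per call
_CROSS_2D = ndimage.generate_binary_structure(2, 1)


def morph(
    volume: LabelVolume,
    roi: ROIDefinition,
    op: str,
    iterations: int = 1,
    scope: str = "slice",
    structure: Optional[np.ndarray] = None,
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """Binary dilation/erosion of one ROI's bit plane.

    scope "slice" applies the in-plane 3x3 cross independently per slice;
    scope "volume" uses the 3-D 6-neighborhood.  Other ROIs' bits are never
    touched; in exclusive mode dilation refuses to grow over voxels already
    labeled by another ROI.
    """
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    if op not in ("dilate", "erode"):
        raise ValidationError(f"op must be 'dilate' or 'erode', got {op!r}")
    if scope not in ("slice", "volume"):
        raise ValidationError(f"scope must be 'slice' or 'volume', got {scope!r}")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    _check_gate(project, series_id, user)

    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)

    if structure is None:
        if scope == "slice":
            structure = _CROSS_2D[:, :, None]  # (3, 3, 1): in-plane only
        else:
            structure = ndimage.generate_binary_structure(3, 1)
    mask = volume.roi_mask(roi.mask_value)
    if op == "dilate":
        new_mask = ndimage.binary_dilation(mask, structure=structure, iterations=iterations)
    else:
        # border_value=1 keeps erosion dual to dilation at the volume edge,
        # so opening(X) <= X <= closing(X) holds on the finite grid
        new_mask = ndimage.binary_erosion(
            mask, structure=structure, iterations=iterations, border_value=1
        )

    bit = np.uint64(roi.mask_value)
    if op == "dilate" and project is not None and project.exclusive_mode:
        other = (volume.labels & ~bit) != 0
        new_mask &= ~other | mask  # keep what we had, never take others' voxels
    changed_slices = np.nonzero((new_mask ^ mask).any(axis=(0, 1)))[0]
    volume.labels &= ~bit
    volume.labels |= np.where(new_mask, bit, np.uint64(0))
    for z in changed_slices:
        volume.provenance[(int(z), roi.mask_value)] = "manual"
    return volume


def add_point(
    volume: LabelVolume,
    roi: ROIDefinition,
    coordinate: tuple[int, int, int],
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """Append a point annotation; duplicates on the same coordinate rejected."""
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    if roi.kind != "point":
        raise WrongToolError(f"ROI {roi.name!r} is an area ROI; use paint tools")
    _check_gate(project, series_id, user)
    x, y, z = coordinate
    X, Y, Z = volume.shape
    if not (0 <= x < X and 0 <= y < Y and 0 <= z < Z):
        raise ValidationError(f"point {coordinate} out of bounds for shape {volume.shape}")
    entry = (roi.mask_value, (int(x), int(y), int(z)))
    if entry in volume.points:
        raise ValidationError(f"point {coordinate} already recorded for ROI {roi.name!r}")
    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)
    volume.points.append(entry)
    return volume


def remove_point(
    volume: LabelVolume,
    roi: ROIDefinition,
    coordinate: tuple[int, int, int],
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    if roi.kind != "point":
        raise WrongToolError(f"ROI {roi.name!r} is an area ROI")
    _check_gate(project, series_id, user)
    entry = (roi.mask_value, tuple(int(c) for c in coordinate))
    if entry not in volume.points:
        raise PointNotFoundError(f"no point {coordinate} recorded for ROI {roi.name!r}")
    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)
    volume.points.remove(entry)
    return volume


def undo(project: Project, series_id: str) -> bool:
    """Restore the previous label state; returns False (no-op) on empty stack."""
    hist = _history(project, series_id)
    volume = project.get_labels(series_id)
    if not hist.undo_stack:
        return False
    hist.redo_stack.append(volume.copy())
    _restore(volume, hist.undo_stack.pop())
    return True


def redo(project: Project, series_id: str) -> bool:
    hist = _history(project, series_id)
    volume = project.get_labels(series_id)
    if not hist.redo_stack:
        return False
    hist.undo_stack.append(volume.copy())
    _restore(volume, hist.redo_stack.pop())
    return True


# ---------------------------------------------------------------------------
# semi-automated edge refinement
# ---------------------------------------------------------------------------

def percentile_band_refiner(
    percentiles: tuple[float, float] = (2.0, 98.0),
    max_growth: float = 8.0,
) -> Refiner:
    """Build the default refiner.

    The refiner thresholds the slice to the [p_lo, p_hi] percentile band of
    the intensities currently labeled, then keeps the 4-connected component
    containing the region centroid (falling back to the in-band labeled
    voxel nearest the centroid when the centroid itself is out of band).
    A component larger than ``max_growth`` times the input region is
    treated as a leak into background and yields an empty region.
    """

    def refine(image_slice: np.ndarray, region: np.ndarray) -> np.ndarray:
        empty = np.zeros_like(region)
        n = int(region.sum())
        if n == 0:
            return empty
        vals = image_slice[region]
        lo, hi = np.percentile(vals, percentiles)
        band = (image_slice >= lo) & (image_slice <= hi)
        comp, _ = ndimage.label(band, structure=_CROSS_2D)
        cx, cy = (int(round(c)) for c in np.argwhere(region).mean(axis=0))
        cx = min(max(cx, 0), region.shape[0] - 1)
        cy = min(max(cy, 0), region.shape[1] - 1)
        if band[cx, cy]:
            label = comp[cx, cy]
        else:
            inband = np.argwhere(region & band)
            if len(inband) == 0:
                return empty
            d2 = ((inband - np.array([cx, cy])) ** 2).sum(axis=1)
            px, py = inband[int(np.argmin(d2))]
            label = comp[px, py]
        out = comp == label
        if out.sum() > max_growth * n:
            return empty
        return out

    return refine


def _replace_slice_region(
    volume: LabelVolume, roi: ROIDefinition, z: int, region: np.ndarray, exclusive: bool
) -> None:
    bit = np.uint64(roi.mask_value)
    plane = volume.labels[:, :, z]
    plane &= ~bit
    if exclusive:
        take = region & (plane == 0)
        plane[take] = bit
    else:
        plane[region] |= bit


def snap_contour(
    image: np.ndarray,
    volume: LabelVolume,
    roi: ROIDefinition,
    slice_index: int,
    refiner: Optional[Refiner] = None,
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """Replace a slice's rough ROI region with the refiner's output.

    Provenance: a slice that had never been manually edited for this ROI is
    marked "auto" (rendered in a lighter color downstream); a manually
    edited slice stays "manual".
    """
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    _check_gate(project, series_id, user)
    region = volume.roi_mask(roi.mask_value)[:, :, slice_index]
    if not region.any():
        raise EmptyRegionError(f"ROI {roi.name!r} has no voxels on slice {slice_index}")
    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)
    refiner = refiner or percentile_band_refiner()
    refined = refiner(image[:, :, slice_index], region)
    exclusive = bool(project.exclusive_mode) if project is not None else False
    _replace_slice_region(volume, roi, slice_index, refined, exclusive)
    was_manual = volume.provenance.get((slice_index, roi.mask_value)) == "manual"
    volume.provenance[(slice_index, roi.mask_value)] = "manual" if was_manual else "auto"
    return volume


def auto_contour(
    image: np.ndarray,
    volume: LabelVolume,
    roi: ROIDefinition,
    slice_range: tuple[int, int],
    refiner: Optional[Refiner] = None,
    project: Optional[Project] = None,
    series_id: Optional[str] = None,
    user: Optional[str] = None,
) -> LabelVolume:
    """Propagate snap-contour refinement across a slice range.

    Seeded (already labeled) slices inside the range are refined first;
    refinement then sweeps outward, seeding each unlabeled slice with the
    refined region of its nearest refined neighbor, and stops in a
    direction when a refined region comes back empty or the range bound is
    reached.
    """
    if roi.locked:
        raise LockedROIError(f"ROI {roi.name!r} is locked")
    _check_gate(project, series_id, user)
    z0, z1 = slice_range
    Z = volume.shape[2]
    if not (0 <= z0 <= z1 < Z):
        raise ValidationError(f"invalid slice range {slice_range} for {Z} slices")
    mask = volume.roi_mask(roi.mask_value)
    seeds = [z for z in range(z0, z1 + 1) if mask[:, :, z].any()]
    if not seeds:
        raise EmptyRegionError(f"no labeled seed slice for ROI {roi.name!r} in range {slice_range}")

    hist = _history(project, series_id)
    if hist is not None:
        hist.record(volume)
    refiner = refiner or percentile_band_refiner()
    exclusive = bool(project.exclusive_mode) if project is not None else False
    refined: dict[int, np.ndarray] = {}

    def has_contrast(z: int, region: np.ndarray) -> bool:
        """Seeded-region contrast gate for propagated slices: once the object
        vanishes, the copied region no longer stands out from its ring of
        surrounding voxels, and propagation must stop."""
        ring = ndimage.binary_dilation(region, _CROSS_2D, iterations=2) & ~region
        if not ring.any():
            return True
        plane = image[:, :, z]
        inside, outside = plane[region], plane[ring]
        spread = max(float(inside.std()), float(outside.std()), 1e-9)
        return abs(float(inside.mean()) - float(outside.mean())) > spread

    def refine_slice(z: int, region: np.ndarray) -> np.ndarray:
        out = refiner(image[:, :, z], region)
        _replace_slice_region(volume, roi, z, out, exclusive)
        if out.any():
            was_manual = volume.provenance.get((z, roi.mask_value)) == "manual"
            volume.provenance[(z, roi.mask_value)] = "manual" if was_manual else "auto"
        refined[z] = out
        return out

    seed_set = set(seeds)
    for z in seeds:
        refine_slice(z, volume.roi_mask(roi.mask_value)[:, :, z])
    # ascending sweep, then descending: each unlabeled slice seeded from its
    # refined neighbor; an empty refinement stops that direction until the
    # next seeded slice restarts it
    for order in (range(z0, z1 + 1), range(z1, z0 - 1, -1)):
        prev: Optional[np.ndarray] = None
        for z in order:
            if z in seed_set:
                prev = refined[z] if refined[z].any() else None
            elif z in refined:
                prev = refined[z] if refined[z].any() else None
            elif prev is not None:
                if not has_contrast(z, prev):
                    refined[z] = np.zeros_like(prev)
                    prev = None
                    continue
                out = refine_slice(z, prev)
                prev = out if out.any() else None
    return volume
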