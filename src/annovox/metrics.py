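"""Descriptive ROI statistics and segmentation agreement metrics.

Agreement between a reference segmentation A and a prediction B is measured
per slice and per volume with the two standard overlap coefficients

    Dice    D = 2|A ∩ B| / (|A| + |B|)
    Jaccard J = |A ∩ B| / |A ∪ B|      (J = D / (2 − D))

computed on a single ROI's bit plane.  The volume summary pools the voxels
of the selected slices (it is not the mean of per-slice values), so slices
with tiny regions do not dominate.  A slice where both masks are empty is
vacuously perfect: it reports 1.0 and carries a ``both_empty`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import LabelVolume, ROIDefinition
from .errors import ShapeMismatchError, ValidationError

__all__ = ["ROIStats", "AgreementReport", "roi_statistics", "agreement", "dice_jaccard"]

HISTOGRAM_BINS = 64


@dataclass
class ROIStats:
    """Descriptive statistics of the image intensities under one ROI.

    ``physical_volume`` is voxel_count times the voxel volume, where voxel
    volume is |det| of the 3x3 block of the affine (mm^3 for a standard
    NIfTI affine).  Moments are None when the ROI is empty in scope.
    """

    scope: str
    voxel_count: int
    physical_volume: float
    mean: Optional[float]
    std: Optional[float]
    min: Optional[float]
    max: Optional[float]
    histogram: Optional[tuple[np.ndarray, np.ndarray]]  # (counts, bin_edges)
    empty: bool = False


@dataclass
class AgreementReport:
    per_slice: list[tuple[int, float, float]]  # (slice, dice, jaccard)
    volume_dice: float
    volume_jaccard: float
    flags: dict = field(default_factory=dict)  # e.g. {"both_empty_slices": [...]}


def dice_jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Dice and Jaccard of two boolean arrays; both-empty reports (1, 1, True)."""
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0, True
    inter = int((a & b).sum())
    union = na + nb - inter
    return 2.0 * inter / (na + nb), inter / union, False


def roi_statistics(
    image: np.ndarray,
    volume: LabelVolume,
    roi: ROIDefinition,
    scope: str = "volume",
    slice_index: Optional[int] = None,
) -> ROIStats:
    """Statistics over intensities of voxels carrying the ROI bit.

    scope "slice" restricts to one z slice (``slice_index`` required);
    histogram uses 64 equal-width bins over the observed [min, max].
    """
    if scope not in ("slice", "volume"):
        raise ValidationError(f"scope must be 'slice' or 'volume', got {scope!r}")
    if scope == "slice" and slice_index is None:
        raise ValidationError("slice scope requires a slice index")
    if image.shape != volume.shape:
        raise ShapeMismatchError(f"image {image.shape} vs labels {volume.shape}")
    mask = volume.roi_mask(roi.mask_value)
    if scope == "slice":
        sel = np.zeros_like(mask)
        sel[:, :, slice_index] = mask[:, :, slice_index]
        mask = sel
    vals = np.asarray(image)[mask]
    voxel_vol = abs(float(np.linalg.det(volume.affine[:3, :3])))
    n = int(vals.size)
    if n == 0:
        return ROIStats(scope, 0, 0.0, None, None, None, None, None, empty=True)
    vmin, vmax = float(vals.min()), float(vals.max())
    counts, edges = np.histogram(vals, bins=HISTOGRAM_BINS, range=(vmin, vmax) if vmax > vmin else (vmin, vmin + 1))
    return ROIStats(
        scope=scope,
        voxel_count=n,
        physical_volume=n * voxel_vol,
        mean=float(vals.mean()),
        std=float(vals.std(ddof=0)),
        min=vmin,
        max=vmax,
        histogram=(counts, edges),
    )


def agreement(
    reference: LabelVolume,
    prediction: LabelVolume,
    roi: ROIDefinition,
    slices: Optional[Sequence[int]] = None,
) -> AgreementReport:
    """Per-slice and pooled-volume Dice/Jaccard for one ROI.

    ``slices`` defaults to every slice.  The volume metric pools all voxels
    of the selected slices into one pair of sets.
    """
    if reference.shape != prediction.shape:
        raise ShapeMismatchError(
            f"reference {reference.shape} vs prediction {prediction.shape}"
        )
    Z = reference.shape[2]
    if slices is None:
        slices = range(Z)
    slices = [int(z) for z in slices]
    if any(z < 0 or z >= Z for z in slices):
        raise ValidationError(f"slice selection out of range 0..{Z - 1}")

    ref_mask = reference.roi_mask(roi.mask_value)
    pred_mask = prediction.roi_mask(roi.mask_value)
    per_slice = []
    both_empty = []
    for z in slices:
        d, j, empty = dice_jaccard(ref_mask[:, :, z], pred_mask[:, :, z])
        per_slice.append((z, d, j))
        if empty:
            both_empty.append(z)
    sel = np.zeros(Z, dtype=bool)
    sel[slices] = True
    vd, vj, vempty = dice_jaccard(ref_mask[:, :, sel], pred_mask[:, :, sel])
    flags = {}
    if both_empty:
        flags["both_empty_slices"] = both_empty
    if vempty:
        flags["both_empty_volume"] = True
    return AgreementReport(per_slice=per_slice, volume_dice=vd, volume_jaccard=vj, flags=flags)
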