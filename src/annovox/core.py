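"""Project-level annotation data model.

A :class:`Project` fixes the annotation *schema* for an entire imaging
dataset: the table of region-of-interest (ROI) definitions, the text
annotation fields, and the one-label-per-voxel (exclusive) switch.  Every
series in the dataset labels voxels against the same schema, which is what
makes annotations comparable across the dataset and usable as deep-learning
training targets.

Voxel labels are stored as a multi-label bitmask grid (:class:`LabelVolume`):
each ROI owns one bit (its ``mask_value``, a power of two) and a voxel's
stored integer is the bitwise OR of the ROIs labeling it.  A voxel may carry
several bits (e.g. both "kidney" and "tumor") unless the project is in
exclusive mode.  Bits are allocated lowest-first and never recycled, so a
deleted ROI can never silently alias an old grid.

Annotation data (labels, points, text values, versions) lives apart from
the source imaging; source NIfTI files are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    SchemaError,
    UnknownFieldError,
    UnknownROIError,
    ValidationError,
)

MAX_ROI_BITS = 64  # one export word

__all__ = [
    "ROIDefinition",
    "TextFieldDefinition",
    "SeriesRecord",
    "LabelVolume",
    "Project",
    "define_roi",
    "delete_roi",
    "rename_roi",
    "set_roi_color",
    "set_roi_locked",
    "add_text_field",
    "set_text_value",
    "list_series",
    "set_exclusive_mode",
    "series_edited",
]

# fixed palette cycled through when the caller does not pick a color
_PALETTE = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
]


@dataclass
class ROIDefinition:
    """One dataset-level region-of-interest definition.

    ``mask_value`` is the ROI's bit in every label grid of the project —
    always a power of two, unique within the project, and immutable:
    name, RadLex ID and color may be edited freely without touching any
    stored label grid.
    """

    name: str
    mask_value: int
    radlex_id: Optional[str] = None
    color: tuple[int, int, int] = (255, 0, 0)
    kind: str = "area"  # "area" | "point"
    locked: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("area", "point"):
            raise ValidationError(f"ROI kind must be 'area' or 'point', got {self.kind!r}")
        mv = int(self.mask_value)
        if mv <= 0 or mv & (mv - 1):
            raise SchemaError(f"mask_value must be a positive power of two, got {mv}")
        if len(self.color) != 3 or any(not (0 <= c <= 255) for c in self.color):
            raise ValidationError(f"color must be an RGB triple in 0..255, got {self.color!r}")


@dataclass
class TextFieldDefinition:
    """A named text annotation field; ``allowed_values=None`` means free text."""

    name: str
    allowed_values: Optional[list[str]] = None


@dataclass
class SeriesRecord:
    """One imaging series (a single acquisition volume) within the project.

    ``hierarchy_key`` orders series in the Patient -> Study -> Series
    hierarchy and doubles as the mirrored relative path used when masks
    are exported.  ``metadata`` holds read-only values attached from a
    secondary CSV.
    """

    series_id: str
    source_path: Optional[str] = None
    hierarchy_key: tuple[str, ...] = ()
    owner: Optional[str] = None
    locked: bool = False
    text_values: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)


class LabelVolume:
    """Per-voxel multi-label bitmask grid aligned to a source volume.

    Parameters
    ----------
    shape
        ``(X, Y, Z)`` voxel counts, identical to the source data grid.
    affine
        4x4 voxel-to-world transform, copied exactly from the source
        NIfTI so exported masks overlay the imaging.

    Attributes
    ----------
    labels : ndarray of uint64
        ``labels[x, y, z]`` is the bitwise OR of the mask_values of every
        ROI labeling that voxel.
    provenance : dict
        ``(z_slice, mask_value) -> "manual" | "auto"`` recording whether a
        slice's ROI labels were human-edited or wholly machine-generated
        (machine-generated slices render in a lighter ROI color downstream).
    points : list
        Point annotations as ``(mask_value, (x, y, z))`` tuples.
    """

    def __init__(self, shape: Sequence[int], affine: Optional[np.ndarray] = None):
        shape = tuple(int(s) for s in shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValidationError(f"LabelVolume shape must be a positive (X, Y, Z), got {shape}")
        self.labels = np.zeros(shape, dtype=np.uint64)
        self.affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float).copy()
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        self.provenance: dict[tuple[int, int], str] = {}
        self.points: list[tuple[int, tuple[int, int, int]]] = []

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_mask(self, mask_value: int) -> np.ndarray:
        """Boolean grid of voxels carrying this ROI's bit."""
        return (self.labels & np.uint64(mask_value)) != 0

    def is_empty(self) -> bool:
        return not self.labels.any() and not self.points

    def copy(self) -> "LabelVolume":
        dup = LabelVolume(self.shape, self.affine)
        dup.labels = self.labels.copy()
        dup.provenance = dict(self.provenance)
        dup.points = list(self.points)
        return dup

    def state_equal(self, other: "LabelVolume") -> bool:
        return (
            np.array_equal(self.labels, other.labels)
            and self.provenance == other.provenance
            and self.points == other.points
        )


@dataclass
class Project:
    """A dataset annotation project: schema + series + annotation storage."""

    roi_table: list[ROIDefinition] = field(default_factory=list)
    text_fields: list[TextFieldDefinition] = field(default_factory=list)
    series: list[SeriesRecord] = field(default_factory=list)
    exclusive_mode: bool = False
    annotation_store: Optional[str] = None
    workflow: Optional[object] = None  # WorkflowSpec, attached by annovox.workflow
    # series_id -> LabelVolume (the working annotation state)
    labels: dict[str, LabelVolume] = field(default_factory=dict)
    # series_id -> list[VersionEntry] (append-only history, annovox.io)
    versions: dict[str, list] = field(default_factory=dict)
    # series_id -> EditHistory (annovox.edits); in-memory undo/redo stacks
    histories: dict[str, object] = field(default_factory=dict)
    # series_id -> SeriesCustody (annovox.workflow); pool/owner state
    custody: dict[str, object] = field(default_factory=dict)
    # bits ever allocated; never shrinks, so deleted ROIs' bits are not reused
    _allocated_bits: set[int] = field(default_factory=set)

    # -- lookups ---------------------------------------------------------
    def get_roi(self, name: str) -> ROIDefinition:
        for roi in self.roi_table:
            if roi.name == name:
                return roi
        raise UnknownROIError(f"ROI {name!r} is not defined in this project")

    def roi_by_mask_value(self, mask_value: int) -> ROIDefinition:
        for roi in self.roi_table:
            if roi.mask_value == mask_value:
                return roi
        raise UnknownROIError(f"no ROI with mask_value {mask_value}")

    def get_field(self, name: str) -> TextFieldDefinition:
        for f in self.text_fields:
            if f.name == name:
                return f
        raise UnknownFieldError(f"text field {name!r} is not defined")

    def get_series(self, series_id: str) -> SeriesRecord:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise UnknownFieldError(f"series {series_id!r} not found")

    def add_series(self, record: SeriesRecord) -> SeriesRecord:
        if any(s.series_id == record.series_id for s in self.series):
            raise SchemaError(f"series id {record.series_id!r} already present")
        self.series.append(record)
        return record

    def get_labels(self, series_id: str) -> LabelVolume:
        self.get_series(series_id)
        if series_id not in self.labels:
            raise UnknownFieldError(f"series {series_id!r} has no label volume attached")
        return self.labels[series_id]

    def attach_labels(self, series_id: str, volume: LabelVolume) -> None:
        self.get_series(series_id)
        self.labels[series_id] = volume

    def defined_bits(self) -> int:
        word = 0
        for roi in self.roi_table:
            word |= roi.mask_value
        return word


# ---------------------------------------------------------------------------
# schema operations
# ---------------------------------------------------------------------------

def define_roi(
    project: Project,
    name: str,
    radlex_id: Optional[str] = None,
    color: Optional[tuple[int, int, int]] = None,
    kind: str = "area",
) -> ROIDefinition:
    """Add a new ROI to the project schema.

    The new ROI receives the lowest power-of-two ``mask_value`` never used
    before in this project (bits are not recycled after deletion).  At most
    64 bits are ever allocated, the width of one exported mask word.
    """
    if any(r.name == name for r in project.roi_table):
        raise SchemaError(f"ROI name {name!r} already in use (names are case-sensitive)")
    bit = next((1 << k for k in range(MAX_ROI_BITS) if (1 << k) not in project._allocated_bits), None)
    if bit is None:
        raise CapacityError(
            f"all {MAX_ROI_BITS} mask bits of one export word are allocated; "
            "split the project to export further ROIs"
        )
    if color is None:
        color = _PALETTE[len(project._allocated_bits) % len(_PALETTE)]
    roi = ROIDefinition(name=name, mask_value=bit, radlex_id=radlex_id, color=tuple(color), kind=kind)
    project.roi_table.append(roi)
    project._allocated_bits.add(bit)
    return roi


def delete_roi(project: Project, name: str, force: bool = False) -> None:
    """Remove an ROI definition; refuses if voxels still carry its bit.

    With ``force=True`` the bit is cleared from every attached label grid
    first.  The mask_value is never reissued either way.
    """
    roi = project.get_roi(name)
    bit = np.uint64(roi.mask_value)
    labeled = any((vol.labels & bit).any() or any(mv == roi.mask_value for mv, _ in vol.points)
                  for vol in project.labels.values())
    if labeled and not force:
        raise ValidationError(
            f"ROI {name!r} still labels voxels; pass force=True to delete and clear them"
        )
    if labeled:
        for vol in project.labels.values():
            vol.labels &= ~bit
            vol.points = [p for p in vol.points if p[0] != roi.mask_value]
            vol.provenance = {k: v for k, v in vol.provenance.items() if k[1] != roi.mask_value}
    project.roi_table.remove(roi)


def rename_roi(project: Project, name: str, new_name: str) -> ROIDefinition:
    """Rename an ROI; never touches mask_value or any label grid."""
    if any(r.name == new_name for r in project.roi_table):
        raise SchemaError(f"ROI name {new_name!r} already in use")
    roi = project.get_roi(name)
    roi.name = new_name
    return roi


def set_roi_color(project: Project, name: str, color: tuple[int, int, int]) -> ROIDefinition:
    roi = project.get_roi(name)
    if len(color) != 3 or any(not (0 <= c <= 255) for c in color):
        raise ValidationError(f"color must be an RGB triple in 0..255, got {color!r}")
    roi.color = tuple(color)
    return roi


def set_roi_locked(project: Project, name: str, flag: bool) -> ROIDefinition:
    """Lock/unlock an ROI against manual, semi-automated and model edits."""
    roi = project.get_roi(name)
    roi.locked = bool(flag)
    return roi


def add_text_field(
    project: Project, name: str, allowed_values: Optional[Iterable[str]] = None
) -> TextFieldDefinition:
    if any(f.name == name for f in project.text_fields):
        raise SchemaError(f"text field {name!r} already defined")
    fdef = TextFieldDefinition(name=name, allowed_values=list(allowed_values) if allowed_values is not None else None)
    project.text_fields.append(fdef)
    return fdef


def set_text_value(project: Project, series_id: str, field_name: str, value: str) -> SeriesRecord:
    """Store a text annotation, validating restricted fields."""
    fdef = project.get_field(field_name)
    record = project.get_series(series_id)
    if fdef.allowed_values is not None and value not in fdef.allowed_values:
        raise ValidationError(
            f"{value!r} not in allowed values {fdef.allowed_values} for field {field_name!r}"
        )
    record.text_values[field_name] = value
    return record


def series_edited(project: Project, series_id: str) -> bool:
    """True iff the series has any nonempty annotation content (current or versioned)."""
    record = project.get_series(series_id)
    vol = project.labels.get(series_id)
    if vol is not None and not vol.is_empty():
        return True
    for entry in project.versions.get(series_id, []):
        snap = entry.snapshot
        if snap["labels"].any() or snap["points"]:
            return True
    return bool(record.text_values)


def list_series(project: Project, columns: Sequence[str] = ()) -> pd.DataFrame:
    """Tabulate series in hierarchy order with edited flags and text columns.

    ``columns`` may name defined text fields or attached-metadata columns;
    missing values render as empty strings.
    """
    defined = {f.name for f in project.text_fields}
    meta_cols = set()
    for s in project.series:
        meta_cols.update(s.metadata)
    for col in columns:
        if col not in defined and col not in meta_cols:
            raise UnknownFieldError(f"unknown column {col!r}")
    ordered = sorted(project.series, key=lambda s: (s.hierarchy_key, s.series_id))
    rows = []
    for s in ordered:
        row = {"series_id": s.series_id, "edited": series_edited(project, s.series_id)}
        for col in columns:
            row[col] = s.text_values.get(col, s.metadata.get(col, ""))
        rows.append(row)
    return pd.DataFrame(rows, columns=["series_id", "edited", *columns])


def set_exclusive_mode(project: Project, flag: bool) -> None:
    """Toggle one-ROI-per-voxel enforcement.

    Turning it on is refused while any voxel carries more than one label —
    collapsing labels silently would lose data.
    """
    if flag and not project.exclusive_mode:
        for sid, vol in project.labels.items():
            multi = _popcount(vol.labels) > 1
            if multi.any():
                n = int(multi.sum())
                raise ValidationError(
                    f"cannot enable exclusive mode: series {sid!r} has {n} voxels with multiple labels"
                )
    project.exclusive_mode = bool(flag)


def _popcount(labels: np.ndarray) -> np.ndarray:
    """Per-voxel number of set bits in a uint64 grid."""
    out = np.zeros(labels.shape, dtype=np.uint8)
    work = labels.copy()
    while work.any():
        out += (work & np.uint64(1)).astype(np.uint8)
        work >>= np.uint64(1)
    return out


def validate_project(project: Project) -> None:
    """Assert the project-wide invariants; raises SchemaError on violation."""
    names = [r.name for r in project.roi_table]
    if len(names) != len(set(names)):
        raise SchemaError("duplicate ROI names")
    bits = [r.mask_value for r in project.roi_table]
    if len(bits) != len(set(bits)):
        raise SchemaError("duplicate mask_values")
    word = np.uint64(project.defined_bits())
    for sid, vol in project.labels.items():
        if (vol.labels & ~word).any():
            raise SchemaError(f"series {sid!r} labels carry undefined bits")
        if project.exclusive_mode and (_popcount(vol.labels) > 1).any():
            raise SchemaError(f"series {sid!r} violates exclusive mode")
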