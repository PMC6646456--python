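"""Reading source volumes and persisting annotations independently of imaging.

Contracts enforced here:

* Source imaging is never modified — annotation metadata lives in a
  separate annotation store, and mask export writes new files into a
  destination hierarchy that mirrors the dataset hierarchy.
* Exported masks are NIfTI volumes whose affine equals the source affine
  exactly, so they overlay the imaging in any viewer.
* A combined mask encodes overlapping ROIs as the bitwise OR of their
  mask values; a sidecar CSV maps ``roi_name, radlex_id, mask_value`` so
  the mask can be decoded without the project file.
* Version history is append-only: rolling back creates a new version whose
  content is the old snapshot; history is never rewritten.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import os
import shutil
import warnings
from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    LabelVolume,
    Project,
    ROIDefinition,
    SeriesRecord,
    TextFieldDefinition,
)
from .errors import (
    CapacityError,
    ShapeMismatchError,
    UnknownLabelError,
    UnknownROIError,
    UnsupportedShapeError,
    ValidationError,
    VersionNotFoundError,
)
from .metrics import roi_statistics

__all__ = [
    "MaskExportOptions",
    "VersionEntry",
    "load_volume",
    "save_volume",
    "export_masks",
    "import_masks",
    "export_tables",
    "attach_metadata_csv",
    "commit_version",
    "history",
    "rollback",
    "file_checksum",
    "save_project",
    "load_project",
    "save_annotations",
    "load_annotations",
]

SIDECAR_COLUMNS = ["roi_name", "radlex_id", "mask_value"]


@dataclass
class MaskExportOptions:
    destination_root: str
    combine_overlaps: bool = True  # single file, bitwise-OR encoding
    include_source_copy: bool = False
    include_annotation_file: bool = False


@dataclass
class VersionEntry:
    """One annotation version: an immutable snapshot plus audit fields."""

    version_id: int
    user: str
    timestamp: str
    note: str
    snapshot: dict = field(repr=False, default_factory=dict)
    digest: str = ""


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def load_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D NIfTI volume; returns (data, affine) untouched.

    No resampling or reorientation is performed and the file is opened
    read-only: annotation never alters image data files.
    """
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValidationError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise UnsupportedShapeError(
            f"{path!r} is {data.ndim}-D; only 3-D volumes are supported"
        )
    return data, np.asarray(img.affine, dtype=float)


def save_volume(path: str, data: np.ndarray, affine: np.ndarray) -> str:
    """Write a NIfTI volume (helper for phantoms and mask export)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), path)
    return path


def _mask_dtype(highest_bit: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if highest_bit <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise CapacityError("mask bits exceed 64-bit export word")


def _series_dir(root: str, record: SeriesRecord) -> str:
    parts = record.hierarchy_key if record.hierarchy_key else (record.series_id,)
    return os.path.join(root, *parts)


# ---------------------------------------------------------------------------
# mask export / import
# ---------------------------------------------------------------------------

def export_masks(project: Project, series_id: str, options: MaskExportOptions) -> dict:
    """Export a series' voxel annotations as NIfTI mask(s) plus sidecar CSV.

    Combined mode writes one file whose voxel values are the bitwise OR of
    the mask values of all ROIs labeling each voxel; per-ROI mode writes
    one binary file per ROI with values {0, mask_value}.  Returns a dict
    with the written paths.
    """
    record = project.get_series(series_id)
    volume = project.get_labels(series_id)
    if volume.is_empty():
        raise ValidationError(f"series {series_id!r} has no annotations to export")

    out_dir = _series_dir(options.destination_root, record)
    os.makedirs(out_dir, exist_ok=True)
    present_bits = [r.mask_value for r in project.roi_table if volume.roi_mask(r.mask_value).any()]
    written = {"masks": [], "sidecar": None, "source_copy": None, "annotation_file": None}

    if options.combine_overlaps:
        if len(project.roi_table) > 64:
            raise CapacityError("more than 64 ROIs cannot share one combined mask word")
        highest = max(present_bits, default=1)
        data = volume.labels.astype(_mask_dtype(highest))
        path = os.path.join(out_dir, f"{record.series_id}_mask.nii.gz")
        save_volume(path, data, volume.affine)
        written["masks"].append(path)
    else:
        for roi in project.roi_table:
            mask = volume.roi_mask(roi.mask_value)
            if not mask.any():
                continue
            data = np.where(mask, roi.mask_value, 0).astype(_mask_dtype(roi.mask_value))
            path = os.path.join(out_dir, f"{record.series_id}_mask_{roi.name}.nii.gz")
            save_volume(path, data, volume.affine)
            written["masks"].append(path)

    sidecar = os.path.join(out_dir, f"{record.series_id}_mask_mapping.csv")
    rows = [
        {"roi_name": r.name, "radlex_id": r.radlex_id or "", "mask_value": r.mask_value}
        for r in project.roi_table
    ]
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(sidecar, index=False)
    written["sidecar"] = sidecar

    if options.include_source_copy and record.source_path:
        dst = os.path.join(out_dir, os.path.basename(record.source_path))
        shutil.copy2(record.source_path, dst)
        written["source_copy"] = dst
    if options.include_annotation_file:
        ann = os.path.join(out_dir, f"{record.series_id}_annotations.yaml")
        with open(ann, "w") as fh:
            yaml.safe_dump(_annotation_header(record, volume), fh, sort_keys=False)
        written["annotation_file"] = ann
    return written


def read_sidecar(path: str) -> dict[str, int]:
    """Read a sidecar mapping CSV into ``{roi_name: mask_value}``."""
    df = pd.read_csv(path)
    missing = [c for c in ("roi_name", "mask_value") if c not in df.columns]
    if missing:
        raise ValidationError(f"sidecar {path!r} missing columns {missing}")
    return {str(r.roi_name): int(r.mask_value) for r in df.itertuples()}


def import_masks(
    path: str,
    mapping: dict[str, int],
    project: Project,
    series_id: str,
) -> LabelVolume:
    """Decode a mask NIfTI into the series' label grid.

    ``mapping`` maps ROI names to the bit values used *in the file*; each
    named ROI must be defined in the project (imported voxels receive the
    project's bit for that name).  A voxel value containing a bit absent
    from the mapping is an unknown-label error.  Export followed by import
    is the identity on label grids.
    """
    record = project.get_series(series_id)
    data, affine = load_volume(path)
    existing = project.labels.get(series_id)
    if existing is not None and tuple(data.shape) != existing.shape:
        raise ShapeMismatchError(
            f"mask shape {data.shape} != series shape {existing.shape}"
        )

    mapped_word = 0
    bit_to_target: dict[int, int] = {}
    for name, file_bit in mapping.items():
        file_bit = int(file_bit)
        if file_bit <= 0 or file_bit & (file_bit - 1):
            raise ValidationError(f"mapping value {file_bit} for {name!r} is not a power of two")
        try:
            roi = project.get_roi(name)
        except UnknownROIError as exc:
            raise UnknownROIError(
                f"mask value {file_bit} maps to ROI {name!r} which is not defined in the project"
            ) from exc
        mapped_word |= file_bit
        bit_to_target[file_bit] = roi.mask_value

    values = data.astype(np.uint64)
    unknown = values & ~np.uint64(mapped_word)
    if unknown.any():
        bad = int(np.unique(unknown[unknown != 0])[0])
        raise UnknownLabelError(
            f"mask contains value bits {bad} not covered by the sidecar mapping"
        )

    volume = existing if existing is not None else LabelVolume(data.shape, affine)
    for file_bit, target_bit in bit_to_target.items():
        sel = (values & np.uint64(file_bit)) != 0
        volume.labels[sel] |= np.uint64(target_bit)
        for z in np.nonzero(sel.any(axis=(0, 1)))[0]:
            volume.provenance[(int(z), target_bit)] = "manual"
    project.labels[series_id] = volume
    return volume


# ---------------------------------------------------------------------------
# tabular exports and secondary metadata
# ---------------------------------------------------------------------------

def export_tables(
    project: Project,
    what: str,
    fmt: str,
    path: str,
    images: Optional[dict[str, np.ndarray]] = None,
) -> str:
    """Export descriptive-statistics or text-annotation tables (CSV/XLSX).

    stats: one row per (series, ROI) with volume-scope ROI statistics;
    text: one row per series, one column per defined text field.
    """
    if what not in ("stats", "text"):
        raise ValidationError("what must be 'stats' or 'text'")
    if fmt not in ("csv", "xlsx"):
        raise ValidationError("format must be 'csv' or 'xlsx'")
    if not project.series:
        raise ValidationError("project has no series")

    if what == "text":
        cols = [f.name for f in project.text_fields]
        rows = [
            {"series_id": s.series_id, **{c: s.text_values.get(c, "") for c in cols}}
            for s in sorted(project.series, key=lambda s: (s.hierarchy_key, s.series_id))
        ]
        df = pd.DataFrame(rows, columns=["series_id", *cols])
    else:
        rows = []
        for s in sorted(project.series, key=lambda s: (s.hierarchy_key, s.series_id)):
            vol = project.labels.get(s.series_id)
            if vol is None:
                continue
            if images is not None and s.series_id in images:
                img = images[s.series_id]
            elif s.source_path:
                img, _ = load_volume(s.source_path)
            else:
                continue
            for roi in project.roi_table:
                st = roi_statistics(img, vol, roi, scope="volume")
                rows.append(
                    {
                        "series_id": s.series_id,
                        "roi": roi.name,
                        "voxel_count": st.voxel_count,
                        "physical_volume_mm3": st.physical_volume,
                        "mean": st.mean,
                        "std": st.std,
                        "min": st.min,
                        "max": st.max,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=[
                "series_id", "roi", "voxel_count", "physical_volume_mm3",
                "mean", "std", "min", "max",
            ],
        )

    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    if fmt == "csv":
        df.to_csv(path, index=False)
    else:
        df.to_excel(path, index=False)
    return path


def attach_metadata_csv(project: Project, csv_path: str, id_column: str = "series_id") -> dict:
    """Attach a secondary CSV of per-series metadata as read-only columns.

    Returns a report ``{"matched": [...], "unmatched": [...]}`` where
    unmatched lists CSV identifiers with no corresponding series.
    """
    df = pd.read_csv(csv_path, dtype=str)
    if len(df) == 0:
        warnings.warn(f"metadata CSV {csv_path!r} has no rows; nothing attached")
        return {"matched": [], "unmatched": []}
    if id_column not in df.columns:
        raise ValidationError(f"metadata CSV lacks identifier column {id_column!r}")
    dupes = df[id_column][df[id_column].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate identifier rows in metadata CSV: {sorted(set(dupes))}")

    known = {s.series_id: s for s in project.series}
    matched, unmatched = [], []
    for _, row in df.iterrows():
        sid = row[id_column]
        if sid in known:
            values = {c: ("" if pd.isna(row[c]) else str(row[c])) for c in df.columns if c != id_column}
            known[sid].metadata.update(values)
            matched.append(sid)
        else:
            unmatched.append(sid)
    return {"matched": matched, "unmatched": unmatched}


# ---------------------------------------------------------------------------
# versioning
# ---------------------------------------------------------------------------

def _snapshot(project: Project, series_id: str) -> dict:
    record = project.get_series(series_id)
    vol = project.labels.get(series_id)
    if vol is None:
        vol = LabelVolume((1, 1, 1))
    return {
        "labels": vol.labels.copy(),
        "affine": vol.affine.copy(),
        "points": list(vol.points),
        "provenance": dict(vol.provenance),
        "text_values": dict(record.text_values),
    }


def _digest(snapshot: dict) -> str:
    h = hashlib.sha256()
    h.update(snapshot["labels"].tobytes())
    h.update(repr(sorted(snapshot["points"])).encode())
    h.update(repr(sorted(snapshot["provenance"].items())).encode())
    h.update(repr(sorted(snapshot["text_values"].items())).encode())
    return h.hexdigest()


def commit_version(project: Project, series_id: str, user: str, note: str = "") -> VersionEntry:
    """Snapshot the series' current annotation state as a new version.

    Commits also clear the in-memory undo/redo stacks: undo never crosses a
    version boundary.
    """
    project.get_series(series_id)
    if series_id not in project.versions and project.annotation_store:
        _load_versions(project, series_id)
    entries = project.versions.setdefault(series_id, [])
    snap = _snapshot(project, series_id)
    entry = VersionEntry(
        version_id=len(entries) + 1,
        user=user,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        note=note,
        snapshot=snap,
        digest=_digest(snap),
    )
    entries.append(entry)
    hist = project.histories.get(series_id)
    if hist is not None:
        hist.clear()
    if project.annotation_store:
        _persist_version(project, series_id, entry)
    return entry


def _versions_dir(project: Project, series_id: str) -> str:
    record = project.get_series(series_id)
    return os.path.join(_series_dir(project.annotation_store, record), "versions")


def _persist_version(project: Project, series_id: str, entry: VersionEntry) -> None:
    vdir = _versions_dir(project, series_id)
    os.makedirs(vdir, exist_ok=True)
    snap = entry.snapshot
    np.savez_compressed(
        os.path.join(vdir, f"v{entry.version_id}.npz"),
        labels=snap["labels"], affine=snap["affine"],
    )
    meta_path = os.path.join(vdir, "versions.yaml")
    meta = []
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or []
    meta.append(
        {
            "version_id": entry.version_id,
            "user": entry.user,
            "timestamp": entry.timestamp,
            "note": entry.note,
            "digest": entry.digest,
            "points": [[int(mv), list(map(int, xyz))] for mv, xyz in snap["points"]],
            "provenance": [[int(z), int(mv), who] for (z, mv), who in sorted(snap["provenance"].items())],
            "text_values": dict(snap["text_values"]),
        }
    )
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _load_versions(project: Project, series_id: str) -> None:
    vdir = _versions_dir(project, series_id)
    meta_path = os.path.join(vdir, "versions.yaml")
    if not os.path.exists(meta_path):
        return
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or []
    entries = []
    for m in meta:
        with np.load(os.path.join(vdir, f"v{m['version_id']}.npz")) as z:
            labels = z["labels"].astype(np.uint64)
            affine = z["affine"]
        entries.append(
            VersionEntry(
                version_id=int(m["version_id"]),
                user=m["user"],
                timestamp=m["timestamp"],
                note=m.get("note", ""),
                digest=m.get("digest", ""),
                snapshot={
                    "labels": labels,
                    "affine": affine,
                    "points": [(int(mv), tuple(int(c) for c in xyz)) for mv, xyz in m.get("points", [])],
                    "provenance": {(int(z_), int(mv)): who for z_, mv, who in m.get("provenance", [])},
                    "text_values": dict(m.get("text_values", {})),
                },
            )
        )
    project.versions[series_id] = entries


def history(project: Project, series_id: str) -> list[VersionEntry]:
    project.get_series(series_id)
    if series_id not in project.versions and project.annotation_store:
        _load_versions(project, series_id)
    return list(project.versions.get(series_id, []))


def rollback(project: Project, series_id: str, version_id: int, user: str = "system") -> VersionEntry:
    """Restore a previous version's snapshot as a *new* version.

    History is append-only: nothing is deleted, and the rollback itself
    appears in the change history.
    """
    entries = history(project, series_id)
    target = next((e for e in entries if e.version_id == version_id), None)
    if target is None:
        raise VersionNotFoundError(f"series {series_id!r} has no version {version_id}")
    record = project.get_series(series_id)
    snap = target.snapshot
    vol = project.labels.get(series_id)
    if vol is None or vol.labels.shape != snap["labels"].shape:
        vol = LabelVolume(snap["labels"].shape, snap["affine"])
        project.labels[series_id] = vol
    vol.labels[...] = snap["labels"]
    vol.points = list(snap["points"])
    vol.provenance = dict(snap["provenance"])
    record.text_values = dict(snap["text_values"])
    return commit_version(project, series_id, user, note=f"rollback to v{version_id}")


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# project descriptor + annotation store persistence
# ---------------------------------------------------------------------------

def _annotation_header(record: SeriesRecord, volume: LabelVolume) -> dict:
    return {
        "series_id": record.series_id,
        "shape": list(volume.shape),
        "affine": volume.affine.tolist(),
        "points": [[int(mv), list(map(int, xyz))] for mv, xyz in volume.points],
        "provenance": [[int(z), int(mv), who] for (z, mv), who in sorted(volume.provenance.items())],
        "text_values": dict(record.text_values),
    }


def save_project(project: Project, path: str) -> str:
    """Write the project descriptor YAML (schema, series, workflow)."""
    doc = {
        "exclusive_mode": project.exclusive_mode,
        "annotation_store": project.annotation_store,
        "allocated_bits": sorted(project._allocated_bits),
        "rois": [
            {
                "name": r.name,
                "mask_value": r.mask_value,
                "radlex_id": r.radlex_id,
                "color": list(r.color),
                "kind": r.kind,
                "locked": r.locked,
            }
            for r in project.roi_table
        ],
        "text_fields": [
            {"name": f.name, "allowed_values": f.allowed_values} for f in project.text_fields
        ],
        "series": [
            {
                "series_id": s.series_id,
                "source_path": s.source_path,
                "hierarchy_key": list(s.hierarchy_key),
                "text_values": dict(s.text_values),
            }
            for s in project.series
        ],
    }
    if project.workflow is not None:
        from . import workflow as _wf

        doc["workflow"] = _wf.workflow_to_dict(project.workflow)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_project(path: str) -> Project:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    project = Project(
        exclusive_mode=bool(doc.get("exclusive_mode", False)),
        annotation_store=doc.get("annotation_store"),
    )
    for r in doc.get("rois", []):
        project.roi_table.append(
            ROIDefinition(
                name=r["name"],
                mask_value=int(r["mask_value"]),
                radlex_id=r.get("radlex_id"),
                color=tuple(r.get("color", (255, 0, 0))),
                kind=r.get("kind", "area"),
                locked=bool(r.get("locked", False)),
            )
        )
    project._allocated_bits = set(int(b) for b in doc.get("allocated_bits", []))
    project._allocated_bits.update(r.mask_value for r in project.roi_table)
    for f in doc.get("text_fields", []):
        project.text_fields.append(
            TextFieldDefinition(name=f["name"], allowed_values=f.get("allowed_values"))
        )
    for s in doc.get("series", []):
        project.series.append(
            SeriesRecord(
                series_id=s["series_id"],
                source_path=s.get("source_path"),
                hierarchy_key=tuple(s.get("hierarchy_key", ())),
                text_values=dict(s.get("text_values", {})),
            )
        )
    if "workflow" in doc and doc["workflow"] is not None:
        from . import workflow as _wf

        project.workflow = _wf.parse_workflow(doc["workflow"])
    return project


def save_annotations(project: Project, series_id: str) -> tuple[str, str]:
    """Persist one series' label state into the annotation store.

    Layout: ``<store>/<mirrored series path>/annotations.yaml`` (header)
    plus ``labels.npz`` (compressed grid).  The store location is
    independent of the imaging, so the same imaging can back several
    annotation projects.
    """
    if not project.annotation_store:
        raise ValidationError("project has no annotation_store configured")
    record = project.get_series(series_id)
    volume = project.get_labels(series_id)
    out_dir = _series_dir(project.annotation_store, record)
    os.makedirs(out_dir, exist_ok=True)
    header = os.path.join(out_dir, "annotations.yaml")
    blob = os.path.join(out_dir, "labels.npz")
    with open(header, "w") as fh:
        yaml.safe_dump(_annotation_header(record, volume), fh, sort_keys=False)
    np.savez_compressed(blob, labels=volume.labels, affine=volume.affine)
    return header, blob


def load_annotations(project: Project, series_id: str) -> LabelVolume:
    if not project.annotation_store:
        raise ValidationError("project has no annotation_store configured")
    record = project.get_series(series_id)
    out_dir = _series_dir(project.annotation_store, record)
    header = os.path.join(out_dir, "annotations.yaml")
    blob = os.path.join(out_dir, "labels.npz")
    if not (os.path.exists(header) and os.path.exists(blob)):
        raise ValidationError(f"no stored annotations for series {series_id!r}")
    with open(header) as fh:
        doc = yaml.safe_load(fh)
    with np.load(blob) as z:
        labels = z["labels"]
        affine = z["affine"]
    volume = LabelVolume(labels.shape, affine)
    volume.labels[...] = labels.astype(np.uint64)
    volume.points = [(int(mv), tuple(int(c) for c in xyz)) for mv, xyz in doc.get("points", [])]
    volume.provenance = {
        (int(z_), int(mv)): who for z_, mv, who in doc.get("provenance", [])
    }
    record.text_values = dict(doc.get("text_values", {}))
    project.labels[series_id] = volume
    return volume
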