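"""Metadata-driven model plugin harness.

A segmentation or classification model enters the system as a *bundle*:
an HDF5 weights file plus a YAML metadata descriptor.  The metadata — not
code — tells the harness everything it needs to run the model: the input
mode (per-slice 2-D or sliding-window 3-D patches), the affine transforms
and intensity normalization to apply to each section, and how model output
channels map back onto project annotations (ROIs for segmentation, text
field values for classification).  This "no-coding" contract lets a model
trained elsewhere be dropped into a watched directory and used for draft
annotation without touching the annotation tool's code.

The execution backend is a plain predict-function contract
(``predict(section) -> scores``); the bundled loader builds an
:mod:`annovox.nets` network from the HDF5 file, and named custom loader
hooks can supply any other backend.

3-D patch inference tiles the volume with stride = patch/2 per axis and
blends overlapping per-class scores with a separable Hann window,
renormalized so the blend weights sum to exactly 1 at every voxel.
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import yaml
from scipy import ndimage

from .core import LabelVolume, Project
from .errors import LockedROIError, ModelImportError, UnknownROIError, ValidationError
from . import core as _core
from .nets import load_network

__all__ = [
    "InputSpec",
    "NormalizationSpec",
    "OutputSpec",
    "ModelSpec",
    "ModelRegistry",
    "register_loader",
    "import_model",
    "load_predictor",
    "preprocess",
    "blend_patch_scores",
    "infer",
    "discover_models",
    "write_bundle",
]

AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class InputSpec:
    mode: str = "2d"  # "2d" | "3d_patch"
    axis: str = "axial"
    plane_shape: Optional[tuple[int, int]] = None
    patch_shape: Optional[tuple[int, int, int]] = None
    affine_ops: list = field(default_factory=list)
    channels: int = 1


@dataclass
class NormalizationSpec:
    method: str = "none"  # none | minmax | zscore | fixed_window
    window: Optional[tuple[float, float]] = None  # for fixed_window


@dataclass
class OutputSpec:
    task: str = "segmentation"  # segmentation | classification
    # segmentation: class index -> ROI name
    # classification: class index -> (text field, value)
    mapping: dict = field(default_factory=dict)
    rule: str = "argmax"  # argmax | threshold
    thresholds: dict = field(default_factory=dict)  # class index -> theta


@dataclass
class ModelSpec:
    name: str
    version: int
    weights_ref: Optional[str]
    input: InputSpec
    normalization: NormalizationSpec
    output: OutputSpec
    custom_loader: Optional[str] = None


class ModelRegistry:
    """Versioned model store: full history kept, newest version active."""

    def __init__(self) -> None:
        self.entries: dict[str, dict[int, ModelSpec]] = {}
        self.active: dict[str, int] = {}

    def get_active(self, name: str) -> ModelSpec:
        if name not in self.active:
            raise ModelImportError(f"no model named {name!r} registered")
        return self.entries[name][self.active[name]]

    def versions(self, name: str) -> list[int]:
        return sorted(self.entries.get(name, {}))

    def activate(self, name: str, version: int) -> None:
        if version not in self.entries.get(name, {}):
            raise ModelImportError(f"model {name!r} has no version {version}")
        self.active[name] = version


# named custom loader hooks: name -> callable(ModelSpec) -> predictor
_LOADERS: dict[str, Callable[[ModelSpec], object]] = {}


def register_loader(name: str, loader: Callable[[ModelSpec], object]) -> None:
    _LOADERS[name] = loader


def load_predictor(spec: ModelSpec) -> object:
    if spec.custom_loader is not None:
        if spec.custom_loader not in _LOADERS:
            raise ModelImportError(f"custom loader {spec.custom_loader!r} is not registered")
        return _LOADERS[spec.custom_loader](spec)
    if not spec.weights_ref:
        raise ModelImportError(f"model {spec.name!r} has neither weights nor a custom loader")
    return load_network(spec.weights_ref)


# ---------------------------------------------------------------------------
# metadata parsing / validation
# ---------------------------------------------------------------------------

def _parse_metadata(metadata: dict, base_dir: str = "") -> ModelSpec:
    try:
        name = metadata["name"]
    except KeyError as exc:
        raise ModelImportError("model metadata missing 'name'") from exc
    weights = metadata.get("weights")
    if weights is not None and base_dir and not os.path.isabs(weights):
        weights = os.path.join(base_dir, weights)

    idoc = metadata.get("input", {}) or {}
    mode = idoc.get("mode", "2d")
    if mode not in ("2d", "3d_patch"):
        raise ModelImportError(f"input mode must be '2d' or '3d_patch', got {mode!r}")
    axis = idoc.get("axis", "axial")
    if axis not in AXIS_INDEX:
        raise ModelImportError(f"axis must be one of {sorted(AXIS_INDEX)}, got {axis!r}")
    ispec = InputSpec(
        mode=mode,
        axis=axis,
        plane_shape=tuple(idoc["plane_shape"]) if idoc.get("plane_shape") else None,
        patch_shape=tuple(idoc["patch_shape"]) if idoc.get("patch_shape") else None,
        affine_ops=list(idoc.get("affine_ops", [])),
        channels=int(idoc.get("channels", 1)),
    )
    if mode == "3d_patch" and ispec.patch_shape is None:
        raise ModelImportError("3d_patch mode requires input.patch_shape")

    ndoc = metadata.get("normalization", {}) or {}
    method = ndoc.get("method", "none")
    if method not in ("none", "minmax", "zscore", "fixed_window"):
        raise ModelImportError(f"unknown normalization method {method!r}")
    window = ndoc.get("window")
    if method == "fixed_window":
        if window is None or len(window) != 2 or window[0] >= window[1]:
            raise ModelImportError("fixed_window normalization requires window [lo, hi], lo < hi")
        window = (float(window[0]), float(window[1]))
    nspec = NormalizationSpec(method=method, window=window)

    odoc = metadata.get("output", {}) or {}
    task = odoc.get("task", "segmentation")
    if task not in ("segmentation", "classification"):
        raise ModelImportError(f"unknown task {task!r}")
    rule = odoc.get("rule", "argmax")
    if rule not in ("argmax", "threshold"):
        raise ModelImportError(f"unknown decision rule {rule!r}")
    mapping: dict = {}
    for key, val in (odoc.get("mapping") or {}).items():
        cls = int(key)
        if task == "segmentation":
            mapping[cls] = str(val)
        else:
            if not isinstance(val, dict) or "field" not in val or "value" not in val:
                raise ModelImportError(
                    "classification mapping values must be {field: ..., value: ...}"
                )
            mapping[cls] = (str(val["field"]), str(val["value"]))
    thresholds = {int(k): float(v) for k, v in (odoc.get("thresholds") or {}).items()}
    ospec = OutputSpec(task=task, mapping=mapping, rule=rule, thresholds=thresholds)

    return ModelSpec(
        name=name,
        version=int(metadata.get("version", 0)),
        weights_ref=weights,
        input=ispec,
        normalization=nspec,
        output=ospec,
        custom_loader=metadata.get("custom_loader"),
    )


def _validate_against_project(spec: ModelSpec, project: Project) -> None:
    if spec.output.task == "segmentation":
        for cls, roi_name in spec.output.mapping.items():
            try:
                project.get_roi(roi_name)
            except UnknownROIError as exc:
                raise ModelImportError(
                    f"mapping class {cls} -> ROI {roi_name!r} which is undefined in the project"
                ) from exc
    else:
        for cls, (fname, value) in spec.output.mapping.items():
            fdef = project.get_field(fname)
            if fdef.allowed_values is not None and value not in fdef.allowed_values:
                raise ModelImportError(
                    f"mapping class {cls} -> value {value!r} not allowed for field {fname!r}"
                )


def import_model(
    metadata: dict,
    registry: ModelRegistry,
    project: Optional[Project] = None,
    base_dir: str = "",
) -> ModelSpec:
    """Validate metadata and register the model; re-imports bump the version.

    The weights file must exist (unless a custom loader supplies the
    model), the output mapping must reference annotations defined in the
    project when one is given, and a declared ``plane_shape`` must match
    the loaded model's own input shape when the model declares one.
    """
    spec = _parse_metadata(metadata, base_dir=base_dir)
    if spec.custom_loader is None:
        if not spec.weights_ref or not os.path.exists(spec.weights_ref):
            raise ModelImportError(f"weights file {spec.weights_ref!r} not found")
        predictor = load_predictor(spec)
        declared = getattr(predictor, "input_shape", None)
        if declared is not None and spec.input.plane_shape is not None:
            if tuple(declared[:2]) != tuple(spec.input.plane_shape):
                raise ModelImportError(
                    f"metadata plane_shape {spec.input.plane_shape} mismatches model "
                    f"input shape {tuple(declared)}"
                )
    if project is not None:
        _validate_against_project(spec, project)

    versions = registry.entries.setdefault(spec.name, {})
    if spec.version <= 0:
        spec.version = max(versions, default=0) + 1
    elif spec.version in versions:
        raise ModelImportError(f"model {spec.name!r} already has version {spec.version}")
    versions[spec.version] = spec
    registry.active[spec.name] = max(versions)
    return spec


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _apply_affine_op(section: np.ndarray, op) -> np.ndarray:
    if op == "flip_x":
        return section[::-1, ...]
    if op == "flip_y":
        return section[:, ::-1, ...]
    if isinstance(op, dict) and "rot90" in op:
        return np.rot90(section, k=int(op["rot90"]))
    if isinstance(op, dict) and "scale_to_shape" in op:
        target = tuple(op["scale_to_shape"])
        factors = [t / s for t, s in zip(target, section.shape[: len(target)])]
        factors += [1.0] * (section.ndim - len(target))
        return ndimage.zoom(section, factors, order=1)
    raise ValidationError(f"unknown affine op {op!r}")


def preprocess(section: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Apply the metadata's affine ops in order, then intensity normalization.

    Degenerate sections (zero dynamic range under minmax, zero std under
    zscore) normalize to all-zeros with a warning rather than dividing by
    zero.
    """
    x = np.asarray(section, dtype=float)
    for op in spec.input.affine_ops:
        x = _apply_affine_op(x, op)
    norm = spec.normalization
    if norm.method == "minmax":
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            warnings.warn("minmax normalization of a constant section; returning zeros")
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    if norm.method == "zscore":
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0.0:
            warnings.warn("zscore normalization with zero std; returning zeros")
            return np.zeros_like(x)
        return (x - mu) / sd
    if norm.method == "fixed_window":
        lo, hi = norm.window
        return (np.clip(x, lo, hi) - lo) / (hi - lo)
    return x


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _decide(scores: np.ndarray, out: OutputSpec) -> dict[int, np.ndarray]:
    """Per-class boolean masks from a (..., C) score array."""
    masks = {}
    if out.rule == "argmax":
        winner = np.argmax(scores, axis=-1)
        for cls in out.mapping:
            masks[cls] = winner == cls
    else:
        for cls in out.mapping:
            theta = out.thresholds.get(cls, 0.5)
            masks[cls] = scores[..., cls] >= theta
    return masks


def _hann_window(shape: tuple[int, ...]) -> np.ndarray:
    w = np.ones(shape)
    for ax, n in enumerate(shape):
        # offset Hann: strictly positive, so every voxel keeps support
        win = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(n) + 0.5) / n) + 1e-3
        w *= win.reshape([-1 if a == ax else 1 for a in range(len(shape))])
    return w


def _patch_starts(dim: int, patch: int) -> list[int]:
    stride = max(patch // 2, 1)
    starts = list(range(0, max(dim - patch, 0) + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return sorted(set(starts))


def blend_weights(volume_shape: tuple[int, int, int], patch_shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel total blend weight before normalization (diagnostic)."""
    acc = np.zeros(volume_shape)
    w = _hann_window(patch_shape)
    for sx in _patch_starts(volume_shape[0], patch_shape[0]):
        for sy in _patch_starts(volume_shape[1], patch_shape[1]):
            for sz in _patch_starts(volume_shape[2], patch_shape[2]):
                acc[sx : sx + patch_shape[0], sy : sy + patch_shape[1], sz : sz + patch_shape[2]] += w
    return acc


def blend_patch_scores(
    image: np.ndarray,
    patch: tuple[int, int, int],
    score_fn: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Sliding-window per-class scores blended with a partition of unity.

    Windows step half a patch per axis (plus a final flush window), each
    weighted by a strictly positive separable Hann window; dividing by the
    accumulated weight makes every voxel's blend weights sum to exactly 1.
    """
    if any(p > s for p, s in zip(patch, image.shape)):
        raise ValidationError(f"patch {patch} larger than volume {image.shape}")
    w = _hann_window(patch)
    acc: Optional[np.ndarray] = None
    wsum = np.zeros(image.shape)
    for sx in _patch_starts(image.shape[0], patch[0]):
        for sy in _patch_starts(image.shape[1], patch[1]):
            for sz in _patch_starts(image.shape[2], patch[2]):
                sub = (slice(sx, sx + patch[0]), slice(sy, sy + patch[1]), slice(sz, sz + patch[2]))
                scores = score_fn(image[sub])
                if scores.shape[:3] != tuple(patch):
                    raise ValidationError(
                        f"patch predictor must return {patch} + (C,) scores, got {scores.shape}"
                    )
                if acc is None:
                    acc = np.zeros(image.shape + (scores.shape[-1],))
                acc[sub] += scores * w[..., None]
                wsum[sub] += w
    return acc / wsum[..., None]


def infer(
    spec: ModelSpec,
    image: np.ndarray,
    project: Project,
    series_id: Optional[str] = None,
    predictor: Optional[object] = None,
) -> Union[LabelVolume, str]:
    """Run a model over a volume and map its output onto annotations.

    Segmentation returns a draft :class:`LabelVolume` with all produced
    (slice, ROI) provenance set to ``auto``; classification returns the
    mapped text value (and stores it when ``series_id`` is given).
    """
    if predictor is None:
        predictor = load_predictor(spec)
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValidationError(f"inference expects a 3-D volume, got shape {image.shape}")

    if spec.output.task == "segmentation":
        target_rois = {cls: project.get_roi(name) for cls, name in spec.output.mapping.items()}
        for roi in target_rois.values():
            if roi.locked:
                raise LockedROIError(f"target ROI {roi.name!r} is locked")

    if spec.input.mode == "2d":
        axis = AXIS_INDEX[spec.input.axis]
        n_slices = image.shape[axis]
        if spec.output.task == "classification":
            slice_scores = []
            for k in range(n_slices):
                section = preprocess(np.take(image, k, axis=axis), spec)
                scores = np.asarray(predictor.predict(section), dtype=float)
                if scores.ndim != 1:
                    scores = scores.reshape(-1)
                slice_scores.append(scores)
            mean_scores = np.mean(slice_scores, axis=0)
            _check_channels(mean_scores.shape[-1], spec)
            cls = (
                int(np.argmax(mean_scores))
                if spec.output.rule == "argmax"
                else int(np.argmax(mean_scores))
            )
            if cls not in spec.output.mapping:
                raise ValidationError(f"predicted class {cls} has no mapping")
            fname, value = spec.output.mapping[cls]
            if series_id is not None:
                _core.set_text_value(project, series_id, fname, value)
            return value

        draft = _new_draft(project, series_id, image.shape)
        for k in range(n_slices):
            section = np.take(image, k, axis=axis)
            x = preprocess(section, spec)
            scores = np.asarray(predictor.predict(x), dtype=float)
            if scores.ndim != 3:
                raise ValidationError(
                    f"segmentation predictor must return (H, W, C) scores, got {scores.shape}"
                )
            _check_channels(scores.shape[-1], spec)
            if scores.shape[:2] != section.shape:
                # undo any scale_to_shape so scores align with the source grid
                factors = [s / t for s, t in zip(section.shape, scores.shape[:2])] + [1.0]
                scores = ndimage.zoom(scores, factors, order=1)
            masks = _decide(scores, spec.output)
            _write_class_masks_2d(draft, masks, target_rois, k, axis, project.exclusive_mode)
        return draft

    # 3d_patch
    if spec.output.task != "segmentation":
        raise ValidationError("3d_patch mode supports segmentation only")
    patch = spec.input.patch_shape
    blended = blend_patch_scores(
        image, patch, lambda sub: np.asarray(predictor.predict(preprocess(sub, spec)), dtype=float)
    )
    _check_channels(blended.shape[-1], spec)
    masks = _decide(blended, spec.output)
    draft = _new_draft(project, series_id, image.shape)
    for cls, m in masks.items():
        roi = target_rois[cls]
        if project.exclusive_mode:
            free = draft.labels == 0
            m = m & free
        draft.labels[m] |= np.uint64(roi.mask_value)
        for z in np.nonzero(m.any(axis=(0, 1)))[0]:
            draft.provenance[(int(z), roi.mask_value)] = "auto"
    return draft


def _check_channels(n_channels: int, spec: ModelSpec) -> None:
    if spec.output.mapping and max(spec.output.mapping) >= n_channels:
        raise ValidationError(
            f"model outputs {n_channels} channels but mapping references class "
            f"{max(spec.output.mapping)}"
        )


def _new_draft(project: Project, series_id: Optional[str], shape) -> LabelVolume:
    affine = None
    if series_id is not None and series_id in project.labels:
        affine = project.labels[series_id].affine
    return LabelVolume(shape, affine)


def _write_class_masks_2d(
    draft: LabelVolume,
    masks: dict[int, np.ndarray],
    target_rois: dict,
    k: int,
    axis: int,
    exclusive: bool,
) -> None:
    index = [slice(None)] * 3
    index[axis] = k
    index = tuple(index)
    plane = draft.labels[index]
    for cls, m in masks.items():
        roi = target_rois[cls]
        if exclusive:
            m = m & (plane == 0)
        plane[m] |= np.uint64(roi.mask_value)
        if m.any():
            if axis == 2:
                draft.provenance[(k, roi.mask_value)] = "auto"
            else:
                # a non-axial plane touches many z slices
                for z in np.nonzero(m.any(axis=0))[0]:
                    draft.provenance[(int(z), roi.mask_value)] = "auto"
    draft.labels[index] = plane


# ---------------------------------------------------------------------------
# bundles and discovery
# ---------------------------------------------------------------------------

def write_bundle(metadata: dict, directory: str, filename: Optional[str] = None) -> str:
    """Write a metadata YAML next to its weights (test/distribution helper)."""
    os.makedirs(directory, exist_ok=True)
    filename = filename or f"{metadata['name']}_v{metadata.get('version', 1)}.yaml"
    path = os.path.join(directory, filename)
    with open(path, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)
    return path


def discover_models(
    registry: ModelRegistry,
    directory: str,
    project: Optional[Project] = None,
) -> tuple[list[ModelSpec], list[str]]:
    """Scan a watched directory for model bundles and import the new ones.

    A bundle is a ``*.yaml``/``*.yml`` metadata file whose ``weights`` key
    points at an HDF5 file (relative paths resolve against the bundle's
    directory).  Bundles already registered at the same or lower version
    are skipped, so rescanning is idempotent; malformed bundles are
    reported and skipped without aborting the scan.  Returns
    ``(imported_specs, skipped_reports)``.
    """
    imported: list[ModelSpec] = []
    reports: list[str] = []
    paths = sorted(glob.glob(os.path.join(directory, "*.yaml")) + glob.glob(os.path.join(directory, "*.yml")))
    for path in paths:
        try:
            with open(path) as fh:
                metadata = yaml.safe_load(fh)
            if not isinstance(metadata, dict) or "name" not in metadata:
                raise ModelImportError("not a model metadata document")
            name = metadata["name"]
            version = int(metadata.get("version", 0))
            existing = registry.versions(name)
            if existing and version <= max(existing):
                continue  # already have this or a newer version
            spec = import_model(
                metadata, registry, project=project, base_dir=os.path.dirname(path)
            )
            imported.append(spec)
        except Exception as exc:
            reports.append(f"{os.path.basename(path)}: {exc}")
    return imported, reports
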