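"""Iterative model-assisted annotation loop (annotate, train, draft, correct).

The loop emulates how an annotation project bootstraps itself with deep
learning: a small first batch is labeled from scratch, a model is trained
on everything labeled so far, the model drafts labels for the next batch,
a human corrects the drafts, and the cycle repeats until the dataset is
covered or the model is good enough.  The payoff claimed for the method is
that correcting a decent draft is much cheaper than labeling from scratch.

Human correction time is not reproducible at desk scale, so the harness
uses a declared proxy: **edit cost**, the number of (voxel, label)
discrepancies between draft and truth — the voxels a corrector would have
to flip.  Correction itself is perfect (the corrected state *is* the
truth), modeling the reviewed-and-approved end state of a multiuser
workflow.  Iteration 0's cost is exactly the de-novo cost ``|truth|``.

Two degenerate trainers pin down the harness limits: an oracle trainer
(drafts equal truth, cost 0 after iteration 0) and a null trainer (drafts
empty, cost stuck at de-novo).  The default practical trainer is a
per-voxel logistic model over local intensity features — trainable in
seconds on one CPU — whose drafts improve as the training set grows.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, Project, define_roi
from .errors import ShapeMismatchError, ValidationError
from .metrics import dice_jaccard
from .models import InputSpec, ModelSpec, NormalizationSpec, OutputSpec, infer

__all__ = [
    "simulate_correction",
    "run_aid",
    "logistic_trainer",
    "null_trainer",
    "make_oracle_trainer",
]

# trainer contract: (samples, seed) -> predictor; samples are
# (image volume, boolean truth mask) pairs; the predictor maps a 2-D
# slice (H, W) or (H, W, 1) to per-pixel class scores (H, W, 2)
Trainer = Callable[[Sequence[tuple[np.ndarray, np.ndarray]], int], object]


def simulate_correction(
    draft: LabelVolume, truth: LabelVolume
) -> tuple[LabelVolume, int]:
    """Perfect correction of a draft against truth.

    Returns ``(corrected, edit_cost)`` where corrected equals the truth
    and edit_cost counts every (voxel, label-bit) in the symmetric
    difference — the desk-scale proxy for human correction effort.
    An empty draft therefore costs exactly ``|truth|``.
    """
    if draft.shape != truth.shape:
        raise ShapeMismatchError(f"draft {draft.shape} vs truth {truth.shape}")
    diff = draft.labels ^ truth.labels
    cost = 0
    work = diff.copy()
    while work.any():
        cost += int((work & np.uint64(1)).sum())
        work >>= np.uint64(1)
    return truth.copy(), cost


@dataclass
class _AidRow:
    iteration: int
    training_set_size: int
    mean_draft_dice: float
    mean_edit_cost: float


def _aid_model_spec(roi_name: str) -> ModelSpec:
    return ModelSpec(
        name="aid_draft",
        version=1,
        weights_ref=None,
        input=InputSpec(mode="2d", axis="axial"),
        normalization=NormalizationSpec(method="none"),
        output=OutputSpec(task="segmentation", mapping={1: roi_name}, rule="argmax"),
    )


def run_aid(
    project: Project,
    suite: Sequence[tuple[np.ndarray, LabelVolume]],
    trainer_hook: Trainer,
    iterations: int,
    batch_per_iteration: int,
    seed: int = 0,
    roi_name: Optional[str] = None,
) -> pd.DataFrame:
    """Run the iterative annotation loop over a phantom suite.

    Iteration 0 labels the first batch from scratch (edit cost =
    de-novo).  Every later iteration trains on all corrected volumes,
    drafts the next batch through the model-plugin inference path,
    corrects the drafts, and logs ``(iteration, training_set_size,
    mean_draft_dice, mean_edit_cost)``.  All randomness derives from
    ``seed``; identical seeds give identical reports.
    """
    if iterations < 2:
        raise ValidationError("the loop needs at least 2 iterations (bootstrap + one model round)")
    if batch_per_iteration < 1:
        raise ValidationError("batch_per_iteration must be >= 1")
    if iterations * batch_per_iteration > len(suite):
        raise ValidationError(
            f"suite of {len(suite)} phantoms too small for "
            f"{iterations} x {batch_per_iteration} batches"
        )
    if roi_name is None:
        if not project.roi_table:
            define_roi(project, "object")
        roi_name = project.roi_table[0].name
    roi = project.get_roi(roi_name)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(suite))
    spec = _aid_model_spec(roi_name)

    corrected: list[tuple[np.ndarray, np.ndarray]] = []
    rows: list[_AidRow] = []
    for it in range(iterations):
        batch = [suite[i] for i in order[it * batch_per_iteration : (it + 1) * batch_per_iteration]]
        dices, costs = [], []
        if it == 0:
            for image, truth in batch:
                empty = LabelVolume(truth.shape, truth.affine)
                d, _, _ = dice_jaccard(
                    empty.roi_mask(roi.mask_value), truth.roi_mask(roi.mask_value)
                )
                fixed, cost = simulate_correction(empty, truth)
                corrected.append((image, fixed.roi_mask(roi.mask_value)))
                dices.append(d)
                costs.append(cost)
        else:
            predictor = trainer_hook(corrected, int(rng.integers(0, 2**31 - 1)))
            if predictor is None:
                break  # trainer failure: return the partial report
            for image, truth in batch:
                draft = infer(spec, image, project, predictor=predictor)
                draft.affine = truth.affine.copy()
                d, _, _ = dice_jaccard(
                    draft.roi_mask(roi.mask_value), truth.roi_mask(roi.mask_value)
                )
                fixed, cost = simulate_correction(draft, truth)
                corrected.append((image, fixed.roi_mask(roi.mask_value)))
                dices.append(d)
                costs.append(cost)
        rows.append(
            _AidRow(
                iteration=it,
                training_set_size=len(corrected),
                mean_draft_dice=float(np.mean(dices)),
                mean_edit_cost=float(np.mean(costs)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def _slice_features(section: np.ndarray) -> np.ndarray:
    """Per-pixel features of a 2-D slice: raw and Gaussian-smoothed intensity."""
    x = np.asarray(section, dtype=float)
    if x.ndim == 3:
        x = x[:, :, 0]
    return np.stack(
        [x, ndimage.gaussian_filter(x, 1.0), ndimage.gaussian_filter(x, 2.0)], axis=-1
    )


class _LogisticSlicePredictor:
    def __init__(self, model):
        self._model = model

    def predict(self, section: np.ndarray) -> np.ndarray:
        feats = _slice_features(section)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self._model.predict_proba(flat)
        out = np.zeros((flat.shape[0], 2))
        # predict_proba columns follow model.classes_; map onto (bg, fg)
        for col, cls in enumerate(self._model.classes_):
            out[:, int(cls)] = proba[:, col]
        return out.reshape(feats.shape[0], feats.shape[1], 2)


def logistic_trainer(
    samples: Sequence[tuple[np.ndarray, np.ndarray]], seed: int = 0
) -> object:
    """Default trainable model: per-voxel logistic regression.

    Features are the raw slice intensity and two Gaussian smoothings
    (sigma 1 and 2 voxels).  Training voxels are subsampled per volume
    (all foreground up to 10k plus an equal background sample) to keep
    fitting under a second per iteration.
    """
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for image, mask in samples:
        vol_feats = np.stack(
            [_slice_features(image[:, :, z]) for z in range(image.shape[2])], axis=2
        )  # (X, Y, Z, F)
        flat = vol_feats.reshape(-1, vol_feats.shape[-1])
        flat_mask = np.asarray(mask, dtype=bool).reshape(-1)
        fg_idx = np.nonzero(flat_mask)[0]
        bg_idx = np.nonzero(~flat_mask)[0]
        if len(fg_idx) > 10_000:
            fg_idx = rng.choice(fg_idx, 10_000, replace=False)
        n_bg = min(len(bg_idx), max(len(fg_idx), 1_000))
        bg_idx = rng.choice(bg_idx, n_bg, replace=False)
        idx = np.concatenate([fg_idx, bg_idx])
        feats.append(flat[idx])
        labels.append(flat_mask[idx].astype(int))
    X = np.concatenate(feats)
    y = np.concatenate(labels)
    if len(np.unique(y)) < 2:
        return _ConstantPredictor(0)  # nothing to learn; predict background
    model = LogisticRegression(max_iter=500, random_state=int(seed) % (2**32 - 1))
    model.fit(X, y)
    return _LogisticSlicePredictor(model)


class _ConstantPredictor:
    def __init__(self, cls: int):
        self._cls = cls

    def predict(self, section: np.ndarray) -> np.ndarray:
        x = np.asarray(section)
        if x.ndim == 3:
            x = x[:, :, 0]
        out = np.zeros(x.shape + (2,))
        out[..., self._cls] = 1.0
        return out


def null_trainer(samples, seed: int = 0) -> object:
    """Degenerate trainer: drafts are always empty (background only)."""
    return _ConstantPredictor(0)


def make_oracle_trainer(suite: Sequence[tuple[np.ndarray, LabelVolume]], mask_value: int = 1) -> Trainer:
    """Trainer whose predictor reproduces the suite's truth exactly.

    The predictor recognizes each slice it is shown by content (a hash of
    the raw intensities) and answers with the corresponding truth slice —
    the upper bound of what any trained model could achieve on the suite.
    """
    lut: dict[bytes, np.ndarray] = {}
    for image, truth in suite:
        mask = truth.roi_mask(mask_value)
        for z in range(image.shape[2]):
            key = hashlib.sha1(np.asarray(image[:, :, z], dtype=float).tobytes()).digest()
            lut[key] = mask[:, :, z]

    class _OraclePredictor:
        def predict(self, section: np.ndarray) -> np.ndarray:
            x = np.asarray(section, dtype=float)
            if x.ndim == 3:
                x = x[:, :, 0]
            key = hashlib.sha1(x.tobytes()).digest()
            mask = lut.get(key)
            out = np.zeros(x.shape + (2,))
            if mask is None:
                out[..., 0] = 1.0
            else:
                out[..., 0] = ~mask
                out[..., 1] = mask
            return out

    def trainer(samples, seed: int = 0) -> object:
        return _OraclePredictor()

    return trainer
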