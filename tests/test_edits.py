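"""Voxel editing operators against brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from annovox.core import LabelVolume, SeriesRecord
from annovox.edits import (
    EditRequest,
    apply_edit,
    add_point,
    auto_contour,
    disc_footprint,
    flood_fill,
    morph,
    redo,
    remove_point,
    snap_contour,
    undo,
)
from annovox.errors import (
    EmptyRegionError,
    PointNotFoundError,
    ValidationError,
    WrongToolError,
)


def _flood_oracle(candidates: np.ndarray, seed: tuple[int, int], connectivity: int) -> np.ndarray:
    """Breadth-first connected component of the seed over a boolean plane."""
    if not candidates[seed]:
        return np.zeros_like(candidates)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    out = np.zeros_like(candidates)
    out[seed] = True
    queue = deque([seed])
    while queue:
        x, y = queue.popleft()
        for dx, dy in offsets:
            nx, ny = x + dx, y + dy
            if 0 <= nx < candidates.shape[0] and 0 <= ny < candidates.shape[1]:
                if candidates[nx, ny] and not out[nx, ny]:
                    out[nx, ny] = True
                    queue.append((nx, ny))
    return out


def _morph_oracle(mask: np.ndarray, offsets, op: str) -> np.ndarray:
    """Brute-force binary morphology over an offset set (one iteration)."""
    out = np.zeros_like(mask)
    idx = np.argwhere(mask) if op == "dilate" else np.argwhere(np.ones_like(mask))
    for p in idx:
        if op == "dilate":
            for off in offsets:
                q = tuple(p + off)
                if all(0 <= qi < si for qi, si in zip(q, mask.shape)):
                    out[q] = True
        else:
            ok = True
            for off in offsets:
                q = tuple(p + off)
                if not all(0 <= qi < si for qi, si in zip(q, mask.shape)) or not mask[q]:
                    ok = False
                    break
            if ok:
                out[tuple(p)] = True
    return out


CROSS3 = [np.array(o) for o in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]]


class TestPaintErase:
    def test_radius_zero_brush_touches_exactly_one_voxel(self, project, image):
        vol = LabelVolume(image.shape)
        req = EditRequest(roi=project.get_roi("kidney"), mode="paint",
                          footprint=[(5, 5)], slice=5)
        apply_edit(image, vol, req, project)
        assert vol.labels[5, 5, 5] == 1
        assert int((vol.labels != 0).sum()) == 1
        assert vol.provenance[(5, 1)] == "manual"

    def test_threshold_keeps_only_in_range_voxels(self, project):
        img = np.zeros((8, 8, 3))
        img[1, 1, 1], img[2, 2, 1], img[3, 3, 1] = 5.0, 50.0, 500.0
        vol = LabelVolume(img.shape)
        req = EditRequest(roi=project.get_roi("kidney"), mode="paint",
                          footprint=[(1, 1), (2, 2), (3, 3)], slice=1,
                          threshold_range=(10.0, 100.0))
        apply_edit(img, vol, req, project)
        assert vol.labels[2, 2, 1] == 1
        assert int((vol.labels != 0).sum()) == 1

    def test_slice_extent_clamps_at_volume_boundary(self, project, image):
        vol = LabelVolume(image.shape)
        req = EditRequest(roi=project.get_roi("kidney"), mode="paint",
                          footprint=[(4, 4)], slice=0, slice_extent=1)
        apply_edit(image, vol, req, project)
        touched = sorted(int(z) for z in np.nonzero(vol.labels.any(axis=(0, 1)))[0])
        assert touched == [0, 1]

    def test_erase_clears_only_target_bit(self, project, image):
        vol = LabelVolume(image.shape)
        vol.labels[5, 5, 5] = np.uint64(3)  # kidney + tumor
        req = EditRequest(roi=project.get_roi("tumor"), mode="erase",
                          footprint=[(5, 5)], slice=5)
        apply_edit(image, vol, req, project)
        assert vol.labels[5, 5, 5] == 1

    def test_point_roi_rejected_by_area_tool(self, project, image):
        vol = LabelVolume(image.shape)
        req = EditRequest(roi=project.get_roi("L3_vertebra"), mode="paint",
                          footprint=[(5, 5)], slice=5)
        with pytest.raises(WrongToolError):
            apply_edit(image, vol, req, project)

    def test_threshold_subset_and_locality_randomized(self, project, rng):
        """New labels stay inside the window; voxels outside footprint x extent never change."""
        roi = project.get_roi("kidney")
        for _ in range(20):
            img = rng.normal(50, 30, size=(12, 12, 8))
            vol = LabelVolume(img.shape)
            pre = rng.random(img.shape) < 0.2
            vol.labels[pre] = np.uint64(2)
            before = vol.labels.copy()
            fp = [(int(rng.integers(0, 12)), int(rng.integers(0, 12))) for _ in range(10)]
            z = int(rng.integers(0, 8))
            k = int(rng.integers(0, 3))
            lo, hi = sorted(rng.normal(50, 30, size=2))
            req = EditRequest(roi=roi, mode="paint", footprint=fp, slice=z,
                              slice_extent=k, threshold_range=(lo, hi))
            apply_edit(img, vol, req, project)
            newly = (vol.labels & np.uint64(1)) != 0
            assert np.all((img[newly] >= lo) & (img[newly] <= hi))
            allowed = np.zeros(img.shape, dtype=bool)
            for x, y in fp:
                allowed[x, y, max(0, z - k):z + k + 1] = True
            assert np.array_equal(vol.labels[~allowed], before[~allowed])


class TestFloodFill:
    def test_threshold_block_fill_matches_bfs_oracle(self, project):
        img = np.zeros((5, 5, 1))
        img[1:4, 1:4, 0] = 100.0
        vol = LabelVolume(img.shape)
        flood_fill(img, vol, project.get_roi("kidney"), (2, 2, 0),
                   threshold_range=(50, 150), connectivity=4, project=project)
        oracle = _flood_oracle((img[:, :, 0] >= 50) & (img[:, :, 0] <= 150), (2, 2), 4)
        assert oracle.sum() == 9
        np.testing.assert_array_equal((vol.labels[:, :, 0] & np.uint64(1)) != 0, oracle)

    def test_seed_outside_window_is_noop(self, project):
        img = np.zeros((5, 5, 1))
        vol = LabelVolume(img.shape)
        flood_fill(img, vol, project.get_roi("kidney"), (0, 0, 0),
                   threshold_range=(50, 150), project=project)
        assert not vol.labels.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_diagonal_chain_connectivity(self, project, connectivity):
        img = np.zeros((6, 6, 1))
        for i in range(5):
            img[i, i, 0] = 100.0
        vol = LabelVolume(img.shape)
        flood_fill(img, vol, project.get_roi("kidney"), (0, 0, 0),
                   threshold_range=(50, 150), connectivity=connectivity, project=project)
        got = (vol.labels[:, :, 0] & np.uint64(1)) != 0
        oracle = _flood_oracle((img[:, :, 0] >= 50) & (img[:, :, 0] <= 150), (0, 0), connectivity)
        np.testing.assert_array_equal(got, oracle)
        assert int(got.sum()) == (5 if connectivity == 8 else 1)


class TestMorphology:
    def test_dilate_single_voxel_gives_inplane_cross(self, project):
        vol = LabelVolume((7, 7, 3))
        vol.labels[3, 3, 1] = np.uint64(1)
        morph(vol, project.get_roi("kidney"), "dilate", scope="slice", project=project)
        mask = vol.roi_mask(1)
        assert int(mask.sum()) == 5
        assert not mask[:, :, 0].any() and not mask[:, :, 2].any()

    def test_erode_cross_recovers_single_voxel_vs_oracle(self, project):
        vol = LabelVolume((7, 7, 1))
        for dx, dy in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
            vol.labels[3 + dx, 3 + dy, 0] = np.uint64(1)
        before = vol.roi_mask(1).copy()
        morph(vol, project.get_roi("kidney"), "erode", scope="slice", project=project)
        oracle = _morph_oracle(before, CROSS3, "erode")
        np.testing.assert_array_equal(vol.roi_mask(1), oracle)
        assert int(vol.roi_mask(1).sum()) == 1

    def test_erode_isolated_voxel_empties_roi(self, project):
        vol = LabelVolume((5, 5, 1))
        vol.labels[2, 2, 0] = np.uint64(1)
        morph(vol, project.get_roi("kidney"), "erode", scope="slice", project=project)
        assert not vol.labels.any()

    def test_other_roi_bits_untouched(self, project):
        vol = LabelVolume((7, 7, 1))
        vol.labels[3, 3, 0] = np.uint64(3)
        morph(vol, project.get_roi("kidney"), "dilate", scope="slice", project=project)
        assert vol.roi_mask(2).sum() == 1  # tumor unchanged

    def test_opening_subset_closing_on_random_masks(self, project, rng):
        roi = project.get_roi("kidney")
        for _ in range(10):
            base = rng.random((10, 10, 4)) < 0.35
            vol = LabelVolume(base.shape)
            vol.labels[base] = np.uint64(1)
            opened = vol.copy()
            morph(opened, roi, "erode", scope="volume")
            morph(opened, roi, "dilate", scope="volume")
            closed = vol.copy()
            morph(closed, roi, "dilate", scope="volume")
            morph(closed, roi, "erode", scope="volume")
            x = vol.roi_mask(1)
            assert np.all(opened.roi_mask(1) <= x)
            assert np.all(x <= closed.roi_mask(1))

    def test_exclusive_dilation_never_overwrites_other_roi(self, project):
        project.exclusive_mode = True
        vol = LabelVolume((7, 7, 1))
        vol.labels[3, 3, 0] = np.uint64(1)
        vol.labels[4, 3, 0] = np.uint64(2)
        morph(vol, project.get_roi("kidney"), "dilate", scope="slice", project=project)
        assert vol.labels[4, 3, 0] == 2  # tumor voxel preserved
        from annovox.core import _popcount
        assert int(_popcount(vol.labels).max()) <= 1


class TestPoints:
    def test_add_and_remove_point(self, project, volume):
        roi = project.get_roi("L3_vertebra")
        add_point(volume, roi, (10, 12, 5))
        assert (4, (10, 12, 5)) in volume.points
        remove_point(volume, roi, (10, 12, 5))
        assert volume.points == []

    def test_duplicate_coordinate_rejected(self, project, volume):
        roi = project.get_roi("L3_vertebra")
        add_point(volume, roi, (1, 2, 3))
        with pytest.raises(ValidationError):
            add_point(volume, roi, (1, 2, 3))

    def test_remove_missing_point_is_lookup_error(self, project, volume):
        with pytest.raises(PointNotFoundError):
            remove_point(volume, project.get_roi("L3_vertebra"), (0, 0, 0))

    def test_area_roi_rejected_by_point_tool(self, project, volume):
        with pytest.raises(WrongToolError):
            add_point(volume, project.get_roi("kidney"), (1, 1, 1))


class TestUndoRedo:
    def _setup(self, project, image):
        project.add_series(SeriesRecord(series_id="s1"))
        vol = LabelVolume(image.shape)
        project.attach_labels("s1", vol)
        return vol

    def test_undo_restores_pre_edit_state_bit_exactly(self, project, image):
        vol = self._setup(project, image)
        req = EditRequest(roi=project.get_roi("kidney"), mode="paint",
                          footprint=disc_footprint((8, 8), 2), slice=4)
        before = vol.copy()
        apply_edit(image, vol, req, project, "s1")
        assert not vol.state_equal(before)
        assert undo(project, "s1")
        assert vol.state_equal(before)

    def test_redo_restores_post_edit_state(self, project, image):
        vol = self._setup(project, image)
        req = EditRequest(roi=project.get_roi("kidney"), mode="paint",
                          footprint=[(3, 3)], slice=2)
        apply_edit(image, vol, req, project, "s1")
        after = vol.copy()
        undo(project, "s1")
        assert redo(project, "s1")
        assert vol.state_equal(after)

    def test_undo_redo_replay_matches_edit_log_oracle(self, project, image):
        """Two edits, two undos, one redo lands on the state after edit 1."""
        vol = self._setup(project, image)
        roi = project.get_roi("kidney")
        states = [vol.copy()]
        for z in (1, 2):
            apply_edit(image, vol,
                       EditRequest(roi=roi, mode="paint", footprint=[(z, z)], slice=z),
                       project, "s1")
            states.append(vol.copy())
        undo(project, "s1")
        undo(project, "s1")
        assert vol.state_equal(states[0])
        redo(project, "s1")
        assert vol.state_equal(states[1])

    def test_empty_stacks_are_noops(self, project, image):
        self._setup(project, image)
        assert not undo(project, "s1")
        assert not redo(project, "s1")


def _disc(shape, center, radius):
    xs, ys = np.ogrid[: shape[0], : shape[1]]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2


class TestContourRefinement:
    def test_partial_disc_snaps_to_full_disc(self, project):
        """Rough partial seed inside a homogeneous disc refines to the disc."""
        img = np.zeros((32, 32, 1))
        disc = _disc((32, 32), (16, 16), 8)
        img[:, :, 0][disc] = 100.0
        vol = LabelVolume(img.shape)
        partial = _disc((32, 32), (16, 16), 4)
        vol.labels[:, :, 0][partial] = np.uint64(1)
        snap_contour(img, vol, project.get_roi("kidney"), 0, project=project)
        # oracle: intensities of the partial seed are all 100, so the band is
        # {100} and the centroid's 4-connected component is exactly the disc
        np.testing.assert_array_equal(vol.roi_mask(1)[:, :, 0], disc)

    def test_refiner_is_idempotent_on_isolated_blob(self, project):
        img = np.zeros((20, 20, 1))
        blob = _disc((20, 20), (10, 10), 5)
        img[:, :, 0][blob] = 100.0
        vol = LabelVolume(img.shape)
        vol.labels[:, :, 0][blob] = np.uint64(1)
        snap_contour(img, vol, project.get_roi("kidney"), 0, project=project)
        np.testing.assert_array_equal(vol.roi_mask(1)[:, :, 0], blob)

    def test_auto_generated_slice_marked_lighter_provenance(self, project):
        img = np.zeros((20, 20, 1))
        blob = _disc((20, 20), (10, 10), 5)
        img[:, :, 0][blob] = 100.0
        vol = LabelVolume(img.shape)
        vol.labels[:, :, 0][blob] = np.uint64(1)  # seeded without manual edit
        snap_contour(img, vol, project.get_roi("kidney"), 0, project=project)
        assert vol.provenance[(0, 1)] == "auto"

    def test_snap_empty_slice_is_precondition_error(self, project):
        img = np.zeros((10, 10, 2))
        vol = LabelVolume(img.shape)
        with pytest.raises(EmptyRegionError):
            snap_contour(img, vol, project.get_roi("kidney"), 0, project=project)

    def test_cylinder_propagates_with_high_per_slice_dice(self, project):
        """Seed the middle slice of a cylinder; every slice refines to Dice >= 0.95."""
        from annovox.metrics import dice_jaccard

        img = np.zeros((24, 24, 9))
        disc = _disc((24, 24), (12, 12), 6)
        for z in range(1, 8):  # cylinder spans slices 1..7
            img[:, :, z][disc] = 100.0
        vol = LabelVolume(img.shape)
        vol.labels[:, :, 4][_disc((24, 24), (12, 12), 4)] = np.uint64(1)
        auto_contour(img, vol, project.get_roi("kidney"), (1, 7), project=project)
        for z in range(1, 8):
            d, _, _ = dice_jaccard(vol.roi_mask(1)[:, :, z], disc)
            assert d >= 0.95

    def test_propagation_stops_where_object_vanishes(self, project):
        img = np.zeros((24, 24, 9))
        disc = _disc((24, 24), (12, 12), 6)
        for z in range(2, 6):
            img[:, :, z][disc] = 100.0  # slices 0,1 and 6,7,8 are background
        vol = LabelVolume(img.shape)
        vol.labels[:, :, 4][disc] = np.uint64(1)
        auto_contour(img, vol, project.get_roi("kidney"), (0, 8), project=project)
        assert not vol.roi_mask(1)[:, :, 0].any()
        assert not vol.roi_mask(1)[:, :, 8].any()

    def test_range_without_seed_is_precondition_error(self, project):
        img = np.zeros((10, 10, 6))
        vol = LabelVolume(img.shape)
        vol.labels[5, 5, 0] = np.uint64(1)
        with pytest.raises(EmptyRegionError):
            auto_contour(img, vol, project.get_roi("kidney"), (2, 5), project=project)
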