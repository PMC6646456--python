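"""Model plugin harness: import, preprocessing, inference, discovery."""

import os

import numpy as np
import pytest

from annovox.core import Project, SeriesRecord, add_text_field
from annovox.errors import LockedROIError, ModelImportError, ValidationError
from annovox.models import (
    ModelRegistry,
    ModelSpec,
    InputSpec,
    NormalizationSpec,
    OutputSpec,
    blend_weights,
    discover_models,
    import_model,
    infer,
    preprocess,
    register_loader,
    write_bundle,
)
from annovox.nets import make_threshold_segmenter, save_network


@pytest.fixture
def seg_metadata(tmp_path):
    weights = str(tmp_path / "threshold.h5")
    save_network(make_threshold_segmenter(), weights)
    return {
        "name": "kidney_seg",
        "weights": weights,
        "input": {"mode": "2d", "axis": "axial"},
        "normalization": {"method": "minmax"},
        "output": {"task": "segmentation", "rule": "argmax", "mapping": {1: "kidney"}},
    }


class TestImport:
    def test_same_name_import_increments_version_and_activates(self, seg_metadata, project):
        registry = ModelRegistry()
        s1 = import_model(dict(seg_metadata), registry, project)
        s2 = import_model(dict(seg_metadata), registry, project)
        assert (s1.version, s2.version) == (1, 2)
        assert registry.active["kidney_seg"] == 2
        assert registry.versions("kidney_seg") == [1, 2]  # history preserved

    def test_mapping_to_undefined_roi_rejected(self, seg_metadata):
        bare = Project()
        with pytest.raises(ModelImportError, match="kidney"):
            import_model(dict(seg_metadata), ModelRegistry(), bare)

    def test_missing_weights_rejected(self, seg_metadata):
        md = dict(seg_metadata)
        md["weights"] = "/nonexistent/weights.h5"
        with pytest.raises(ModelImportError):
            import_model(md, ModelRegistry())

    def test_plane_shape_mismatch_rejected(self, tmp_path, project):
        net = make_threshold_segmenter()
        net.input_shape = (32, 32, 1)
        weights = str(tmp_path / "shaped.h5")
        save_network(net, weights)
        md = {
            "name": "m", "weights": weights,
            "input": {"mode": "2d", "plane_shape": [16, 16]},
            "output": {"task": "segmentation", "mapping": {1: "kidney"}},
        }
        with pytest.raises(ModelImportError, match="plane_shape"):
            import_model(md, ModelRegistry(), project)

    def test_classification_mapping_validated_against_field(self, tmp_path):
        proj = Project()
        add_text_field(proj, "contrast_phase", ["arterial", "venous"])
        weights = str(tmp_path / "w.h5")
        save_network(make_threshold_segmenter(), weights)
        md = {
            "name": "phase", "weights": weights,
            "output": {"task": "classification",
                       "mapping": {0: {"field": "contrast_phase", "value": "oral"}}},
        }
        with pytest.raises(ModelImportError, match="oral"):
            import_model(md, ModelRegistry(), proj)


class TestPreprocess:
    def _spec(self, **kw):
        return ModelSpec(
            name="t", version=1, weights_ref=None,
            input=InputSpec(affine_ops=kw.get("ops", [])),
            normalization=NormalizationSpec(**kw.get("norm", {"method": "none"})),
            output=OutputSpec(),
        )

    def test_zscore_normalizes_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 10, size=(16, 16))
        out = preprocess(x, self._spec(norm={"method": "zscore"}))
        assert abs(out.mean()) < 1e-6 and abs(out.std() - 1) < 1e-6

    def test_fixed_window_clips_then_scales(self):
        spec = self._spec(norm={"method": "fixed_window", "window": (-100.0, 300.0)})
        out = preprocess(np.array([[500.0, -200.0, 100.0]]), spec)
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0 and out[0, 2] == pytest.approx(0.5)

    def test_constant_section_minmax_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            out = preprocess(np.full((4, 4), 7.0), self._spec(norm={"method": "minmax"}))
        assert not out.any()

    def test_rot_flip_composition_matches_index_permutation_oracle(self):
        x = np.arange(6, dtype=float).reshape(2, 3)
        spec = self._spec(ops=[{"rot90": 1}, "flip_x"])
        out = preprocess(x, spec)
        oracle = np.rot90(x, 1)[::-1, :]  # direct composition
        np.testing.assert_array_equal(out, oracle)

    def test_affine_ops_permute_without_loss(self):
        """flip/rot ops on a labeled index grid lose and duplicate nothing."""
        x = np.arange(20, dtype=float).reshape(4, 5)
        for ops in ([["flip_x"], ["flip_y"], [{"rot90": 2}], [{"rot90": 1}, "flip_y"]]):
            out = preprocess(x, self._spec(ops=ops))
            assert sorted(out.ravel().tolist()) == sorted(x.ravel().tolist())


class TestInference:
    def _seg_spec(self):
        return ModelSpec(
            name="t", version=1, weights_ref=None,
            input=InputSpec(mode="2d", axis="axial"),
            normalization=NormalizationSpec(method="minmax"),
            output=OutputSpec(task="segmentation", mapping={1: "kidney"}, rule="argmax"),
        )

    def test_threshold_net_equals_direct_thresholding(self, project, rng):
        """Draft labels equal thresholding the minmax-normalized volume at 0.5."""
        image = rng.normal(50, 20, size=(10, 12, 6))
        draft = infer(self._seg_spec(), image, project, predictor=make_threshold_segmenter())
        got = draft.roi_mask(1)
        oracle = np.zeros(image.shape, dtype=bool)
        for z in range(image.shape[2]):
            sl = image[:, :, z]
            oracle[:, :, z] = (sl - sl.min()) / (sl.max() - sl.min()) > 0.5
        np.testing.assert_array_equal(got, oracle)
        assert all(v == "auto" for v in draft.provenance.values())

    def test_locked_target_roi_rejected(self, project, rng):
        project.get_roi("kidney").locked = True
        with pytest.raises(LockedROIError):
            infer(self._seg_spec(), rng.normal(size=(6, 6, 3)), project,
                  predictor=make_threshold_segmenter())

    def test_channel_count_mismatch_rejected(self, project, rng):
        spec = self._seg_spec()
        spec.output.mapping = {5: "kidney"}  # model only outputs 2 channels
        with pytest.raises(ValidationError, match="channels"):
            infer(spec, rng.normal(size=(6, 6, 3)), project,
                  predictor=make_threshold_segmenter())

    def test_classification_writes_mapped_text_value(self, rng):
        proj = Project()
        add_text_field(proj, "contrast_phase", ["non-contrast", "venous"])
        proj.add_series(SeriesRecord(series_id="s1"))

        class TwoClass:
            def predict(self, section):
                return np.array([0.2, 0.8])  # class 1 always

        spec = ModelSpec(
            name="phase", version=1, weights_ref=None,
            input=InputSpec(mode="2d"),
            normalization=NormalizationSpec(),
            output=OutputSpec(task="classification",
                              mapping={0: ("contrast_phase", "non-contrast"),
                                       1: ("contrast_phase", "venous")}),
        )
        value = infer(spec, rng.normal(size=(6, 6, 3)), proj, series_id="s1",
                      predictor=TwoClass())
        assert value == "venous"
        assert proj.get_series("s1").text_values["contrast_phase"] == "venous"

    def test_inference_is_deterministic(self, project, rng):
        image = rng.normal(size=(8, 8, 4))
        d1 = infer(self._seg_spec(), image, project, predictor=make_threshold_segmenter())
        d2 = infer(self._seg_spec(), image, project, predictor=make_threshold_segmenter())
        np.testing.assert_array_equal(d1.labels, d2.labels)


class TestPatchInference:
    def _patch_spec(self, patch):
        return ModelSpec(
            name="p", version=1, weights_ref=None,
            input=InputSpec(mode="3d_patch", patch_shape=patch),
            normalization=NormalizationSpec(method="none"),
            output=OutputSpec(task="segmentation", mapping={1: "kidney"}, rule="argmax"),
        )

    def test_blend_weights_are_partition_of_unity(self):
        """After normalization, per-voxel blend weights sum to exactly 1 for
        every patch/volume layout tested: blending constant unit scores must
        return exactly 1 everywhere."""
        from annovox.models import blend_patch_scores

        for shape, patch in [((16, 16, 16), (8, 8, 8)), ((20, 14, 10), (8, 6, 4)),
                             ((9, 9, 9), (9, 9, 9)), ((13, 11, 7), (4, 4, 4))]:
            assert (blend_weights(shape, patch) > 0).all()  # every voxel covered
            blended = blend_patch_scores(
                np.zeros(shape), patch, lambda sub: np.ones(sub.shape + (2,))
            )
            np.testing.assert_allclose(blended, 1.0, atol=1e-12)

    def test_constant_volume_yields_uniform_blended_labels(self, project):
        """A translation-invariant model on a constant volume must produce a
        spatially uniform decision regardless of patch layout."""

        class ConstScore:
            def predict(self, patch):
                out = np.zeros(patch.shape[:3] + (2,))
                out[..., 1] = patch  # score = intensity
                out[..., 0] = 0.5
                return out

        image = np.full((12, 10, 8), 0.9)
        draft = infer(self._patch_spec((6, 6, 4)), image, project, predictor=ConstScore())
        assert draft.roi_mask(1).all()  # 0.9 > 0.5 everywhere, no seams
        image2 = np.full((12, 10, 8), 0.1)
        draft2 = infer(self._patch_spec((6, 6, 4)), image2, project, predictor=ConstScore())
        assert not draft2.labels.any()

    def test_patch_equal_to_volume_matches_single_shot(self, project, rng):
        image = rng.random((8, 8, 8))

        class Identity:
            def predict(self, patch):
                out = np.zeros(patch.shape[:3] + (2,))
                out[..., 1] = patch
                out[..., 0] = 0.5
                return out

        draft = infer(self._patch_spec((8, 8, 8)), image, project, predictor=Identity())
        np.testing.assert_array_equal(draft.roi_mask(1), image > 0.5)


class TestDiscovery:
    def test_discover_imports_and_is_idempotent(self, tmp_path, project, seg_metadata):
        registry = ModelRegistry()
        bundle_dir = str(tmp_path / "watched")
        md = dict(seg_metadata)
        md["version"] = 1
        write_bundle(md, bundle_dir)
        imported, reports = discover_models(registry, bundle_dir, project)
        assert [s.name for s in imported] == ["kidney_seg"] and not reports
        imported2, _ = discover_models(registry, bundle_dir, project)
        assert imported2 == []  # re-scan with no changes imports nothing

    def test_higher_version_drop_becomes_active(self, tmp_path, project, seg_metadata):
        registry = ModelRegistry()
        bundle_dir = str(tmp_path / "watched")
        for v in (1, 3):
            md = dict(seg_metadata)
            md["version"] = v
            write_bundle(md, bundle_dir, filename=f"kidney_seg_v{v}.yaml")
            discover_models(registry, bundle_dir, project)
        assert registry.active["kidney_seg"] == 3

    def test_malformed_bundle_skipped_not_fatal(self, tmp_path, project, seg_metadata):
        registry = ModelRegistry()
        bundle_dir = tmp_path / "watched"
        bundle_dir.mkdir()
        (bundle_dir / "broken.yaml").write_text("::: not yaml {")
        md = dict(seg_metadata)
        md["version"] = 1
        write_bundle(md, str(bundle_dir))
        imported, reports = discover_models(registry, str(bundle_dir), project)
        assert [s.name for s in imported] == ["kidney_seg"]
        assert len(reports) == 1 and "broken.yaml" in reports[0]


class TestCustomLoader:
    def test_registered_hook_supplies_predictor(self, project, rng):
        calls = []

        def hook(spec):
            calls.append(spec.name)
            return make_threshold_segmenter()

        register_loader("toy_hook", hook)
        spec = ModelSpec(
            name="hooked", version=1, weights_ref=None, custom_loader="toy_hook",
            input=InputSpec(mode="2d"),
            normalization=NormalizationSpec(method="minmax"),
            output=OutputSpec(task="segmentation", mapping={1: "kidney"}),
        )
        draft = infer(spec, rng.normal(size=(6, 6, 3)), project)
        assert calls == ["hooked"]
        assert draft.shape == (6, 6, 3)
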