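"""Raster/annotation I/O, depth-to-color alignment, hole filling."""

import numpy as np
import pytest

import weedspot as ws
from weedspot.camera import CameraRig, intrinsics_matrix
from weedspot.rgbd_io import (
    Annotation,
    AnnotationSet,
    DepthRaster,
    align_depth_to_color,
    fill_holes,
    read_depth_png,
    read_voc_annotations,
    write_depth_png,
    write_voc_annotations,
)


class TestVocXml:
    def test_roundtrip_preserves_boxes_and_classes(self, tmp_path, small_scene):
        path = tmp_path / "scene.xml"
        write_voc_annotations(small_scene.annotations, path)
        back = read_voc_annotations(path)
        assert back.image_size == small_scene.annotations.image_size
        assert back.labels() == small_scene.annotations.labels()
        np.testing.assert_allclose(back.boxes(), small_scene.annotations.boxes())

    def test_object_count_preserved(self, tmp_path, small_scene):
        path = tmp_path / "scene.xml"
        write_voc_annotations(small_scene.annotations, path)
        assert path.read_text().count("<object>") == len(small_scene.annotations.objects)

    def test_empty_annotation_list(self, tmp_path):
        path = tmp_path / "empty.xml"
        write_voc_annotations(AnnotationSet((50, 50), []), path)
        back = read_voc_annotations(path)
        assert back.objects == [] and back.image_size == (50, 50)

    def test_voc_one_based_inclusive_convention(self, tmp_path):
        # VOC (1,1,10,10) is 1-based inclusive -> internal half-open (0,0,10,10)
        path = tmp_path / "conv.xml"
        path.write_text(
            "<annotation><size><width>20</width><height>20</height></size>"
            "<object><name>grass</name><bndbox><xmin>1</xmin><ymin>1</ymin>"
            "<xmax>10</xmax><ymax>10</ymax></bndbox></object></annotation>"
        )
        back = read_voc_annotations(path)
        assert back.objects[0].box == (0.0, 0.0, 10.0, 10.0)

    def test_missing_class_name_reports_node(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<annotation><size><width>20</width><height>20</height></size>"
            "<object><bndbox><xmin>1</xmin><ymin>1</ymin>"
            "<xmax>5</xmax><ymax>5</ymax></bndbox></object></annotation>"
        )
        with pytest.raises(IOError, match="<object> #0.*<name>"):
            read_voc_annotations(path)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            Annotation("thistle", (0, 0, 5, 5))


class TestDepthPng:
    def test_lossless_roundtrip(self, tmp_path, small_scene):
        path = tmp_path / "d.png"
        write_depth_png(small_scene.depth, path)
        back = read_depth_png(path)
        np.testing.assert_array_equal(back.values, np.round(small_scene.depth.values))
        np.testing.assert_array_equal(back.valid_mask, small_scene.depth.valid_mask)

    def test_write_read_write_byte_identical(self, tmp_path, small_scene):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        write_depth_png(small_scene.depth, p1)
        write_depth_png(read_depth_png(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="16-bit"):
            write_depth_png(DepthRaster(np.full((4, 4), 70000.0)), tmp_path / "x.png")


def _rig(t=(0.0, 0.0, 0.0)):
    K = intrinsics_matrix(120.0, 120.0, 63.5, 63.5)
    return CameraRig(K_depth=K, K_color=K.copy(), R=np.eye(3), t=np.array(t))


class TestAlignment:
    def test_identity_rig_preserves_depth(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(500, 900, (128, 128)).round()
        depth = DepthRaster(vals)
        out = align_depth_to_color(depth, _rig(), (128, 128))
        # identity transform: each pixel maps to itself
        np.testing.assert_allclose(out.values[out.valid_mask], vals[out.valid_mask])
        assert out.valid_mask.mean() > 0.99

    def test_pure_translation_gives_analytic_disparity(self):
        # fronto-parallel plane at 700 mm, t = (50, 0, 0):
        # expected pixel shift = fx * tx / z = 120 * 50 / 700
        depth = DepthRaster(np.full((128, 128), 700.0))
        out = align_depth_to_color(depth, _rig(t=(50.0, 0.0, 0.0)), (128, 128))
        shift = 120.0 * 50.0 / 700.0
        vv, uu = np.mgrid[0:128, 0:128]
        expected_u = uu + shift
        inside = (expected_u >= 0) & (expected_u <= 127)
        # every valid output pixel keeps the metric value
        assert np.all(out.values[out.valid_mask] == pytest.approx(700.0))
        # the valid region is the shifted plane footprint within 0.5 px
        got_cols = np.nonzero(out.valid_mask.any(axis=0))[0]
        assert abs(got_cols.min() - np.ceil(shift - 0.5)) <= 1
        assert inside.sum() / 128 - 1 <= len(got_cols) <= inside.sum() / 128 + 1

    def test_all_invalid_input_gives_all_invalid_output(self):
        depth = DepthRaster(np.zeros((32, 32)))
        out = align_depth_to_color(depth, _rig(), (32, 32))
        assert not out.valid_mask.any()

    def test_z_buffer_nearer_surface_wins(self):
        # two depth pixels map to the same color pixel: K maps column u with
        # a coarse color grid; construct by shrinking the output
        vals = np.zeros((1, 2))
        vals[0, 0], vals[0, 1] = 800.0, 600.0
        K_d = intrinsics_matrix(100.0, 100.0, 0.5, 0.0)
        K_c = intrinsics_matrix(1e-6, 100.0, 0.0, 0.0)  # squashes all x to u=0
        rig = CameraRig(K_depth=K_d, K_color=K_c)
        out = align_depth_to_color(DepthRaster(vals), rig, (1, 1))
        assert out.values[0, 0] == pytest.approx(600.0)

    def test_metric_values_preserved(self, small_scene):
        filled = fill_holes(small_scene.depth)
        out = align_depth_to_color(filled, _rig(t=(20.0, -10.0, 0.0)), (96, 96))
        src = set(np.round(filled.values[filled.valid_mask]).astype(int).tolist())
        dst = set(np.round(out.values[out.valid_mask]).astype(int).tolist())
        assert dst <= src  # alignment moves values, never invents them


class TestHoleFilling:
    def test_no_holes_is_identity(self):
        depth = DepthRaster(np.full((16, 16), 700.0))
        out = fill_holes(depth)
        np.testing.assert_array_equal(out.values, depth.values)

    def test_single_hole_constant_neighborhood(self):
        vals = np.full((5, 5), 900.0)
        vals[2, 2] = 0.0
        out = fill_holes(DepthRaster(vals))
        assert out.values[2, 2] == pytest.approx(900.0)
        assert out.valid_mask.all()

    def test_scene_fully_filled_valid_untouched_in_range(self, small_scene, filled_depth):
        assert filled_depth.valid_mask.all()
        orig = small_scene.depth
        np.testing.assert_array_equal(
            filled_depth.values[orig.valid_mask], orig.values[orig.valid_mask]
        )
        lo, hi = orig.values[orig.valid_mask].min(), orig.values[orig.valid_mask].max()
        assert np.all(filled_depth.values >= lo) and np.all(filled_depth.values <= hi)

    def test_idempotent(self, filled_depth):
        again = fill_holes(filled_depth)
        np.testing.assert_array_equal(again.values, filled_depth.values)

    def test_accuracy_away_from_discontinuities(self):
        # at smooth regions the fill must track the noise-free surface to
        # within 3x the sensor noise; at canopy step edges the true side is
        # unknowable, so those pixels are excluded
        cfg = ws.SceneConfig(image_size=(128, 128), hole_fraction=0.1, seed=5)
        pair = ws.generate_scene(cfg)
        filled = fill_holes(pair.depth)
        gy, gx = np.gradient(pair.depth_clean)
        smooth = np.hypot(gx, gy) < 2.0  # mm per pixel
        holes = ~pair.depth.valid_mask & smooth
        err = filled.values[holes] - pair.depth_clean[holes]
        assert np.sqrt((err**2).mean()) < 3 * cfg.depth_noise_sd

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError, match="no valid pixels"):
            fill_holes(DepthRaster(np.zeros((8, 8))))


class TestCameraRig:
    def test_yaml_roundtrip(self, tmp_path):
        rig = _rig(t=(10.0, 5.0, -2.0))
        rig.save(tmp_path / "rig.yaml")
        back = CameraRig.load(tmp_path / "rig.yaml")
        np.testing.assert_allclose(back.K_depth, rig.K_depth)
        np.testing.assert_allclose(back.t, rig.t)

    def test_invalid_rotation_rejected(self):
        K = intrinsics_matrix(100.0, 100.0, 50.0, 50.0)
        with pytest.raises(ValueError, match="orthonormal"):
            CameraRig(K_depth=K, K_color=K, R=np.eye(3) * 2)

    def test_singular_intrinsics_rejected(self):
        with pytest.raises(ValueError):
            CameraRig(K_depth=np.zeros((3, 3)), K_color=np.eye(3))
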