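"""Synthetic scene generator: geometry, ground-truth consistency,
annotator consensus and dataset export round-trips."""

import json

import imageio.v3 as iio
import numpy as np
import pytest

from dewquant import (
    PlacementError,
    SceneConfig,
    TransformError,
    augment,
    generate_scene,
    simulate_annotators,
    write_dataset,
)
from dewquant.annotations import read_annotation, rasterize


def small_cfg(**kw):
    base = dict(
        image_width=96,
        image_height=96,
        n_droplets=2,
        droplet_diameter_range=(12, 20),
        background_kind="glass",
        seed=5,
    )
    base.update(kw)
    return SceneConfig(**base)


class TestGenerateScene:
    def test_empty_scene(self):
        img, gt = generate_scene(small_cfg(n_droplets=0))
        assert gt.per_droplet_area == []
        assert gt.droplet_label_map.sum() == 0
        assert np.all(gt.consensus_edges == 0)

    def test_circular_droplet_area_matches_disk(self):
        r = 12.0
        cfg = small_cfg(
            n_droplets=1,
            droplet_diameter_range=(2 * r, 2 * r),
            droplet_aspect_range=(1.0, 1.0),
        )
        _, gt = generate_scene(cfg)
        assert gt.per_droplet_area[0] == pytest.approx(np.pi * r * r, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        img1, gt1 = generate_scene(small_cfg())
        img2, gt2 = generate_scene(small_cfg())
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(gt1.droplet_label_map, gt2.droplet_label_map)
        np.testing.assert_array_equal(gt1.consensus_edges, gt2.consensus_edges)
        assert gt1.per_droplet_area == gt2.per_droplet_area

    def test_area_list_consistent_with_label_map(self):
        _, gt = generate_scene(small_cfg(n_droplets=3, seed=9))
        assert sum(gt.per_droplet_area) == int((gt.droplet_label_map > 0).sum())
        for i, area in enumerate(gt.per_droplet_area, start=1):
            assert area == int((gt.droplet_label_map == i).sum())

    def test_consensus_bounds_and_support(self):
        _, gt = generate_scene(small_cfg(n_droplets=3, annotators_k=3, seed=2))
        cons = gt.consensus_edges
        assert cons.min() >= 0.0 and cons.max() <= 1.0
        levels = np.unique(np.round(cons * 3))
        assert set(levels).issubset({0, 1, 2, 3})

    def test_impossible_placement_raises(self):
        cfg = small_cfg(n_droplets=40, droplet_diameter_range=(30, 40))
        with pytest.raises(PlacementError):
            generate_scene(cfg)

    def test_droplets_fully_inside_frame(self):
        _, gt = generate_scene(small_cfg(n_droplets=3, seed=3))
        lab = gt.droplet_label_map
        assert lab[0, :].sum() == 0 and lab[-1, :].sum() == 0
        assert lab[:, 0].sum() == 0 and lab[:, -1].sum() == 0


class TestSimulateAnnotators:
    def _line_mask(self):
        mask = np.zeros((15, 15), dtype=np.uint8)
        mask[7, 2:13] = 1
        return mask

    def test_single_annotator_no_jitter_is_identity(self):
        mask = self._line_mask()
        out = simulate_annotators(mask, k=1, jitter_px=0, seed=0)
        np.testing.assert_array_equal(out, mask.astype(float))

    def test_consensus_of_identical_annotators(self):
        mask = self._line_mask()
        out = simulate_annotators(mask, k=4, jitter_px=0, seed=0)
        np.testing.assert_array_equal(out, mask.astype(float))

    def test_jittered_consensus_stays_within_tolerance(self):
        mask = self._line_mask()
        out = simulate_annotators(mask, k=2, jitter_px=1, seed=1)
        true_coords = np.argwhere(mask)
        for r, c in np.argwhere(out > 0):
            dist = np.min(np.hypot(*(true_coords - (r, c)).T))
            assert dist <= 1.0 + 1e-9
        assert set(np.unique(out)).issubset({0.0, 0.5, 1.0})

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotators(self._line_mask(), k=0, jitter_px=0)


class TestAugment:
    def test_rotate_zero_is_identity(self):
        img, gt = generate_scene(small_cfg())
        img2, gt2 = augment(img, gt, "rotate", {"angle": 0})
        np.testing.assert_array_equal(img, img2)
        np.testing.assert_array_equal(gt.droplet_label_map, gt2.droplet_label_map)
        assert gt.per_droplet_area == gt2.per_droplet_area

    def test_scale_two_quadruples_area(self):
        img, gt = generate_scene(small_cfg(n_droplets=1))
        _, gt2 = augment(img, gt, "scale", {"factor": 2.0})
        assert gt2.per_droplet_area[0] == pytest.approx(
            4 * gt.per_droplet_area[0], rel=0.10
        )

    def test_rotation_preserves_droplet_count_and_area(self):
        img, gt = generate_scene(small_cfg(n_droplets=3, seed=4))
        _, gt2 = augment(img, gt, "rotate", {"angle": 37.0})
        assert len(gt2.per_droplet_area) == len(gt.per_droplet_area)
        assert sum(gt2.per_droplet_area) == pytest.approx(
            sum(gt.per_droplet_area), rel=0.10
        )

    def test_crop_without_droplet_raises(self):
        img, gt = generate_scene(small_cfg())
        with pytest.raises(TransformError):
            augment(img, gt, "crop", {"row": 0, "col": 0, "height": 3, "width": 3})

    def test_crop_keeps_consistency(self):
        img, gt = generate_scene(small_cfg(n_droplets=3, seed=8))
        img2, gt2 = augment(
            img, gt, "crop", {"row": 10, "col": 10, "height": 70, "width": 70}
        )
        assert img2.shape[:2] == gt2.droplet_label_map.shape
        assert sum(gt2.per_droplet_area) == int((gt2.droplet_label_map > 0).sum())


class TestWriteDataset:
    def test_manifest_and_files_exist(self, tmp_path):
        manifest = write_dataset(tmp_path, 2, small_cfg())
        assert manifest["n_scenes"] == 2
        for entry in manifest["scenes"]:
            for key in ("image", "labels", "consensus", "annotation"):
                assert (tmp_path / entry[key]).exists()
        with open(tmp_path / "manifest.json") as fh:
            assert json.load(fh)["n_scenes"] == 2

    def test_label_map_round_trip(self, tmp_path):
        manifest = write_dataset(tmp_path, 1, small_cfg(n_droplets=3, seed=6))
        entry = manifest["scenes"][0]
        labels = iio.imread(tmp_path / entry["labels"]).astype(np.int32)
        areas = [int((labels == i).sum()) for i in range(1, labels.max() + 1)]
        assert areas == entry["per_droplet_area"]

    def test_polygon_rasterization_matches_label_map(self, tmp_path):
        manifest = write_dataset(tmp_path, 1, small_cfg(n_droplets=2, seed=7))
        entry = manifest["scenes"][0]
        labels = iio.imread(tmp_path / entry["labels"]).astype(np.int32)
        record = read_annotation(tmp_path / entry["annotation"])
        raster, _ = rasterize(record)
        for i in range(1, labels.max() + 1):
            a = labels == i
            best_iou = max(
                (
                    ((a & (raster == j)).sum()) / ((a | (raster == j)).sum())
                    for j in range(1, raster.max() + 1)
                ),
                default=0.0,
            )
            assert best_iou >= 0.9
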