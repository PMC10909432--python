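"""Iron-blob segmentation/classification, distance stats, PPC fractions."""

import numpy as np
import pytest

from mpioquant.histo import (
    IronBlob,
    PositivePixelParams,
    classify_blob,
    count_per_fov,
    mpio_density,
    positive_pixel_fraction,
    segment_iron,
    vessel_distance_stats,
)
from mpioquant.synth.histology import HistoScene, generate_histo_scene, render_histo

BEAD_AREA = np.pi * 0.25


def scene_image(macs, beads=(), vessels=(((10.0, 10.0), 3.0),), field=(200.0, 200.0), ps=0.5):
    scene = HistoScene(field_size=field, vessels=list(vessels),
                       macrophages=list(macs), single_mpio=list(beads), pixel_size=ps)
    return render_histo(scene), scene


class TestSegmentIron:
    def test_blank_image_gives_no_blobs(self):
        image = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert segment_iron(image, pixel_size=0.5) == []

    def test_missing_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel_size"):
            segment_iron(np.zeros((8, 8, 3), dtype=np.uint8))

    def test_three_blobs_centroids_within_one_pixel(self):
        macs = [((50.0, 60.0), 20.0), ((120.0, 40.0), 12.0), ((80.0, 150.0), 30.0)]
        image, scene = scene_image(macs)
        blobs = segment_iron(image, pixel_size=scene.pixel_size)
        assert len(blobs) == 3
        got = sorted(b.centroid for b in blobs)
        for (gx, gy), ((tx, ty), _) in zip(got, sorted(macs)):
            assert abs(gx - tx) <= scene.pixel_size and abs(gy - ty) <= scene.pixel_size

    def test_blob_areas_match_disc_oracle(self):
        macs = [((60.0, 60.0), 25.0), ((140.0, 140.0), 10.0)]
        image, scene = scene_image(macs)
        blobs = segment_iron(image, pixel_size=scene.pixel_size)
        for blob, (_, true_area) in zip(sorted(blobs, key=lambda b: -b.area),
                                        sorted(macs, key=lambda m: -m[1])):
            assert blob.area == pytest.approx(true_area, rel=0.15)

    def test_vessels_and_background_are_not_segmented(self):
        image, scene = scene_image([], vessels=[((100.0, 100.0), 8.0)])
        assert segment_iron(image, pixel_size=scene.pixel_size) == []


class TestClassifyBlob:
    def test_one_bead_area_is_single(self):
        assert classify_blob(BEAD_AREA) == "single_mpio"

    def test_ten_bead_areas_is_aggregation(self):
        assert classify_blob(10 * BEAD_AREA) == "aggregation"

    def test_boundary_counts_as_aggregation(self):
        assert classify_blob(2 * BEAD_AREA) == "aggregation"
        assert classify_blob(2 * BEAD_AREA * (1 - 1e-9)) == "single_mpio"

    def test_blob_instance_gets_labelled(self):
        blob = IronBlob(centroid=(0.0, 0.0), area=50.0, n_pixels=200)
        assert classify_blob(blob) == "aggregation"
        assert blob.blob_class == "aggregation"

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            classify_blob(0.0)


class TestVesselDistanceStats:
    def test_three_four_five(self):
        stats = vessel_distance_stats(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        assert stats.distances[0] == pytest.approx(5.0)

    def test_median_and_fraction(self):
        macs = np.array([[5.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        stats = vessel_distance_stats(macs, np.array([[0.0, 0.0]]))
        assert stats.median == pytest.approx(10.0)
        assert stats.frac_within_25um == 1.0

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(11)
        macs = rng.uniform(0, 500, (200, 2))
        vessels = rng.uniform(0, 500, (10, 2))
        stats = vessel_distance_stats(macs, vessels)
        for i, (mx, my) in enumerate(macs):
            best = min(((mx - vx) ** 2 + (my - vy) ** 2) ** 0.5 for vx, vy in vessels)
            assert stats.distances[i] == pytest.approx(best, rel=1e-12)

    def test_cumulative_histogram_monotone_ending_at_one(self):
        rng = np.random.default_rng(12)
        stats = vessel_distance_stats(rng.uniform(0, 100, (50, 2)), np.array([[50.0, 50.0]]))
        assert np.all(np.diff(stats.cumulative_fraction) >= 0)
        assert stats.cumulative_fraction[-1] == pytest.approx(1.0)

    def test_no_vessels_rejected(self):
        with pytest.raises(ValueError):
            vessel_distance_stats(np.array([[0.0, 0.0]]), np.empty((0, 2)))


class TestMpioDensity:
    def test_zero_blobs(self):
        assert mpio_density([], 2.0) == 0.0

    def test_ten_singles_over_two_mm2(self):
        blobs = ["single_mpio"] * 10 + ["aggregation"] * 3
        assert mpio_density(blobs, 2.0) == pytest.approx(5.0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            mpio_density([], 0.0)

    def test_scene_recovery(self):
        """Known bound count recovered exactly on a disjoint synthetic scene."""
        scene = generate_histo_scene(10, 20, 15, seed=13, field_size=(800.0, 800.0))
        image = render_histo(scene)
        blobs = segment_iron(image, pixel_size=scene.pixel_size)
        for b in blobs:
            classify_blob(b)
        singles = [b for b in blobs if b.blob_class == "single_mpio"]
        assert len(singles) == 15
        assert mpio_density(blobs, 0.5) == pytest.approx(30.0)


class TestCountPerFov:
    def test_blank_fovs_all_zero(self):
        blank = np.full((32, 32, 3), 255, dtype=np.uint8)
        table, summary = count_per_fov([blank] * 8, pixel_size=0.5)
        assert (table["n_total"] == 0).all()
        assert summary == {"mean": 0.0, "sd": 0.0, "n_fov": 8}

    def test_counts_match_bead_numbers(self):
        images = []
        for n in (1, 2, 3):
            beads = [(30.0 + 20.0 * i, 100.0) for i in range(n)]
            image, _ = scene_image([], beads=beads)
            images.append(image)
        table, summary = count_per_fov(images, pixel_size=0.5)
        assert list(table["n_total"]) == [1, 2, 3]
        assert summary["mean"] == pytest.approx(2.0)
        assert summary["sd"] == pytest.approx(1.0)

    def test_counts_match_ground_truth_on_random_scenes(self):
        for seed in range(5):
            scene = generate_histo_scene(8, 25, 12, seed=seed, field_size=(700.0, 700.0))
            table, _ = count_per_fov([render_histo(scene)], pixel_size=scene.pixel_size)
            assert table.loc[0, "n_total"] == 25 + 12
            assert table.loc[0, "n_single_mpio"] == 12

    def test_no_images_rejected(self):
        with pytest.raises(ValueError):
            count_per_fov([], pixel_size=0.5)


class TestPositivePixelFraction:
    def test_uniform_moderate(self):
        image = np.full((20, 20), 190, dtype=np.uint8)
        res = positive_pixel_fraction(image)
        assert res.moderate_fraction == 1.0
        assert res.strong_fraction == 0.0
        assert res.positive_fraction == 1.0

    def test_uniform_strong(self):
        res = positive_pixel_fraction(np.full((20, 20), 5, dtype=np.uint8))
        assert res.strong_fraction == 1.0 and res.moderate_fraction == 0.0

    def test_window_boundaries_inclusive_and_strict(self):
        values = np.array([184, 185, 202, 203, 9, 10], dtype=np.uint8)
        res = positive_pixel_fraction(values)
        assert res.moderate_fraction == pytest.approx(2 / 6)
        assert res.strong_fraction == pytest.approx(1 / 6)

    def test_half_positive(self):
        image = np.concatenate([np.full(50, 190), np.full(50, 250)]).astype(np.uint8)
        assert positive_pixel_fraction(image).positive_fraction == pytest.approx(0.5)

    def test_rgb_uses_luma(self):
        # 0.299*190 + 0.587*190 + 0.114*190 = 190 -> moderate
        image = np.full((4, 4, 3), 190, dtype=np.uint8)
        assert positive_pixel_fraction(image).moderate_fraction == 1.0

    def test_invariant_to_roi_pixel_ordering_and_bounded(self):
        rng = np.random.default_rng(14)
        image = rng.integers(0, 256, (30, 30), dtype=np.uint8)
        mask = rng.uniform(size=image.shape) < 0.5
        res = positive_pixel_fraction(image, roi_mask=mask)
        shuffled = positive_pixel_fraction(image[mask][rng.permutation(mask.sum())])
        assert res.positive_fraction == pytest.approx(shuffled.positive_fraction)
        assert 0.0 <= res.positive_fraction <= 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            positive_pixel_fraction(np.zeros((5, 5)), roi_mask=np.zeros((5, 5), bool))

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            PositivePixelParams(moderate_low=210, moderate_high=202)
        with pytest.raises(ValueError):
            PositivePixelParams(strong_max=200)
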