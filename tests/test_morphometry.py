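"""Geometry metrics, size filtering, NN distances and tile aggregation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from mitoboot.morphometry import (
    MitoObject,
    SizeFilter,
    aggregate_tile,
    compute_object_metrics,
    filter_objects,
    frame_to_objects,
    nearest_neighbor_distances,
    normalize_to_control,
    objects_to_frame,
)


def _make_object(object_id, tile_id="t0", x=0.0, y=0.0, area=1.0):
    return MitoObject(
        object_id=object_id,
        tile_id=tile_id,
        centroid_x=x,
        centroid_y=y,
        area=area,
        feret_diameter=1.0,
        short_axis=0.5,
        long_axis=1.0,
        aspect_ratio=0.5,
    )


class TestComputeObjectMetrics:
    def test_solid_rectangle(self):
        """A 20x10 px rectangle at 0.05 um/px: area 0.5 um^2, aspect 0.5."""
        mask = np.zeros((30, 40), dtype=np.int32)
        mask[5:15, 5:25] = 1
        (obj,) = compute_object_metrics(mask, pixel_size=0.05)
        assert obj.area == pytest.approx(0.5)
        assert obj.aspect_ratio == pytest.approx(0.5, abs=1e-9)

    def test_square_feret_is_pixel_center_diagonal(self):
        """10x10 px square: Feret = 9 * 0.05 * sqrt(2) between corner centres."""
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[3:13, 3:13] = 1
        (obj,) = compute_object_metrics(mask, pixel_size=0.05)
        assert obj.feret_diameter == pytest.approx(9 * 0.05 * np.sqrt(2))

    def test_disc_aspect_ratio_near_one(self):
        rr, cc = np.mgrid[:101, :101]
        mask = (((rr - 50) ** 2 + (cc - 50) ** 2) <= 40**2).astype(np.int32)
        (obj,) = compute_object_metrics(mask, pixel_size=0.01)
        assert obj.aspect_ratio == pytest.approx(1.0, abs=1e-6)

    def test_empty_mask_and_format_errors(self):
        assert compute_object_metrics(np.zeros((5, 5), dtype=np.int16), 0.1) == []
        with pytest.raises(TypeError):
            compute_object_metrics(np.zeros((5, 5)), 0.1)  # float raster
        with pytest.raises(ValueError):
            compute_object_metrics(np.zeros((5, 5), dtype=np.int16), -1.0)

    def test_translation_invariance_and_scaling(self):
        """Metrics ignore image translation; area ~ px^2, Feret ~ px."""
        rng = np.random.default_rng(7)
        blob = (rng.random((12, 12)) > 0.4).astype(np.int32)
        blob[5, 5] = 1
        from scipy.ndimage import label

        lab, _ = label(blob)
        blob = (lab == lab[5, 5]).astype(np.int32)
        m1 = np.zeros((40, 40), dtype=np.int32)
        m2 = np.zeros((40, 40), dtype=np.int32)
        m1[2:14, 3:15] = blob
        m2[20:32, 18:30] = blob
        o1 = compute_object_metrics(m1, 0.05)[0]
        o2 = compute_object_metrics(m2, 0.05)[0]
        assert o1.area == o2.area
        assert o1.feret_diameter == pytest.approx(o2.feret_diameter)
        assert o1.aspect_ratio == pytest.approx(o2.aspect_ratio)
        o3 = compute_object_metrics(m1, 0.10)[0]
        assert o3.area == pytest.approx(4 * o1.area)
        assert o3.feret_diameter == pytest.approx(2 * o1.feret_diameter)

    def test_feret_matches_brute_force_on_random_blobs(self):
        """Convex-hull Feret equals the max over all pixel-centre pairs."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            mask = (rng.random((25, 25)) > 0.5).astype(np.int32)
            mask[0, 0] = 1
            coords = np.argwhere(mask > 0)
            brute = pdist(coords.astype(float)).max() * 0.04
            mask[mask > 0] = 1
            objs = compute_object_metrics(mask, 0.04)
            # single label covering all set pixels
            assert objs[0].feret_diameter == pytest.approx(brute, abs=1e-12)


class TestFilterObjects:
    @pytest.mark.parametrize(
        "area,kept",
        [(0.005, False), (0.01, True), (1.0, True), (2.1, True), (2.11, False)],
    )
    def test_boundaries_inclusive(self, area, kept):
        objs = filter_objects([_make_object(1, area=area)], SizeFilter())
        assert (len(objs) == 1) is kept

    def test_invalid_filter(self):
        with pytest.raises(ValueError):
            SizeFilter(min_area=2.0, max_area=1.0)


class TestNearestNeighbor:
    def test_two_points(self):
        objs = [_make_object(1, x=0, y=0), _make_object(2, x=3, y=4)]
        nearest_neighbor_distances(objs)
        assert objs[0].nn_distance == pytest.approx(5.0)
        assert objs[1].nn_distance == pytest.approx(5.0)

    def test_three_points_derived(self):
        objs = [
            _make_object(1, x=0, y=0),
            _make_object(2, x=3, y=4),
            _make_object(3, x=0, y=10),
        ]
        nearest_neighbor_distances(objs)
        assert [o.nn_distance for o in objs] == pytest.approx(
            [5.0, 5.0, np.sqrt(45)]
        )

    def test_singleton_tile_warns(self):
        objs = [_make_object(1)]
        with pytest.warns(UserWarning):
            nearest_neighbor_distances(objs)
        assert objs[0].nn_distance is None

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(3)
        objs = [
            _make_object(i, x=rng.uniform(0, 10), y=rng.uniform(0, 10))
            for i in range(60)
        ]
        nearest_neighbor_distances(objs)
        pts = np.array([[o.centroid_x, o.centroid_y] for o in objs])
        for i, obj in enumerate(objs):
            d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
            d[i] = np.inf
            assert obj.nn_distance == pytest.approx(d.min())


class TestAggregateTile:
    def test_count_and_total(self):
        objs = [_make_object(1, area=0.5), _make_object(2, area=0.25)]
        rec = aggregate_tile(
            objs, "t0", section_id="s", animal_id="a", genotype="CTL", layer="SR"
        )
        assert rec.mito_count == 2
        assert rec.total_mito_area == pytest.approx(0.75)

    def test_empty_tile(self):
        rec = aggregate_tile(
            [], "t0", section_id="s", animal_id="a", genotype="CTL", layer="SR"
        )
        assert rec.mito_count == 0 and rec.total_mito_area == 0

    def test_mixed_tiles_rejected(self):
        objs = [_make_object(1, tile_id="t0"), _make_object(2, tile_id="t1")]
        with pytest.raises(ValueError):
            aggregate_tile(
                objs, "t0", section_id="s", animal_id="a", genotype="CTL", layer="SR"
            )

    def test_filter_then_aggregate_commutes(self):
        """Aggregating a pre-filtered set equals filtering then aggregating."""
        rng = np.random.default_rng(5)
        objs = [_make_object(i, area=a) for i, a in enumerate(rng.uniform(0.001, 3, 50))]
        filt = SizeFilter()
        rec = aggregate_tile(
            filter_objects(objs, filt), "t0",
            section_id="s", animal_id="a", genotype="CTL", layer="SR",
        )
        kept = [o for o in objs if 0.01 <= o.area <= 2.1]
        assert rec.mito_count == len(kept)
        assert rec.total_mito_area == pytest.approx(sum(o.area for o in kept))


class TestNormalizeToControl:
    def test_examples(self):
        assert normalize_to_control([2, 4], [1, 3]).tolist() == [1.0, 2.0]
        ctl = np.array([1.0, 2.0, 3.0])
        assert normalize_to_control(ctl, ctl).mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        vals, ctl = rng.uniform(1, 5, 20), rng.uniform(1, 5, 30)
        np.testing.assert_allclose(
            normalize_to_control(vals, ctl), normalize_to_control(3 * vals, 3 * ctl)
        )

    def test_degenerate_control(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [])
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0, 0.0])


def test_object_frame_round_trip():
    objs = [_make_object(i, x=i, y=2 * i, area=0.3 + 0.1 * i) for i in range(4)]
    nearest_neighbor_distances(objs)
    back = frame_to_objects(objects_to_frame(objs))
    for a, b in zip(objs, back):
        assert a.area == b.area
        assert a.nn_distance == pytest.approx(b.nn_distance)
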