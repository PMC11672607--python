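"""Directional edge responses, edge zeroing, region isolation, centroids."""

import numpy as np
import pytest

from conftest import flood_fill_partition
from morphoseg import (
    BACKGROUND_LABEL,
    Image,
    QuantizedImage,
    center_of_mass,
    detect_edges_horizontal,
    detect_edges_vertical,
    extract_regions,
    merge_edge_maps,
    zero_edge_pixels,
)


def quantized_from_labels(labels):
    labels = np.asarray(labels, dtype=np.int32)
    colors = labels.astype(np.uint32)[:, :, np.newaxis]
    return QuantizedImage(colors, labels)


class TestDirectionalResponses:
    def test_constant_image_gives_zero_response(self):
        plane = np.full((7, 7), 50.0)
        assert not detect_edges_horizontal(plane).any()
        assert not detect_edges_vertical(plane).any()

    def test_horizontal_step_response_magnitude_four(self):
        """Two horizontal bands: |response| = 4 at the two rows adjacent to
        the boundary (hand-convolved step edge), 0 elsewhere."""
        plane = np.zeros((8, 8))
        plane[4:, :] = 1.0
        resp = detect_edges_horizontal(plane)
        interior = resp[:, 3]  # any interior column
        assert abs(interior[3]) == 4 and abs(interior[4]) == 4
        mask = np.ones(8, dtype=bool)
        mask[[3, 4]] = False
        assert np.all(interior[mask] == 0)

    def test_vertical_step_response_magnitude_four(self):
        plane = np.zeros((8, 8))
        plane[:, 4:] = 1.0
        resp = detect_edges_vertical(plane)
        interior = resp[3, :]
        assert abs(interior[3]) == 4 and abs(interior[4]) == 4

    def test_horizontal_bands_give_no_vertical_response(self):
        plane = np.zeros((8, 8))
        plane[4:, :] = 1.0
        assert not detect_edges_vertical(plane).any()

    def test_transpose_symmetry(self, rng):
        plane = rng.integers(0, 9, (10, 12)).astype(float)
        assert np.array_equal(
            detect_edges_vertical(plane.T), detect_edges_horizontal(plane).T
        )

    def test_translation_equivariance(self, rng):
        """Shifting the input (away from borders) shifts the response."""
        plane = np.zeros((16, 16))
        plane[4:8, 4:8] = 5.0
        shifted = np.roll(plane, (2, 3), axis=(0, 1))
        r0 = detect_edges_horizontal(plane)
        r1 = detect_edges_horizontal(shifted)
        assert np.array_equal(np.roll(r0, (2, 3), axis=(0, 1))[4:14, 4:14], r1[4:14, 4:14])

    def test_multi_channel_input_rejected(self, random_image):
        with pytest.raises(ValueError):
            detect_edges_horizontal(random_image(5, 5, 3))


class TestMergeEdgeMaps:
    def test_zero_responses_give_no_flags(self):
        emap = merge_edge_maps(np.zeros((4, 4)), np.zeros((4, 4)))
        assert not emap.flags.any()

    def test_single_direction_response_flags_pixel(self):
        h = np.zeros((3, 3))
        h[1, 1] = 0.5
        emap = merge_edge_maps(h, np.zeros((3, 3)), threshold=0)
        assert emap.flags[1, 1] and emap.flags.sum() == 1

    def test_flag_count_matches_elementwise_scan(self, rng):
        for _ in range(10):
            h = rng.normal(size=(6, 6))
            v = rng.normal(size=(6, 6))
            thr = 1.0
            emap = merge_edge_maps(h, v, threshold=thr)
            expect = sum(
                1
                for i in range(6)
                for j in range(6)
                if abs(h[i, j]) + abs(v[i, j]) > thr
            )
            assert int(emap.flags.sum()) == expect

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            merge_edge_maps(np.zeros((3, 3)), np.zeros((4, 4)))


class TestZeroEdgePixels:
    def test_empty_edge_map_is_identity(self, rng):
        q = quantized_from_labels(rng.integers(0, 4, (6, 6)))
        emap = merge_edge_maps(np.zeros((6, 6)), np.zeros((6, 6)))
        out = zero_edge_pixels(q, emap)
        assert np.array_equal(out.colors, q.colors)
        assert np.array_equal(out.labels, q.labels)

    def test_all_flagged_gives_background_everywhere(self, rng):
        q = quantized_from_labels(rng.integers(0, 4, (5, 5)))
        h = np.ones((5, 5))
        out = zero_edge_pixels(q, merge_edge_maps(h, h))
        assert np.all(out.labels == BACKGROUND_LABEL)
        assert np.all(out.colors == 0)

    def test_changed_pixel_conservation(self, rng):
        """Pixels changed = flagged pixels not already background."""
        labels = rng.integers(0, 3, (8, 8)).astype(np.int32)
        labels[0, :] = BACKGROUND_LABEL
        q = QuantizedImage(np.maximum(labels, 0).astype(np.uint32)[:, :, None], labels)
        h = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.4)
        emap = merge_edge_maps(h, np.zeros((8, 8)))
        out = zero_edge_pixels(q, emap)
        changed = int((out.labels != q.labels).sum())
        expect = int((emap.flags & (q.labels != BACKGROUND_LABEL)).sum())
        assert changed == expect


class TestExtractRegions:
    def test_two_disjoint_squares_same_color(self):
        labels = np.full((10, 10), BACKGROUND_LABEL, dtype=np.int32)
        labels[1:4, 1:4] = 2
        labels[6:9, 6:9] = 2
        regions = extract_regions(quantized_from_labels(labels))
        assert len(regions) == 2
        assert all(r.area == 9 for r in regions)

    def test_touching_squares_of_different_values_stay_separate(self):
        labels = np.full((6, 12), BACKGROUND_LABEL, dtype=np.int32)
        labels[1:5, 1:6] = 1
        labels[1:5, 6:11] = 2  # edge-touching, different palette value
        regions = extract_regions(quantized_from_labels(labels))
        assert len(regions) == 2
        assert {r.value[0] for r in regions} == {1, 2}

    def test_min_area_filter(self):
        labels = np.full((8, 8), BACKGROUND_LABEL, dtype=np.int32)
        labels[0, 0] = 1
        labels[3:6, 3:6] = 1
        regions = extract_regions(quantized_from_labels(labels), min_area=2)
        assert len(regions) == 1 and regions[0].area == 9

    def test_labels_in_raster_order_of_first_pixel(self):
        labels = np.full((5, 9), BACKGROUND_LABEL, dtype=np.int32)
        labels[3, 0:2] = 1  # later raster position
        labels[0, 5:8] = 2  # earliest raster position
        regions = extract_regions(quantized_from_labels(labels))
        assert regions[0].value[0] == 2 and regions[0].label == 1
        assert regions[1].value[0] == 1 and regions[1].label == 2

    @pytest.mark.parametrize("connectivity", [1, 2])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        """Partition equality with an independent flood fill on random
        quantized label images."""
        for _ in range(20):
            labels = rng.integers(-1, 3, (32, 32)).astype(np.int32)
            regions = extract_regions(
                quantized_from_labels(labels), connectivity=connectivity
            )
            oracle = flood_fill_partition(
                labels, BACKGROUND_LABEL, connectivity=connectivity
            )
            assert len(regions) == len(oracle)
            for reg, (mask, value) in zip(regions, oracle):
                assert np.array_equal(reg.mask, mask)
                assert reg.value[0] == value

    def test_partition_covers_foreground_exactly(self, rng):
        labels = rng.integers(-1, 4, (20, 20)).astype(np.int32)
        regions = extract_regions(quantized_from_labels(labels))
        total = sum(r.area for r in regions)
        assert total == int((labels != BACKGROUND_LABEL).sum())
        stack = np.zeros((20, 20), dtype=int)
        for r in regions:
            stack += r.mask
        assert stack.max() <= 1  # no pixel in two regions


class TestCenterOfMass:
    def test_symmetric_square(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0:3, 0:3] = True
        assert center_of_mass(mask) == (1.0, 1.0)

    def test_three_pixel_l_shape(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[1, 0] = mask[1, 1] = True
        r, c = center_of_mass(mask)
        assert r == pytest.approx(2 / 3) and c == pytest.approx(1 / 3)

    def test_solid_rectangle_closed_form(self):
        a, b, c, d = 2, 6, 3, 9
        mask = np.zeros((10, 12), dtype=bool)
        mask[a : b + 1, c : d + 1] = True
        assert center_of_mass(mask) == ((a + b) / 2, (c + d) / 2)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            mask = rng.random((9, 9)) < 0.4
            if not mask.any():
                continue
            coords = [(i, j) for i in range(9) for j in range(9) if mask[i, j]]
            er = sum(p[0] for p in coords) / len(coords)
            ec = sum(p[1] for p in coords) / len(coords)
            assert center_of_mass(mask) == (pytest.approx(er), pytest.approx(ec))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((3, 3), dtype=bool))
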