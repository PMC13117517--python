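"""Segmentation pipeline against rasterized ground truth: disk areas,
area-filter boundary behavior, level-0 scaling arithmetic, tessellation
versus a brute-force center-in-polygon scan, and monotonicity in the
thresholds."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from attnmil import synthdata, tissueseg
from attnmil.synthdata import ImageSimConfig
from attnmil.tissueseg import (
    PatchGrid,
    SegParams,
    TissueMask,
    filter_contours_by_area,
    rasterize_mask,
    scale_contours_to_level0,
    segment_tissue,
    tessellate,
)


def _square(x0, y0, side):
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
                    dtype=float)


class TestSegmentTissue:
    def test_uniform_white_no_contours(self):
        img = np.full((128, 128, 3), 250, dtype=np.uint8)
        mask = segment_tissue(img, SegParams())
        assert mask.contours == [] and mask.holes == []

    def test_disk_area_within_two_percent(self):
        r = 100
        img, _, _ = synthdata.generate_tissue_image(
            ImageSimConfig(canvas_size=(300, 300), blobs=[((150, 150), r, 220)]))
        mask = segment_tissue(img, SegParams(athresh=100))
        assert len(mask.contours) == 1
        area = Polygon(mask.contours[0]).area
        assert area == pytest.approx(np.pi * r * r, rel=0.02)

    def test_hole_area_filter_boundary(self):
        # a hole well below hole_athresh is absorbed; one above is retained
        big = ImageSimConfig(canvas_size=(300, 300), blobs=[((150, 150), 100, 220)],
                             holes=[((150, 150), 20)])
        img, _, _ = synthdata.generate_tissue_image(big)
        hole_area = np.pi * 20 ** 2
        kept = segment_tissue(img, SegParams(hole_athresh=hole_area * 0.8))
        absorbed = segment_tissue(img, SegParams(hole_athresh=hole_area * 1.2))
        assert len(kept.holes) == 1
        assert absorbed.holes == []

    def test_iou_against_ground_truth(self):
        cfg = ImageSimConfig(
            canvas_size=(400, 400),
            blobs=[((120, 120), 80, 230), ((290, 280), 70, 200)],
            holes=[((120, 120), 25)],
            artifacts=[((350, 60), 2), ((40, 350), 2)],
        )
        img, truth, _ = synthdata.generate_tissue_image(cfg)
        mask = segment_tissue(img, SegParams(athresh=100, hole_athresh=16))
        recovered = rasterize_mask(mask, truth.shape)
        iou = (recovered & truth).sum() / (recovered | truth).sum()
        assert iou >= 0.95

    def test_determinism(self):
        img, _, _ = synthdata.generate_tissue_image(
            ImageSimConfig(canvas_size=(200, 200), blobs=[((100, 100), 60, 210)]))
        m1 = segment_tissue(img, SegParams())
        m2 = segment_tissue(img, SegParams())
        for a, b in zip(m1.contours, m2.contours):
            np.testing.assert_array_equal(a, b)

    def test_monotonicity_in_thresholds(self):
        cfg = ImageSimConfig(canvas_size=(300, 300),
                             blobs=[((80, 80), 50, 120), ((220, 210), 60, 60)])
        img, _, _ = synthdata.generate_tissue_image(cfg)
        n_contours = []
        for athresh in (10, 1000, 10_000):
            n_contours.append(len(segment_tissue(img, SegParams(athresh=athresh)).contours))
        assert n_contours == sorted(n_contours, reverse=True)
        areas = []
        for sthresh in (8, 40, 80, 200):
            m = segment_tissue(img, SegParams(sthresh=sthresh, athresh=10))
            areas.append(rasterize_mask(m, (300, 300)).sum())
        assert areas == sorted(areas, reverse=True)


class TestFilterContours:
    def test_all_below_threshold(self):
        contours = [_square(0, 0, 5), _square(20, 20, 4)]
        tissue, holes, _ = filter_contours_by_area(contours, [-1, -1], 100, 10)
        assert tissue == [] and holes == []

    def test_parent_and_child_kept(self):
        parent = _square(0, 0, 50)
        child = _square(10, 10, 10)
        tissue, holes, parents = filter_contours_by_area([parent, child], [-1, 0], 100, 50)
        assert len(tissue) == 1 and len(holes) == 1 and parents == [0]

    def test_boundary_inclusive_at_athresh(self):
        # areas 99, 100, 101 against athresh 100: exactly two kept (>= rule)
        sides = [np.sqrt(99), 10.0, np.sqrt(101)]
        contours = [_square(60 * i, 0, s) for i, s in enumerate(sides)]
        tissue, _, _ = filter_contours_by_area(contours, [-1, -1, -1], 100.0, 10)
        assert len(tissue) == 2

    def test_hierarchy_length_mismatch(self):
        with pytest.raises(ValueError):
            filter_contours_by_area([_square(0, 0, 5)], [-1, -1], 1, 1)

    def test_orphan_hole_dropped_with_parent(self):
        parent = _square(0, 0, 5)     # below athresh
        child = _square(1, 1, 3)
        tissue, holes, _ = filter_contours_by_area([parent, child], [-1, 0], 100, 1)
        assert tissue == [] and holes == []


class TestScaleContours:
    def test_identity_and_arithmetic(self):
        c = [np.array([[10.0, 20.0], [1.0, 2.0]])]
        np.testing.assert_array_equal(scale_contours_to_level0(c, 1)[0], [[10, 20], [1, 2]])
        np.testing.assert_array_equal(scale_contours_to_level0(c, 4)[0], [[40, 80], [4, 8]])

    def test_float_vs_int_downsample(self):
        c = [np.array([[3.0, 7.0]])]
        np.testing.assert_array_equal(scale_contours_to_level0(c, 4)[0],
                                      scale_contours_to_level0(c, 4.0)[0])

    def test_round_half_away_from_zero(self):
        c = [np.array([[1.0, 3.0]])]
        np.testing.assert_array_equal(scale_contours_to_level0(c, 2.5)[0], [[3, 8]])


class TestTessellate:
    def test_full_tissue_1024_gives_16_patches(self):
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        img[:, :] = [200, 30, 200]  # fully saturated
        mask = segment_tissue(img, SegParams(athresh=100))
        grid = tessellate(mask, 256, (1024, 1024))
        assert len(grid.coords) == 16
        expected = {(x * 256, y * 256) for x in range(4) for y in range(4)}
        assert set(map(tuple, grid.coords)) == expected

    def test_empty_mask_zero_patches(self):
        mask = TissueMask(contours=[], holes=[])
        assert len(tessellate(mask, 256, (1024, 1024)).coords) == 0

    def test_bad_patch_size(self):
        with pytest.raises(ValueError):
            tessellate(TissueMask(contours=[], holes=[]), 0, (100, 100))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_center_scan(self, seed):
        rng = np.random.default_rng(seed)
        blobs = [((float(rng.integers(60, 240)), float(rng.integers(60, 240))),
                  float(rng.integers(30, 55)), 220) for _ in range(2)]
        img, _, _ = synthdata.generate_tissue_image(
            ImageSimConfig(canvas_size=(300, 300), blobs=blobs))
        mask = segment_tissue(img, SegParams(athresh=50))
        ps = 16
        grid = tessellate(mask, ps, (300, 300))
        polys = [Polygon(c) for c in mask.contours]
        hole_polys = [Polygon(c) for c in mask.holes]
        expected = set()
        for x in range(0, 300 - ps + 1, ps):
            for y in range(0, 300 - ps + 1, ps):
                p = Point(x + ps / 2, y + ps / 2)
                if any(poly.contains(p) for poly in polys) and \
                        not any(h.contains(p) for h in hole_polys):
                    expected.add((x, y))
        assert set(map(tuple, grid.coords)) == expected

    def test_patches_disjoint_and_inside_extent(self):
        img, _, _ = synthdata.generate_tissue_image(
            ImageSimConfig(canvas_size=(200, 200), blobs=[((100, 100), 70, 220)]))
        mask = segment_tissue(img, SegParams())
        grid = tessellate(mask, 32, (200, 200))
        coords = set(map(tuple, grid.coords))
        assert len(coords) == len(grid.coords)  # unique => disjoint (grid-aligned)
        for x, y in coords:
            assert 0 <= x and x + 32 <= 200 and 0 <= y and y + 32 <= 200
            assert x % 32 == 0 and y % 32 == 0
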