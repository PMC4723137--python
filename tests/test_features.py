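"""Bin partitioning, region morphometry, per-bin feature aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marginmap import bin_features, partition_bins, region_shape_stats
from marginmap.features import filter_regions_by_diameter, features_to_dataframe
from marginmap.mser import Region, region_overlay


def square_region(r0, c0, size, level=100):
    px = np.argwhere(np.ones((size, size), bool)) + [r0, c0]
    return Region(pixels=px, level=level, stability=0.0)


class TestPartition:
    @pytest.mark.parametrize(
        "w,h,b,nbins",
        [(350, 300, 50, 42), (50, 50, 50, 1), (349, 300, 50, 36), (120, 80, 40, 6)],
    )
    def test_bin_counts(self, w, h, b, nbins):
        grid = partition_bins(w, h, b)
        assert grid.n_bins == nbins
        assert grid.n_rows == h // b and grid.n_cols == w // b

    def test_bins_disjoint_and_anchored(self):
        grid = partition_bins(101, 73, 20)
        seen = set()
        for br in range(grid.n_rows):
            for bc in range(grid.n_cols):
                r0, r1, c0, c1 = grid.bin_extent(br, bc)
                assert r1 - r0 == 20 and c1 - c0 == 20
                cells = {(r, c) for r in range(r0, r1) for c in range(c0, c1)}
                assert not (cells & seen)
                seen |= cells
        assert len(seen) == grid.n_rows * grid.n_cols * 400

    def test_bin_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            partition_bins(40, 60, 50)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 400), st.integers(1, 400), st.integers(1, 100))
    def test_floor_rule(self, w, h, b):
        if b > min(w, h):
            with pytest.raises(ValueError):
                partition_bins(w, h, b)
        else:
            assert partition_bins(w, h, b).n_bins == (w // b) * (h // b)


class TestShapeStats:
    def test_single_pixel(self):
        d, p, s = region_shape_stats(square_region(0, 0, 1), pitch_um=1.5)
        assert d == pytest.approx(2 * np.sqrt(1 / np.pi) * 1.5, rel=1e-12)
        assert p == pytest.approx(6.0)
        assert s == pytest.approx(6.0 / 2.25)

    def test_3x3_square(self):
        d, p, s = region_shape_stats(square_region(5, 5, 3), pitch_um=1.5)
        assert d == pytest.approx(2 * np.sqrt(9 / np.pi) * 1.5, rel=1e-12)
        assert p == pytest.approx(18.0)  # 12 boundary edges * 1.5 um
        assert s == pytest.approx(18.0 / 20.25)

    def test_pitch_scaling(self):
        r = square_region(0, 0, 3)
        d1, p1, s1 = region_shape_stats(r, pitch_um=1.0)
        dk, pk, sk = region_shape_stats(r, pitch_um=3.0)
        assert dk == pytest.approx(3 * d1) and pk == pytest.approx(3 * p1)
        assert sk == pytest.approx(s1 / 3)

    def test_l_shaped_region_perimeter(self):
        # 3 pixels in an L: 8 exposed edges
        px = np.array([[0, 0], [1, 0], [1, 1]])
        r = Region(pixels=px, level=1, stability=0.0)
        _, p, _ = region_shape_stats(r, pitch_um=1.0)
        assert p == 8.0


class TestBinFeatures:
    def test_no_regions_all_empty(self):
        grid = partition_bins(350, 300, 50)
        feats = bin_features([], grid, 1.5)
        assert len(feats) == 42
        assert all(f.empty and f.area_fraction == 0 and f.n_regions == 0 for f in feats)
        assert all(f.avg_diameter_um == 0 and f.avg_shape_per_um == 0 for f in feats)

    def test_single_interior_region(self):
        grid = partition_bins(350, 300, 50)
        feats = bin_features([square_region(60, 60, 3)], grid, 1.5)
        target = [f for f in feats if f.bin_row == 1 and f.bin_col == 1][0]
        assert target.area_fraction == pytest.approx(9 / 2500)
        assert target.avg_diameter_um == pytest.approx(2 * np.sqrt(9 / np.pi) * 1.5)
        assert target.avg_shape_per_um == pytest.approx(18 / 20.25)
        assert target.n_regions == 1 and not target.empty
        assert sum(not f.empty for f in feats) == 1

    def test_area_conservation_across_bins(self):
        rng = np.random.default_rng(4)
        regions = [
            square_region(int(rng.integers(0, 290)), int(rng.integers(0, 340)), int(rng.integers(1, 6)))
            for _ in range(25)
        ]
        grid = partition_bins(350, 300, 50)
        feats = bin_features(regions, grid, 1.5)
        mask_px = int(region_overlay(regions, (300, 350)).sum())
        assert sum(f.area_fraction for f in feats) * 2500 == pytest.approx(mask_px)

    def test_straddling_region_splits_area_but_not_shape(self):
        # 4x4 square across the (0,0)/(0,1) bin boundary: centroid in bin (0,0)
        grid = partition_bins(100, 100, 50)
        r = square_region(10, 47, 4)
        feats = {(f.bin_row, f.bin_col): f for f in bin_features([r], grid, 1.5)}
        assert feats[(0, 0)].area_fraction == pytest.approx(12 / 2500)
        assert feats[(0, 1)].area_fraction == pytest.approx(4 / 2500)
        assert feats[(0, 0)].n_regions == 1
        assert feats[(0, 1)].n_regions == 0 and not feats[(0, 1)].empty
        assert feats[(0, 1)].avg_diameter_um == 0.0

    def test_translation_by_one_bin_permutes_features(self):
        rng = np.random.default_rng(9)
        regions = [
            square_region(int(rng.integers(0, 45)), int(rng.integers(0, 95)), 3)
            for _ in range(8)
        ]
        shifted = [
            Region(pixels=r.pixels + [50, 0], level=r.level, stability=0.0)
            for r in regions
        ]
        grid = partition_bins(100, 150, 50)
        f0 = bin_features(regions, grid, 1.5)
        f1 = bin_features(shifted, grid, 1.5)
        by_rc0 = {(f.bin_row, f.bin_col): f for f in f0}
        by_rc1 = {(f.bin_row, f.bin_col): f for f in f1}
        for (br, bc), f in by_rc0.items():
            if br + 1 < grid.n_rows:
                g = by_rc1[(br + 1, bc)]
                assert g.area_fraction == pytest.approx(f.area_fraction)
                assert g.avg_diameter_um == pytest.approx(f.avg_diameter_um)
                assert g.n_regions == f.n_regions


class TestDiameterFilter:
    def test_modes_partition_the_input(self):
        regions = [square_region(0, 0, s) for s in (1, 3, 6, 9)]
        lt = filter_regions_by_diameter(regions, 1.5, "lt")
        ge = filter_regions_by_diameter(regions, 1.5, "ge")
        assert len(lt) + len(ge) == len(regions)
        assert {id(r) for r in lt} | {id(r) for r in ge} == {id(r) for r in regions}
        # 6x6 -> 10.16 um, 9x9 -> 15.2 um: both at/above the 10 um cutoff
        assert [r.area_px for r in lt] == [1, 9]

    def test_empty_input_and_bad_mode(self):
        assert filter_regions_by_diameter([], 1.5, "lt") == []
        with pytest.raises(ValueError):
            filter_regions_by_diameter([], 1.5, "between")


def test_feature_dataframe_columns():
    grid = partition_bins(100, 100, 50)
    df = features_to_dataframe(bin_features([], grid, 1.5), image_id="x", label=0)
    assert list(df.columns) == [
        "image_id", "bin_row", "bin_col", "area_fraction", "avg_diameter_um",
        "avg_shape_per_um", "n_regions", "empty", "label",
    ]
    assert len(df) == 4
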