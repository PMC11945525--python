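"""Thickness pipeline: cleaning, skeleton, central axis, width recovery."""

import numpy as np
import pytest

from stripseg.thickness import (
    central_axis,
    clean_mask,
    extract_skeleton,
    measure,
    thickness_profile,
)

from .conftest import straight_ribbon
from .oracles import brute_force_diameter_path


class TestCleanMask:
    def test_solid_rectangle_unchanged(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[10:30, 5:35] = 1
        np.testing.assert_array_equal(clean_mask(m, min_area=0), m)

    def test_interior_hole_filled(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[10:30, 5:35] = 1
        m[20, 20] = 0
        assert clean_mask(m, radius=2, min_area=0)[20, 20] == 1

    def test_empty_mask_passes_through(self):
        z = np.zeros((16, 16), dtype=np.uint8)
        np.testing.assert_array_equal(clean_mask(z), z)

    def test_small_components_removed(self):
        m = np.zeros((64, 64), dtype=np.uint8)
        m[10:40, 10:14] = 1    # 120 px ribbon
        m[55:58, 55:58] = 1    # 9 px speck
        cleaned = clean_mask(m, radius=0, min_area=64)
        assert cleaned[56, 56] == 0 and cleaned[20, 11] == 1


class TestExtractSkeleton:
    def test_ribbon_skeleton_is_single_path_near_centerline(self):
        mask = straight_ribbon(9)
        sk = extract_skeleton(mask)
        rows = np.array([n[0] for n in sk.nodes])
        assert len(sk.components) == 1
        assert np.abs(rows - 50).max() <= 1
        assert sk.skeleton.sum() < mask.sum()

    def test_degenerate_blob_single_node_or_tiny(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[3:6, 3:6] = 1
        sk = extract_skeleton(m)
        assert 1 <= sk.graph.number_of_nodes() <= 5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_skeleton(np.zeros((8, 8)))

    def test_skeleton_is_thin(self):
        sk = extract_skeleton(straight_ribbon(13))
        s = sk.skeleton.astype(int)
        # no skeleton pixel has a fully occupied 3x3 neighbourhood
        from scipy import ndimage

        full = ndimage.uniform_filter(s.astype(float), 3) > 0.999
        assert not (full & (s > 0)).any()


class TestCentralAxis:
    def _graph_from_pixels(self, pixels):
        import networkx as nx

        from stripseg.thickness import SkeletonGraph

        g = nx.Graph()
        g.add_nodes_from(pixels)
        for (r, c) in pixels:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) != (0, 0) and (r + dr, c + dc) in pixels:
                        g.add_edge((r, c), (r + dr, c + dc))
        canvas = np.zeros((64, 64), dtype=bool)
        for (r, c) in pixels:
            canvas[r, c] = True
        comps = [set(cc) for cc in nx.connected_components(g)]
        return SkeletonGraph(graph=g, skeleton=canvas, components=comps)

    def test_straight_line_is_its_own_axis(self):
        pixels = {(10, c) for c in range(5, 30)}
        axis = central_axis(self._graph_from_pixels(pixels))
        assert len(axis) == 25
        assert set(map(tuple, axis)) == pixels

    def test_t_shape_takes_the_two_long_arms(self):
        # T: long horizontal bar of 21 (two arms of 10 around a junction),
        # short vertical stem of 4
        pixels = {(20, c) for c in range(10, 31)} | {(r, 20) for r in range(21, 25)}
        sk = self._graph_from_pixels(pixels)
        axis = central_axis(sk)
        oracle = brute_force_diameter_path(list(sk.graph.nodes), set(sk.graph.edges))
        assert len(axis) == len(oracle) == 21
        assert axis[0].tolist() in ([20, 10], [20, 30])

    def test_y_shape_path_at_least_longest_branch(self):
        pixels = (
            {(r, 20) for r in range(10, 25)}
            | {(24 + k, 20 - k) for k in range(1, 8)}
            | {(24 + k, 20 + k) for k in range(1, 10)}
        )
        sk = self._graph_from_pixels(pixels)
        axis = central_axis(sk)
        assert len(axis) >= 15

    def test_single_node_warns(self):
        sk = self._graph_from_pixels({(5, 5)})
        with pytest.warns(UserWarning):
            axis = central_axis(sk)
        assert len(axis) == 1

    def test_cycle_guard_returns_simple_path(self):
        # a ring with a tail: cyclic graph exercises the fallback search
        ring = {(10 + int(6 * np.sin(t)), 20 + int(6 * np.cos(t)))
                for t in np.linspace(0, 2 * np.pi, 60)}
        tail = {(10, c) for c in range(27, 40)}
        sk = self._graph_from_pixels(ring | tail)
        axis = central_axis(sk)
        assert len(axis) == len({tuple(a) for a in axis})  # simple path
        assert len(axis) >= len(tail)


class TestThicknessProfile:
    @pytest.mark.parametrize("width", [5, 7, 9, 13])
    def test_constant_width_recovered_within_one_pixel(self, width):
        mask = straight_ribbon(width)
        sk = extract_skeleton(mask)
        axis = central_axis(sk)
        prof = thickness_profile(mask, axis, trim=5)
        assert abs(prof.summary["mean"] - width) <= 1.0
        assert (prof.thickness_px > 0).all()

    def test_nm_scaling_exact(self):
        mask = straight_ribbon(9)
        axis = central_axis(extract_skeleton(mask))
        prof = thickness_profile(mask, axis, nm_per_px=2.5)
        np.testing.assert_allclose(prof.thickness_nm, prof.thickness_px * 2.5)
        assert prof.summary["mean_nm"] == pytest.approx(prof.summary["mean"] * 2.5)

    def test_width_three_ribbon(self):
        mask = straight_ribbon(3)
        axis = central_axis(extract_skeleton(mask))
        prof = thickness_profile(mask, axis, trim=5)
        assert abs(prof.summary["mean"] - 3) <= 1.0

    def test_rotated_ribbon_within_discretization_allowance(self):
        from skimage.transform import rotate

        mask = straight_ribbon(9, canvas=160, row=80, col_span=(20, 140))
        rot = rotate(mask.astype(float), 45, resize=False, order=0) > 0.5
        axis = central_axis(extract_skeleton(rot))
        prof = thickness_profile(rot, axis, trim=8)
        assert abs(prof.summary["mean"] - 9) <= 1.5

    def test_dilation_increases_thickness_by_two(self):
        from skimage import morphology

        mask = straight_ribbon(9)
        axis = central_axis(extract_skeleton(mask))
        base = thickness_profile(mask, axis, trim=5)
        dilated = morphology.dilation(mask.astype(bool), morphology.disk(1))
        grown = thickness_profile(dilated, axis, trim=5)
        assert grown.summary["mean"] - base.summary["mean"] == pytest.approx(2.0, abs=0.5)

    def test_axis_on_background_rejected(self):
        mask = straight_ribbon(9)
        with pytest.raises(ValueError):
            thickness_profile(mask, np.array([[0, 0], [1, 1]]))


class TestMeasure:
    def test_csv_row_count_matches_trimmed_axis(self, tmp_path):
        import pandas as pd

        mask = straight_ribbon(9)
        prof = measure(mask, trim=5, out_csv=tmp_path / "p.csv")
        df = pd.read_csv(tmp_path / "p.csv")
        assert len(df) == len(prof.axis)
        assert list(df.columns) == ["index", "row", "col", "thickness_px", "thickness_nm"]

    def test_repeated_runs_identical_csv(self, tmp_path):
        mask = straight_ribbon(7)
        measure(mask, out_csv=tmp_path / "a.csv")
        measure(mask, out_csv=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_two_ribbons_longest_wins_with_warning(self):
        m = np.zeros((128, 128), dtype=np.uint8)
        m[20:27, 10:118] = 1   # long ribbon
        m[100:107, 30:60] = 1  # short ribbon
        with pytest.warns(UserWarning, match="components"):
            prof = measure(m, trim=5)
        assert np.abs(prof.axis[:, 0] - 23).max() <= 1

    def test_empty_after_cleaning_raises(self):
        with pytest.raises(ValueError):
            measure(np.zeros((32, 32), dtype=np.uint8))

    def test_synthetic_ribbon_fixture_roundtrip(self, default_sample, tmp_path):
        prof = measure(default_sample.mask, trim=5, out_csv=tmp_path / "s.csv",
                       out_plot=tmp_path / "s.png")
        widths = default_sample.meta["widths"]
        assert widths.min() - 1.5 <= prof.summary["median"] <= widths.max() + 1.5
        assert (tmp_path / "s.png").exists()

    def test_generator_and_measurer_agree_on_constant_width(self):
        """Width-fidelity contract between the simulator and the measurement."""
        from stripseg.synthetic import make_ribbon_mask

        pts = np.array([[60.0, 10.0], [65.0, 60.0], [60.0, 110.0]])
        mask, _ = make_ribbon_mask(pts, 9.0, 128)
        prof = measure(mask, trim=8)
        assert abs(prof.summary["mean"] - 9.0) <= 1.0
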