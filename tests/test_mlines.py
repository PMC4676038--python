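"""M-line ingestion, axis estimation and the reconstruction pipeline."""

import numpy as np
import pytest

from shgvernier import (
    ImageGrid,
    estimate_axes,
    extract_mlines_from_mask,
    filament_pairs_from_mlines,
    load_mlines_from_points,
    make_mline_lattice_fixture,
    sets_are_disjoint,
    synthesize_shg_volume,
    write_mlines,
)
from shgvernier.mlines import MLineFormatError
from shgvernier.tissue import MLineSet

from .oracles import naive_connected_components_26


class TestPointFileIO:
    def test_csv_roundtrip_is_bit_identical(self, tmp_path):
        mset = make_mline_lattice_fixture(2, 5, jitter_um=0.03, seed=9)
        path = tmp_path / "mlines.csv"
        write_mlines(mset, path)
        back = load_mlines_from_points(path)
        assert np.array_equal(back.points_um, mset.points_um)
        assert np.array_equal(back.axes, mset.axes)
        assert np.array_equal(back.fiber_ids, mset.fiber_ids)

    def test_json_roundtrip(self, tmp_path):
        mset = make_mline_lattice_fixture(1, 4, jitter_um=0.0, seed=0)
        path = tmp_path / "mlines.json"
        write_mlines(mset, path)
        back = load_mlines_from_points(path)
        assert np.allclose(back.points_um, mset.points_um)

    def test_missing_column_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x_um,y_um,z_um\n0,0,0\n")
        with pytest.raises(MLineFormatError, match="axis_x"):
            load_mlines_from_points(path)

    def test_zero_axis_row_is_reported_with_index(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x_um,y_um,z_um,axis_x,axis_y,axis_z\n"
            "0,0,0,1,0,0\n"
            "5,0,0,0,0,0\n"
        )
        with pytest.raises(MLineFormatError, match="row 1"):
            load_mlines_from_points(path)

    def test_non_finite_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x_um,y_um,z_um,axis_x,axis_y,axis_z\n"
            "nan,0,0,1,0,0\n"
        )
        with pytest.raises(MLineFormatError, match="non-finite"):
            load_mlines_from_points(path)

    def test_duplicate_points_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "x_um,y_um,z_um,axis_x,axis_y,axis_z\n"
            "0,0,0,1,0,0\n"
            "0.05,0,0,1,0,0\n"
        )
        with pytest.raises(MLineFormatError, match="separation"):
            load_mlines_from_points(path)


class TestMaskExtraction:
    def test_three_disjoint_blobs_give_three_points(self):
        mask = np.zeros((12, 12, 6), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[7:9, 2:4, 2:4] = True
        mask[4:6, 8:10, 1:2] = True
        mset = extract_mlines_from_mask(mask, 0.1)
        assert len(mset) == 3

    def test_single_voxel_centroid_uses_voxel_center_convention(self):
        mask = np.zeros((5, 6, 7), dtype=bool)
        mask[2, 3, 4] = True
        mset = extract_mlines_from_mask(mask, (0.2, 0.3, 0.4))
        assert np.allclose(mset.points_um[0], [2.5 * 0.2, 3.5 * 0.3, 4.5 * 0.4])

    def test_corner_touching_blobs_are_one_component(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[3:5, 3:5, 3:5] = True  # touch only at the corner voxel diagonal
        mset = extract_mlines_from_mask(mask, 0.1)
        assert len(mset) == 1
        assert len(naive_connected_components_26(mask)) == 1

    def test_component_count_matches_brute_force_oracle(self, rng):
        mask = rng.random((10, 10, 10)) < 0.2
        mset = extract_mlines_from_mask(mask, 0.1) if mask.any() else []
        assert len(mset) == len(naive_connected_components_26(mask))

    def test_empty_mask_warns_and_returns_empty_set(self):
        with pytest.warns(UserWarning, match="empty mask"):
            mset = extract_mlines_from_mask(np.zeros((4, 4, 4), bool), 0.1)
        assert len(mset) == 0


class TestEstimateAxes:
    def test_collinear_points_give_the_line_direction(self):
        pts = np.column_stack([np.arange(6) * 1.9, np.zeros(6), np.zeros(6)])
        mset = MLineSet(pts, np.tile([0.0, 0.0, 1.0], (6, 1)))
        out = estimate_axes(mset, k_neighbors=2)
        assert np.allclose(np.abs(out.axes @ [1, 0, 0]), 1.0, atol=1e-9)
        # signs consistent across points
        assert np.allclose(out.axes, out.axes[0])

    def test_two_parallel_fibers_recover_axis_within_5_degrees(self):
        # fibers far enough apart that each point's nearest neighbors are
        # along its own fiber even at the train ends
        mset = make_mline_lattice_fixture(2, 6, jitter_um=0.05, seed=4,
                                          fiber_separation_um=4.0)
        out = estimate_axes(mset, k_neighbors=2)
        cosines = np.abs(out.axes @ [1, 0, 0])
        assert np.all(cosines >= np.cos(np.radians(5.0)))

    def test_matches_brute_force_pca_oracle(self):
        mset = make_mline_lattice_fixture(2, 6, jitter_um=0.02, seed=8)
        out = estimate_axes(mset, k_neighbors=3)
        pts = mset.points_um
        for i in range(len(pts)):
            d = np.linalg.norm(pts - pts[i], axis=1)
            neigh = pts[np.argsort(d)[1:4]] - pts[i]
            cov = neigh.T @ neigh
            w, v = np.linalg.eigh(cov)
            principal = v[:, -1]
            assert abs(out.axes[i] @ principal) == pytest.approx(1.0, abs=1e-6)

    def test_single_point_falls_back_with_warning(self):
        mset = MLineSet(np.array([[0.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]))
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = estimate_axes(mset)
        assert np.allclose(out.axes, [[1, 0, 0]])

    def test_isolated_point_uses_global_axis(self):
        pts = np.array([[0, 0, 0], [1.9, 0, 0], [3.8, 0, 0], [100.0, 0, 5.0]])
        mset = MLineSet(pts, np.tile([1.0, 0.0, 0.0], (4, 1)))
        with pytest.warns(UserWarning, match="isolated"):
            out = estimate_axes(mset, k_neighbors=2, isolation_cutoff_um=5.0)
        assert out.axes.shape == (4, 3)


class TestFilamentPairs:
    def test_lengths_drawn_from_range_are_seeded_and_in_range(self):
        mset = make_mline_lattice_fixture(2, 4, jitter_um=0.0, seed=0)
        a = filament_pairs_from_mlines(mset, filament_length_um=(0.6, 1.0),
                                       spacing_um=0.15, seed=3)
        b = filament_pairs_from_mlines(mset, filament_length_um=(0.6, 1.0),
                                       spacing_um=0.15, seed=3)
        lengths = [s.provenance["filament_length_um"] for s in a]
        assert all(0.6 <= L <= 1.0 for L in lengths)
        assert lengths == [s.provenance["filament_length_um"] for s in b]
        assert len(set(np.round(lengths, 6))) > 1

    def test_nonphysiological_length_requires_override(self):
        mset = make_mline_lattice_fixture(1, 2, jitter_um=0.0, seed=0)
        with pytest.raises(ValueError, match="physiological"):
            filament_pairs_from_mlines(mset, filament_length_um=1.4,
                                       spacing_um=0.15)

    def test_per_fiber_sets_are_spatially_disjoint(self):
        mset = make_mline_lattice_fixture(2, 4, jitter_um=0.0, seed=0)
        pairs = filament_pairs_from_mlines(mset, spacing_um=0.15)
        fiber0 = [p for p, fid in zip(pairs, mset.fiber_ids) if fid == 0]
        fiber1 = [p for p, fid in zip(pairs, mset.fiber_ids) if fid == 1]
        from shgvernier.tissue import ScattererSet

        merged = [ScattererSet.concatenate(fiber0),
                  ScattererSet.concatenate(fiber1)]
        assert sets_are_disjoint(merged, min_distance_um=0.2)


class TestSynthesizeVolume:
    def test_single_mline_gives_two_shg_bands_along_axis(self, beam, cone):
        mset = MLineSet(np.array([[2.0, 0.0, 0.0]]),
                        np.array([[1.0, 0.0, 0.0]]))
        grid = ImageGrid(
            origin_um=np.array([0.0, 0.0, -0.05]),
            axes=np.array([[1.0, 0, 0], [0, 0, 1.0]]),
            shape=(40, 1),
            pixel_size_um=0.1,
        )
        img = synthesize_shg_volume(mset, beam, cone, grid, spacing_um=0.12)
        profile = img.shg[:, 0]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(profile, prominence=0.1 * profile.max())
        assert len(peaks) == 2
        x = (np.arange(40) + 0.5) * 0.1
        assert np.all(np.sign(x[peaks] - 2.0) == [-1, 1])

    def test_rigid_translation_equivariance(self, beam, cone):
        """Moving the M-lines and the grid together re-indexes nothing."""
        mset = make_mline_lattice_fixture(1, 3, jitter_um=0.0, seed=1)
        shift = np.array([0.7, -0.3, 0.4])
        shifted = MLineSet(mset.points_um + shift, mset.axes,
                           mset.fiber_ids, mset.source)
        grid = ImageGrid(
            origin_um=np.array([-0.5, -0.2, -0.2]),
            axes=np.array([[1.0, 0, 0], [0, 0, 1.0]]),
            shape=(20, 4),
            pixel_size_um=0.2,
        )
        grid2 = ImageGrid(
            origin_um=grid.origin_um + shift, axes=grid.axes,
            shape=grid.shape, pixel_size_um=grid.pixel_size_um,
        )
        a = synthesize_shg_volume(mset, beam, cone, grid, spacing_um=0.15)
        b = synthesize_shg_volume(shifted, beam, cone, grid2, spacing_um=0.15)
        assert np.allclose(a.shg, b.shg, rtol=1e-9)
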