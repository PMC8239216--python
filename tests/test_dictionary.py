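"""Dictionary assembly: geometry oracle, column bookkeeping, consistency."""

import numpy as np
import pytest

from axsize.dictionary import (
    DiameterGrid,
    DictionaryConfig,
    DictionaryError,
    DictionaryOperator,
    KIND_BALL,
    KIND_CYLINDER,
    KIND_ZEPPELIN,
    build_dictionary,
    principal_directions,
    voxel_segments,
)
from axsize.scheme import connectom_protocol
from axsize.signals import cylinder_attenuation

from .oracles import ground_truth_coefficients


@pytest.fixture(scope="module")
def scheme():
    return connectom_protocol()


class TestDiameterGrid:
    def test_default_grid(self):
        g = DiameterGrid.default()
        np.testing.assert_allclose(g.values, np.linspace(1.5, 7.0, 12))
        assert not g.included[0] and not g.included[-1]
        assert g.included[1:-1].all()

    def test_alternative_sizes_share_range(self):
        for n in (6, 9, 12, 15):
            g = DiameterGrid.default(n=n)
            assert g.values[0] == 1.5 and g.values[-1] == 7.0
            assert len(g) == n

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            DiameterGrid(np.array([1.0, 1.0, 2.0]), np.array([True] * 3))


class TestVoxelSegments:
    def test_axis_aligned_line_against_voxel_walk_oracle(self):
        """A straight y-line crossing 5 voxels of 2 mm: the independent
        oracle is a plain integer walk over y cells."""
        pts = np.array([[3.0, 0.0, 1.0], [3.0, 10.0, 1.0]])
        vox, lens, tans = voxel_segments(pts, 2.0, (4, 5, 1))
        oracle = {(1, j, 0): 2.0 for j in range(5)}
        got = {tuple(v): l for v, l in zip(vox, lens)}
        assert got.keys() == oracle.keys()
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k], rel=1e-9)
        np.testing.assert_allclose(tans, [[0.0, 1.0, 0.0]] * len(tans))

    def test_diagonal_line_lengths(self):
        # 45-degree line through voxel centers: sqrt(2) * voxel size each
        pts = np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 1.0]])
        vox, lens, _ = voxel_segments(pts, 2.0, (5, 5, 1))
        assert lens.sum() == pytest.approx(8 * np.sqrt(2), rel=1e-9)

    def test_voxel_size_doubling_preserves_total_length(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 0.8, (40, 3)), axis=0) + 20.0
        _, l1, _ = voxel_segments(pts, 2.0, (40, 40, 40))
        _, l2, _ = voxel_segments(pts, 4.0, (20, 20, 20))
        assert l1.sum() == pytest.approx(l2.sum(), rel=0.01)
        assert len(np.unique(voxel_segments(pts, 4.0, (20, 20, 20))[0], axis=0)) < len(
            np.unique(voxel_segments(pts, 2.0, (40, 40, 40))[0], axis=0)
        )

    def test_outside_grid_dropped(self):
        pts = np.array([[-5.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        vox, lens, _ = voxel_segments(pts, 2.0, (2, 2, 1))
        assert np.all(vox >= 0)
        assert lens.sum() == pytest.approx(1.0, rel=1e-9)


class TestBuildDictionary:
    def _tiny(self, scheme, n_streamlines=2, with_dirs=True):
        mask = np.ones((4, 5, 1), dtype=bool)
        sls = [
            np.array([[1.0 + 2 * k, 0.0, 1.0], [1.0 + 2 * k, 10.0, 1.0]])
            for k in range(n_streamlines)
        ]
        dirs = None
        if with_dirs:
            dirs = np.full((4, 5, 1, 1, 3), np.nan)
            dirs[..., 0, :] = [0.0, 1.0, 0.0]
        return build_dictionary(sls, mask, scheme, directions=dirs, voxel_size=2.0)

    def test_column_counts(self, scheme):
        op = self._tiny(scheme)
        assert (op.col_kind == KIND_CYLINDER).sum() == 2 * 12
        # every voxel gets 4 zeppelins (one direction) + 1 ball
        assert (op.col_kind == KIND_ZEPPELIN).sum() == op.n_voxels * 4
        assert (op.col_kind == KIND_BALL).sum() == op.n_voxels

    def test_entries_match_cylinder_signal_scaled_by_traversal(self, scheme):
        op = self._tiny(scheme, n_streamlines=1)
        sig = cylinder_attenuation(
            op.grid.values * 1e-6, np.array([0.0, 1.0, 0.0]), scheme
        )
        cols = np.nonzero((op.col_kind == KIND_CYLINDER) & (op.col_streamline == 0))[0]
        A = op.A.tocsc()
        for di, c in enumerate(cols):
            col = A[:, c].toarray().ravel().reshape(op.n_voxels, op.n_meas)
            hit = np.abs(col).sum(1) > 0
            assert hit.sum() == 5  # five traversed voxels, weight 1 each
            np.testing.assert_allclose(col[hit], np.tile(sig[di], (5, 1)), rtol=1e-12)

    def test_all_entries_non_negative(self, scheme):
        op = self._tiny(scheme)
        assert op.A.data.min() >= 0

    def test_empty_tractogram_raises(self, scheme):
        with pytest.raises(DictionaryError, match="empty"):
            build_dictionary([], np.ones((2, 2, 1), bool), scheme)

    def test_streamline_outside_mask_skipped(self, scheme):
        mask = np.ones((4, 5, 1), dtype=bool)
        sls = [
            np.array([[1.0, 0.0, 1.0], [1.0, 10.0, 1.0]]),
            np.array([[100.0, 0.0, 1.0], [100.0, 10.0, 1.0]]),
        ]
        op = build_dictionary(sls, mask, scheme, voxel_size=2.0)
        assert op.skipped_streamlines == 1

    def test_direction_fallback_uses_mean_tangent(self, scheme):
        # no directions supplied: traversed voxels still get a zeppelin set
        op = self._tiny(scheme, with_dirs=False)
        zep_vox = np.unique(op.col_voxel[op.col_kind == KIND_ZEPPELIN])
        assert len(zep_vox) == 10  # the two traversed columns of 5 voxels

    def test_stick_perp_mode_column_count(self, scheme):
        mask = np.ones((4, 5, 1), dtype=bool)
        sls = [np.array([[1.0, 0.0, 1.0], [1.0, 10.0, 1.0]])]
        dirs = np.full((4, 5, 1, 1, 3), np.nan)
        dirs[..., 0, :] = [0.0, 1.0, 0.0]
        op = build_dictionary(
            sls, mask, scheme, directions=dirs,
            config=DictionaryConfig(zeppelin_mode="stick+perp"), voxel_size=2.0,
        )
        # 1 stick + 4 perpendicular-only per direction
        assert (op.col_kind == KIND_ZEPPELIN).sum() == op.n_voxels * 5

    def test_save_load_roundtrip(self, scheme, tmp_path):
        op = self._tiny(scheme)
        path = tmp_path / "operator.h5"
        op.save(path)
        back = DictionaryOperator.load(path)
        assert (op.A != back.A).nnz == 0
        np.testing.assert_array_equal(op.col_kind, back.col_kind)
        np.testing.assert_array_equal(op.col_streamline, back.col_streamline)
        np.testing.assert_allclose(op.grid.values, back.grid.values)


class TestPrincipalDirections:
    def test_phantom_crossing_voxel_has_two_directions_at_45deg(self, phantom1):
        dirs = principal_directions(phantom1)
        vox = phantom1.region_voxels(3)[0]  # crossing
        d = dirs[tuple(vox)]
        assert np.all(np.isfinite(d))
        cos = abs(np.dot(d[0], d[1]))
        assert np.degrees(np.arccos(cos)) == pytest.approx(45.0, abs=1e-6)

    def test_single_fiber_voxel_has_one_direction(self, phantom1):
        dirs = principal_directions(phantom1)
        vox = phantom1.region_voxels(1)[0]  # A only
        d = dirs[tuple(vox)]
        assert np.all(np.isfinite(d[0])) and np.all(np.isnan(d[1]))

    def test_zero_peaks_mean_no_direction(self):
        peaks = np.zeros((2, 2, 1, 1, 3))
        peaks[0, 0, 0, 0] = [1.0, 0.0, 0.0]
        dirs = principal_directions(peaks)
        assert np.all(np.isfinite(dirs[0, 0, 0, 0]))
        assert np.all(np.isnan(dirs[1, 1, 0, 0]))


class TestForwardConsistency:
    def test_ground_truth_coefficients_explain_noise_free_signal(
        self, phantom1, bundle_model
    ):
        """A coefficient vector constructed from the generating truth
        (gamma projection, fractions, traffic) fits the noise-free volume
        to within 5% relative residual."""
        x = ground_truth_coefficients(phantom1, bundle_model)
        assert np.all(x >= 0)
        op = bundle_model.operator
        y = bundle_model.endog
        rel = np.linalg.norm(op.A @ x - y) / np.linalg.norm(y)
        assert rel <= 0.05
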