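import warnings

import numpy as np
import pytest

import eropipe as ep
from eropipe.decompose import promax, varimax

from conftest import make_dataset


def matrix_with_eigenvalues(eigs, n=40, seed=0):
    """Build an N×M matrix whose column-centered PCA eigenvalues are ``eigs``."""
    rng = np.random.default_rng(seed)
    m = len(eigs)
    # left factors orthonormal and orthogonal to the all-ones vector, so that
    # column centering leaves the construction intact
    basis = np.linalg.qr(np.column_stack([np.ones(n), rng.standard_normal((n, m))]))[0]
    U = basis[:, 1 : m + 1]
    V = np.linalg.qr(rng.standard_normal((m + 3, m)))[0][:, :m]
    s = np.sqrt(np.asarray(eigs, float) * (n - 1))
    X = U @ np.diag(s) @ V.T
    ds = make_dataset(X.reshape(n, 1, 1, m + 3).transpose(0, 1, 2, 3))
    return ds


class TestBuildMatrix:
    def test_synthetic_shape_4420x120(self):
        model = ep.make_default_sources(seed=0, snr_db=None)
        sim = ep.simulate_dataset(model, 68)
        Z = ep.build_matrix(sim.dataset, (0.0, 800.0))
        assert Z.shape == (4420, 120)

    def test_real_shape_4872_rows(self, rng):
        ds = make_dataset(rng.standard_normal((21, 4, 58, 40)), srate=128.0, t0=-200.0)
        Z = ep.build_matrix(ds)
        assert Z.shape[0] == 4872

    def test_row_index_roundtrip(self, rng):
        ds = make_dataset(rng.standard_normal((3, 2, 5, 10)))
        Z = ep.build_matrix(ds)
        for k in range(Z.shape[0]):
            s, c, ch = Z.index_of(k)
            assert Z.row_of(s, c, ch) == k
        # row content matches the cube entry
        assert np.array_equal(Z.Z[Z.row_of(2, 1, 3)], ds.data[2, 1, 3])

    def test_empty_window(self, small_sim):
        with pytest.raises(ValueError):
            ep.build_matrix(small_sim.dataset, (900.0, 1000.0))


class TestRotations:
    def test_varimax_recovers_simple_structure(self):
        rng = np.random.default_rng(0)
        A0 = np.zeros((30, 3))
        for j in range(3):
            A0[10 * j : 10 * (j + 1), j] = rng.uniform(0.5, 1.0, 10)
        theta = 0.4
        mix = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        V, R = varimax(A0 @ mix, kaiser=False)
        # each recovered column matches one original column up to sign
        M = np.abs(A0.T @ V)
        assert np.allclose(np.sort(np.linalg.norm(A0, axis=0) * np.linalg.norm(V, axis=0))[::-1][:3],
                           np.sort(M.max(axis=1))[::-1], rtol=1e-3)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_promax_phi_unit_diagonal(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((40, 4))
        pattern, T, phi = promax(A)
        assert np.allclose(np.diag(phi), 1.0, atol=1e-8)
        assert pattern.shape == A.shape
        assert np.allclose(pattern, A @ T, atol=1e-9)


class TestTpca:
    def test_r_by_cumulative_variance(self):
        ds = matrix_with_eigenvalues([4.0, 3.0, 2.0, 1.0])
        Z = ep.build_matrix(ds)
        # cumulative: 0.4, 0.7, 0.9, 1.0
        assert ep.tpca(Z, 0.99).R == 4
        assert ep.tpca(Z, 0.70).R == 2    # inclusive at exact equality
        assert ep.tpca(Z, 0.71).R == 3

    def test_rank2_exact_reconstruction(self):
        ds = matrix_with_eigenvalues([5.0, 2.0])
        Z = ep.build_matrix(ds)
        dec = ep.tpca(Z, 0.99)
        assert dec.R == 2
        recon = dec.scores @ dec.loadings_rotated.T + Z.column_means
        assert np.max(np.abs(recon - Z.Z)) < 1e-8

    def test_eigen_properties(self, small_filtered):
        Z = ep.build_matrix(small_filtered)
        dec = ep.tpca(Z, 0.99)
        assert np.all(np.diff(dec.eigenvalues) <= 1e-9)
        assert np.all(dec.eigenvalues >= -1e-12)
        assert dec.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        Q = dec.loadings_unrotated.T @ dec.loadings_unrotated
        assert np.allclose(Q, np.eye(dec.R), atol=1e-9)

    def test_reconstruction_consistency(self, small_filtered):
        """scores·patternᵀ equals the retained-subspace projection."""
        Z = ep.build_matrix(small_filtered)
        dec = ep.tpca(Z, 0.99)
        X = Z.Z - Z.column_means
        proj = X @ dec.loadings_unrotated @ dec.loadings_unrotated.T
        assert np.allclose(dec.scores @ dec.loadings_rotated.T, proj, atol=1e-6)

    def test_oblique_covariance_identity(self, small_filtered):
        Z = ep.build_matrix(small_filtered)
        dec = ep.tpca(Z, 0.99)
        X = Z.Z - Z.column_means
        n = X.shape[0]
        retained = (X @ dec.loadings_unrotated @ dec.loadings_unrotated.T)
        cov_ret = retained.T @ retained / (n - 1)
        model_cov = dec.loadings_rotated @ dec.factor_correlation @ dec.loadings_rotated.T
        assert np.allclose(model_cov, cov_ret, atol=1e-6 * np.abs(cov_ret).max())

    def test_threshold_validation(self, small_filtered):
        Z = ep.build_matrix(small_filtered)
        with pytest.raises(ValueError):
            ep.tpca(Z, 0.0)
        with pytest.raises(ValueError):
            ep.tpca(Z, 1.5)

    def test_degenerate_rank_reduced(self):
        ds = matrix_with_eigenvalues([5.0, 0.0, 0.0])
        Z = ep.build_matrix(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = ep.tpca(Z, 1.0)
        assert dec.R <= 1 + 2  # reduced to numerical rank


class TestSpatialSimilarity:
    def test_identical(self):
        topo = np.tile(np.array([1.0, 2.0, 0.5, -1.0]), (5, 1))
        mean, sd = ep.spatial_similarity(topo)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_half_flipped_enumeration(self):
        t = np.array([1.0, -2.0, 3.0, 0.5])
        topo = np.vstack([t, t, -t, -t])
        # pairs: (0,1)+ (2,3)+ are +1; the 4 cross pairs are −1 → mean=(2−4)/6
        mean, sd = ep.spatial_similarity(topo)
        assert mean == pytest.approx((2 - 4) / 6)

    def test_three_subjects_hand_pearson(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        c = np.array([3.0, 2.0, 1.0])
        def r(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
        expect = np.array([r(a, b), r(a, c), r(b, c)])
        mean, sd = ep.spatial_similarity(np.vstack([a, b, c]))
        assert mean == pytest.approx(expect.mean())
        assert sd == pytest.approx(expect.std(ddof=0))

    def test_zero_variance_excluded(self):
        topo = np.vstack([np.ones(4), [1, 2, 3, 4], [2, 4, 6, 8]])
        with pytest.warns(UserWarning, match="zero-variance"):
            mean, _ = ep.spatial_similarity(topo)
        assert mean == pytest.approx(1.0)


@pytest.fixture(scope="module")
def decomposition(small_filtered):
    return ep.tpca(ep.build_matrix(small_filtered), 0.99)


class TestSelection:
    def test_simulated_sources_shortlisted(self, decomposition):
        n2 = ep.select_components(decomposition, ep.SelectionCriteria(
            (260, 400), -1, ("FCz", "FC1", "FC2", "Fz", "Cz")))
        p3 = ep.select_components(decomposition, ep.SelectionCriteria(
            (370, 580), +1, ("Cz", "C1", "C2", "CPz", "FCz")))
        assert n2.selected
        assert p3.selected
        assert not set(n2.selected) & set(p3.selected)

    def test_impossible_criteria_empty(self, decomposition):
        with pytest.warns(UserWarning, match="no components"):
            sel = ep.select_components(decomposition, ep.SelectionCriteria(
                (-200, -150), -1, ("Fz",)))
        assert sel.selected == []

    def test_sign_flip_invariance(self, decomposition):
        import copy
        crit = ep.SelectionCriteria((370, 580), +1, ("Cz", "C1", "C2", "CPz", "FCz"))
        base = ep.select_components(decomposition, crit)
        flipped = copy.deepcopy(decomposition)
        j = base.selected[0]
        flipped.loadings_rotated[:, j] *= -1
        flipped.scores[:, j] *= -1
        again = ep.select_components(flipped, crit)
        assert again.selected == base.selected

    def test_unknown_region_channel(self, decomposition):
        with pytest.raises(ValueError, match="not in dataset"):
            ep.select_components(decomposition, ep.SelectionCriteria(
                (260, 400), -1, ("Qz",)))


class TestBackProjection:
    def test_full_selection_recovers_input(self):
        ds = matrix_with_eigenvalues([4.0, 2.0, 1.0])
        Z = ep.build_matrix(ds)
        dec = ep.tpca(Z, 1.0)
        bp = ep.back_project(dec, list(range(dec.R)))
        flat = bp.data.reshape(Z.shape)
        assert np.max(np.abs(flat - Z.Z)) < 1e-8 * max(1.0, np.abs(Z.Z).max())

    def test_rank1_single_component(self):
        ds = matrix_with_eigenvalues([3.0])
        Z = ep.build_matrix(ds)
        dec = ep.tpca(Z, 0.9)
        bp = ep.back_project(dec, [0])
        assert np.max(np.abs(bp.data.reshape(Z.shape) - Z.Z)) < 1e-8

    def test_sign_flip_gives_identical_projection(self, small_filtered):
        import copy
        Z = ep.build_matrix(small_filtered)
        dec = ep.tpca(Z, 0.99)
        ref = ep.back_project(dec, [0, 1]).data
        flipped = copy.deepcopy(dec)
        flipped.loadings_rotated[:, 1] *= -1
        flipped.scores[:, 1] *= -1
        assert np.allclose(ep.back_project(flipped, [0, 1]).data, ref, atol=1e-12)

    def test_scale_equivariance(self, small_filtered):
        Z1 = ep.build_matrix(small_filtered)
        scaled = small_filtered.with_data(small_filtered.data * 3.0)
        Z2 = ep.build_matrix(scaled)
        d1 = ep.tpca(Z1, 0.99)
        d2 = ep.tpca(Z2, 0.99)
        b1 = ep.back_project(d1, list(range(d1.R))).data
        b2 = ep.back_project(d2, list(range(d2.R))).data
        assert np.allclose(b2, 3.0 * b1, atol=1e-7 * np.abs(b1).max())

    def test_empty_selection_rejected(self, small_filtered):
        dec = ep.tpca(ep.build_matrix(small_filtered), 0.99)
        with pytest.raises(ValueError, match="empty"):
            ep.back_project(dec, [])

    def test_partial_projection_omits_column_means(self, small_filtered):
        Z = ep.build_matrix(small_filtered)
        dec = ep.tpca(Z, 0.99)
        bp = ep.back_project(dec, [0])
        expected = np.outer(dec.scores[:, 0], dec.loadings_rotated[:, 0])
        assert np.allclose(bp.data.reshape(Z.shape), expected, atol=1e-10)
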