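import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import distance_matrix

from confland.embedding import (
    EmbeddingModel,
    double_center,
    fit_cmds,
    nearest_psd,
    project_out_of_sample,
    project_trajectory,
)
from confland.fixtures import (
    ToyEnsembleSpec,
    line_config_034,
    make_euclidean_config,
    make_toy_ensemble,
)
from confland.geometry import DissimilarityMatrix, pairwise_rmsd_matrix


def embedded_distances(X):
    return distance_matrix(X, X)


class TestDoubleCenter:
    def test_worked_line_configuration(self):
        # points {0,3,4}: centered coords (-7/3, 2/3, 5/3), so the Gram
        # diagonal is (49/9, 4/9, 25/9)
        _, D = line_config_034()
        B = double_center(D)
        np.testing.assert_allclose(
            np.diag(B), [49 / 9, 4 / 9, 25 / 9], atol=1e-12
        )
        centered = np.array([-7 / 3, 2 / 3, 5 / 3])
        np.testing.assert_allclose(B, np.outer(centered, centered), atol=1e-12)

    def test_zero_matrix_maps_to_zero(self):
        D = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        np.testing.assert_allclose(double_center(D), 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_uniform_weights_row_sums_vanish(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        D = distance_matrix(pts, pts)
        B = double_center(D)
        np.testing.assert_allclose(B.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(B.sum(axis=1), 0.0, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        _, D = line_config_034()
        with pytest.raises(ValueError):
            double_center(D, weights=np.ones(5))


class TestNearestPsd:
    def test_psd_input_unchanged(self, rng):
        A = rng.normal(size=(5, 5))
        B = A @ A.T
        np.testing.assert_allclose(nearest_psd(B), B, atol=1e-10)

    def test_negative_eigenvalue_clipped(self):
        B = np.diag([1.0, -0.5])
        np.testing.assert_allclose(nearest_psd(B), np.diag([1.0, 0.0]), atol=1e-12)

    def test_frobenius_correction_equals_clipped_norm(self, rng):
        A = rng.normal(size=(6, 6))
        B = 0.5 * (A + A.T)
        evals = np.linalg.eigvalsh(B)
        expected = np.sqrt((np.clip(evals, None, 0.0) ** 2).sum())
        got = np.linalg.norm(B - nearest_psd(B))
        assert got == pytest.approx(expected, abs=1e-10)
        # and the result is indeed PSD
        assert np.linalg.eigvalsh(nearest_psd(B)).min() >= -1e-10

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            nearest_psd(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestFitCmds:
    def test_line_configuration_single_component(self):
        _, D = line_config_034()
        with pytest.warns(UserWarning, match="truncating"):
            model = fit_cmds(D, p=2)
        assert model.p == 1
        assert model.explained_variance[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            embedded_distances(model.X), D.D, atol=1e-8
        )

    def test_unit_square_two_equal_eigenvalues(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        D = DissimilarityMatrix(
            [f"c{i}" for i in range(4)], distance_matrix(pts, pts)
        )
        model = fit_cmds(D, p=2)
        assert model.eigenvalues[0] == pytest.approx(model.eigenvalues[1], rel=1e-10)
        np.testing.assert_allclose(embedded_distances(model.X), D.D, atol=1e-8)

    def test_identical_structures_embed_at_origin(self):
        D = DissimilarityMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        model = fit_cmds(D, p=2)
        np.testing.assert_allclose(model.X, 0.0)

    def test_columns_centered_and_normalized_to_eigenvalue(self, rng):
        _, D = make_euclidean_config(12, 3, seed=5)
        model = fit_cmds(D, p=3)
        np.testing.assert_allclose(model.X.sum(axis=0), 0.0, atol=1e-8)
        for k in range(model.p):
            assert model.X[:, k] @ model.X[:, k] == pytest.approx(
                model.eigenvalues[k], rel=1e-10
            )
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_explained_variance_fractions_bounded(self, rng):
        _, D = make_euclidean_config(10, 4, seed=11)
        model = fit_cmds(D, p=2)
        ev = model.explained_variance
        assert np.all(ev >= 0) and np.all(ev <= 1)
        assert ev.sum() <= 1 + 1e-12

    def test_sign_convention_reproducible(self):
        _, D = make_euclidean_config(9, 2, seed=3)
        X1 = fit_cmds(D, p=2).X
        X2 = fit_cmds(D, p=2).X
        np.testing.assert_array_equal(X1, X2)
        for k in range(2):
            assert X1[np.argmax(np.abs(X1[:, k])), k] > 0

    def test_exact_euclidean_strain_vanishes(self):
        _, D = make_euclidean_config(10, 2, seed=7)
        model = fit_cmds(D, p=2)
        assert model.strain < 1e-10
        np.testing.assert_allclose(embedded_distances(model.X), D.D, atol=1e-8)


class TestOutOfSample:
    def test_training_rows_reproduce_embedding(self):
        _, D = make_euclidean_config(10, 2, seed=1)
        model = fit_cmds(D, p=2)
        for i in range(model.n):
            proj = project_out_of_sample(model, D.D[i])
            np.testing.assert_allclose(proj.y, model.X[i], atol=1e-6)

    def test_line_query_lands_at_centered_position(self):
        # query at 1 on the line {0,3,4}: distances (1,2,3)
        _, D = line_config_034()
        with pytest.warns(UserWarning):
            model = fit_cmds(D, p=2)
        proj = project_out_of_sample(model, np.array([1.0, 2.0, 3.0]))
        # sign-robust check: distances to every training point recovered
        d_to_train = np.abs(model.X[:, 0] - proj.y[0])
        np.testing.assert_allclose(d_to_train, [1.0, 2.0, 3.0], atol=1e-6)
        # and the coordinate matches the centered position |1 - 7/3| = 4/3
        assert abs(proj.y[0]) == pytest.approx(4 / 3, abs=1e-6)

    def test_heldout_point_of_exact_config(self):
        pts, _ = make_euclidean_config(12, 2, seed=9)
        train, query = pts[:-1], pts[-1]
        D = DissimilarityMatrix(
            [f"t{i}" for i in range(len(train))],
            distance_matrix(train, train),
        )
        model = fit_cmds(D, p=2)
        a = np.linalg.norm(train - query, axis=1)
        proj = project_out_of_sample(model, a)
        # compare via distances (embedding is unique only up to isometry)
        np.testing.assert_allclose(
            np.linalg.norm(model.X - proj.y, axis=1), a, atol=1e-6
        )

    def test_border_vector_matches_bordered_double_centering(self):
        # O(n) cached-mean formula vs explicit (n+1) zero-weight centering
        pts, D = make_euclidean_config(8, 3, seed=13)
        model = fit_cmds(D, p=3)
        rng = np.random.default_rng(0)
        query = rng.normal(size=3)
        a = np.linalg.norm(pts - query, axis=1)
        proj = project_out_of_sample(model, a)
        n = D.n
        A2 = np.zeros((n + 1, n + 1))
        A2[:n, :n] = D.D**2
        A2[n, :n] = A2[:n, n] = a**2
        w = np.concatenate([np.full(n, 1.0 / n), [0.0]])
        J = np.eye(n + 1) - np.outer(np.ones(n + 1), w)
        Bstar = -0.5 * J @ A2 @ J.T
        np.testing.assert_allclose(proj.b, Bstar[n, :n], atol=1e-10)
        assert proj.beta_self == pytest.approx(Bstar[n, n], abs=1e-10)

    def test_wrong_length_rejected(self):
        _, D = make_euclidean_config(6, 2, seed=2)
        model = fit_cmds(D, p=2)
        with pytest.raises(ValueError):
            project_out_of_sample(model, np.ones(4))

    def test_zero_variance_model_rejected(self):
        D = DissimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)))
        model = fit_cmds(D, p=1)
        with pytest.raises(np.linalg.LinAlgError):
            project_out_of_sample(model, np.zeros(3))


class TestProjectTrajectory:
    def test_training_frames_reproject_onto_x(self):
        spec = ToyEnsembleSpec(
            n_states=2, frames_per_state=5, n_atoms=30, seed=8
        )
        frames, _ = make_toy_ensemble(spec)
        D = pairwise_rmsd_matrix(frames)
        model = fit_cmds(D, p=2)
        Y = project_trajectory(model, frames, training_sets=frames)
        np.testing.assert_allclose(Y, model.X, atol=1e-6)

    def test_two_state_clouds_separate(self):
        from sklearn.metrics import silhouette_score

        spec = ToyEnsembleSpec(
            n_states=2,
            frames_per_state=15,
            n_atoms=30,
            inter_state_displacement=3.0,
            noise_sd=0.1,
            seed=21,
        )
        train, _ = make_toy_ensemble(
            ToyEnsembleSpec(
                n_states=2, frames_per_state=10, n_atoms=30, seed=20
            )
        )
        D = pairwise_rmsd_matrix(train)
        model = fit_cmds(D, p=2)
        frames, labels = make_toy_ensemble(spec)
        Y = project_trajectory(model, frames, training_sets=train)
        assert silhouette_score(Y, labels) > 0.5

    def test_empty_frame_list(self):
        _, D = make_euclidean_config(5, 2, seed=0)
        model = fit_cmds(D, p=2)
        spec = ToyEnsembleSpec(n_states=2, frames_per_state=2, n_atoms=30, seed=0)
        frames, _ = make_toy_ensemble(spec)
        Dr = pairwise_rmsd_matrix(frames)
        model = fit_cmds(Dr, p=2)
        Y = project_trajectory(model, [], training_sets=frames)
        assert Y.shape == (0, 2)


class TestModelSerialization:
    def test_npz_round_trip_preserves_projection(self, tmp_path):
        spec = ToyEnsembleSpec(n_states=2, frames_per_state=4, n_atoms=30, seed=5)
        frames, _ = make_toy_ensemble(spec)
        D = pairwise_rmsd_matrix(frames)
        model = fit_cmds(D, p=2)
        model.atom_index = frames[0].atom_index
        model.training_coords = np.stack([f.coords for f in frames])
        path = tmp_path / "model.npz"
        model.save(path)
        back = EmbeddingModel.load(path)
        assert back.labels == model.labels
        np.testing.assert_array_equal(back.X, model.X)
        Y0 = project_trajectory(model, frames[:2])
        Y1 = project_trajectory(back, frames[:2])
        np.testing.assert_array_equal(Y0, Y1)
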