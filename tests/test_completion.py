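import numpy as np
import pytest

from dmccda import (
    BNNRCompleter,
    CompletionConfig,
    bnnr_complete,
    build_block,
    integrate_scores,
    space_update,
    svt_shrink,
)

from _oracles import nuclear_objective


class TestSpaceUpdate:
    def test_identity_similarity_normalizes_columns(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        Ac, _ = space_update(A, np.eye(2), np.eye(2))
        np.testing.assert_allclose(Ac, A)  # one-hot columns have unit norm

    def test_zero_column_stays_zero(self):
        A = np.array([[1.0, 0.0], [1.0, 0.0]])
        Ac, Ad = space_update(A, np.full((2, 2), 0.5), np.full((2, 2), 0.5))
        np.testing.assert_array_equal(Ac[:, 1], 0.0)

    def test_zero_row_stays_zero(self):
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        _, Ad = space_update(A, np.eye(2), np.full((2, 2), 0.5))
        np.testing.assert_array_equal(Ad[1, :], 0.0)

    def test_hand_computed_normalization(self):
        A = np.array([[1.0, 0.0], [1.0, 1.0]])
        CC = np.array([[1.0, 0.5], [0.5, 1.0]])
        Ac, _ = space_update(A, CC, np.eye(2))
        np.testing.assert_allclose(Ac[:, 0], [1.5 / np.sqrt(2), 1.5 / np.sqrt(2)])

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="CC shape"):
            space_update(np.ones((2, 3)), np.eye(3), np.eye(3))


class TestBuildBlock:
    def test_circ_space_shape_and_slice(self):
        block = build_block(np.zeros((3, 2)), np.eye(3), "circ")
        assert block.M.shape == (3, 5)
        assert (block.score_slice.start, block.score_slice.stop) == (3, 5)

    def test_circ_round_trip(self, rng):
        Ac = rng.uniform(size=(4, 3))
        block = build_block(Ac, np.eye(4), "circ")
        np.testing.assert_array_equal(block.extract_scores(), Ac)

    def test_disease_round_trip_transposes_back(self, rng):
        Ad = rng.uniform(size=(4, 3))
        block = build_block(Ad, np.eye(3), "disease")
        assert block.M.shape == (3, 7)
        np.testing.assert_array_equal(block.extract_scores(), Ad)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="KC shape"):
            build_block(np.zeros((3, 2)), np.eye(2), "circ")


class TestSvtShrink:
    def test_zero_threshold_is_identity(self, rng):
        X = rng.normal(size=(4, 5))
        np.testing.assert_allclose(svt_shrink(X, 0.0), X, atol=1e-12)

    def test_diagonal_closed_form(self):
        np.testing.assert_allclose(
            svt_shrink(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]), atol=1e-12
        )

    def test_symmetric_input_gives_symmetric_output(self, rng):
        X = rng.normal(size=(5, 5))
        X = X + X.T
        Z = svt_shrink(X, 0.7)
        np.testing.assert_allclose(Z, Z.T, atol=1e-10)

    def test_non_finite_input_errors(self):
        with pytest.raises(ValueError, match="finite"):
            svt_shrink(np.array([[np.nan, 0.0]]), 1.0)

    def test_is_prox_of_nuclear_norm(self, rng):
        # prox objective: tau*||Z||_* + 0.5||Z - X||^2, minimized by the output
        X = rng.normal(size=(4, 4))
        tau = 0.5
        Z = svt_shrink(X, tau)
        base = tau * np.linalg.norm(Z, "nuc") + 0.5 * np.linalg.norm(Z - X) ** 2
        for _ in range(200):
            P = Z + rng.normal(scale=1e-3, size=Z.shape)
            probe = tau * np.linalg.norm(P, "nuc") + 0.5 * np.linalg.norm(P - X) ** 2
            assert probe >= base - 1e-12


class TestBnnrComplete:
    def test_fidelity_dominated_limit_reproduces_input(self, rng):
        u = rng.uniform(0.2, 0.8, size=5)
        v = rng.uniform(0.2, 0.8, size=7)
        M = np.outer(u, v)  # rank-1, entries inside [0, 1]
        W = BNNRCompleter(alpha=1e6, max_iter=2000).fit_transform(M)
        np.testing.assert_allclose(W, M, atol=1e-3)

    def test_output_respects_box(self, rng):
        M = rng.normal(size=(6, 9))
        est = BNNRCompleter().fit(M)
        assert est.recovered_.min() >= -1e-12
        assert est.recovered_.max() <= 1 + 1e-12

    def test_bit_determinism(self, rng):
        M = rng.uniform(size=(7, 9))
        W1 = BNNRCompleter().fit_transform(M)
        W2 = BNNRCompleter().fit_transform(M)
        np.testing.assert_array_equal(W1, W2)

    def test_primal_residual_converges_on_random_blocks(self, rng):
        for _ in range(5):
            M = rng.uniform(size=(10, 14))
            est = BNNRCompleter().fit(M)
            assert est.n_iter_ < est.max_iter
            assert est.state_.primal_residual < est.tol
            assert est.state_.residual < est.tol

    def test_decreases_objective_below_input(self, rng):
        M = rng.uniform(size=(6, 6))
        W = BNNRCompleter().fit_transform(M)
        assert nuclear_objective(W, M, 1.0) <= nuclear_objective(np.clip(M, 0, 1), M, 1.0)

    def test_function_wrapper_matches_estimator(self, rng):
        block = build_block(rng.uniform(size=(4, 2)), np.eye(4), "circ")
        W, state = bnnr_complete(block)
        np.testing.assert_array_equal(W, BNNRCompleter().fit_transform(block.M))
        assert state.k >= 1

    def test_trace_recorded_when_asked(self, rng):
        M = rng.uniform(size=(5, 5))
        est = BNNRCompleter(record_trace=True).fit(M)
        assert len(est.state_.trace) == est.n_iter_
        ks, rel, prim = zip(*est.state_.trace)
        assert list(ks) == list(range(1, est.n_iter_ + 1))

    def test_sklearn_get_params_round_trip(self):
        est = BNNRCompleter(beta=5.0)
        assert BNNRCompleter(**est.get_params()).beta == 5.0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha_admm=0.0),
            dict(beta_admm=-1.0),
            dict(alpha_mix=1.5),
            dict(alpha_mix=-0.1),
            dict(max_iter=0),
            dict(tol=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CompletionConfig(**kwargs)


class TestIntegrateScores:
    def test_endpoints(self, rng):
        X, Y = rng.uniform(size=(3, 4)), rng.uniform(size=(3, 4))
        np.testing.assert_array_equal(integrate_scores(X, Y, 1.0), X)
        np.testing.assert_array_equal(integrate_scores(X, Y, 0.0), Y)

    def test_stated_weight(self):
        out = integrate_scores(np.ones((1, 1)), np.zeros((1, 1)), 0.7)
        np.testing.assert_allclose(out, 0.7)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shapes disagree"):
            integrate_scores(np.ones((2, 2)), np.ones((2, 3)), 0.5)
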