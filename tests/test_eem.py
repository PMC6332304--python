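"""Tanimoto kernel oracle, basis contracts and the closed-form EEM solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eemscreen import (
    DegenerateDatasetError,
    EEMClassifier,
    EEMModel,
    InputError,
    ProjectionBasis,
    SyntheticConfig,
    assemble_dataset,
    build_basis,
    eem_fit,
    eem_predict,
    generate_library,
    project,
    score_predictions,
    select_basis,
    split_dataset,
    tanimoto_kernel,
)
from eemscreen.eem import load_model, save_model


def brute_tanimoto(a, b) -> float:
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


class TestTanimotoKernel:
    def test_hand_enumerated_value(self):
        x = np.array([[1, 1, 0, 0]])
        y = np.array([[1, 0, 1, 0]])
        assert tanimoto_kernel(x, y)[0, 0] == pytest.approx(1 / 3)

    def test_identity_and_disjoint_and_empty(self):
        x = np.array([[1, 0, 1, 0]])
        assert tanimoto_kernel(x, x)[0, 0] == 1.0
        assert tanimoto_kernel(x, np.array([[0, 1, 0, 1]]))[0, 0] == 0.0
        zero = np.zeros((1, 4), dtype=int)
        assert tanimoto_kernel(zero, zero)[0, 0] == 1.0

    def test_agrees_with_set_arithmetic_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            d = rng.integers(1, 65)
            a = (rng.random(d) < rng.uniform(0.05, 0.9)).astype(int)
            b = (rng.random(d) < rng.uniform(0.05, 0.9)).astype(int)
            K = tanimoto_kernel(a[None, :], b[None, :])
            assert abs(K[0, 0] - brute_tanimoto(a, b)) <= 1e-12

    def test_rejects_non_binary_and_mismatched(self):
        with pytest.raises(InputError):
            tanimoto_kernel(np.array([[0.5, 1.0]]), np.array([[1, 0]]))
        with pytest.raises(InputError):
            tanimoto_kernel(np.array([[1, 0]]), np.array([[1, 0, 1]]))

    @settings(derandomize=True, max_examples=50)
    @given(
        A=hnp.arrays(np.int8, st.tuples(st.integers(1, 6), st.just(12)),
                     elements=st.integers(0, 1))
    )
    def test_self_kernel_symmetric_unit_diagonal(self, A):
        K = tanimoto_kernel(A, A)
        np.testing.assert_allclose(K, K.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert (K >= 0).all() and (K <= 1 + 1e-15).all()


class TestBasis:
    def test_capping_at_training_size(self):
        idx = select_basis(N=100, h_requested=3000, seed=0)
        assert len(idx) == 100
        assert sorted(idx) == list(range(100))

    def test_seed_determinism_and_distinctness(self):
        a = select_basis(N=1000, h_requested=500, seed=7)
        b = select_basis(N=1000, h_requested=500, seed=7)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == 500
        assert a.min() >= 0 and a.max() < 1000

    def test_full_basis_projection_is_gram_matrix(self):
        rng = np.random.default_rng(1)
        X = (rng.random((12, 20)) < 0.3).astype(np.uint8)
        basis = build_basis(X, h_requested=50, seed=0)
        Phi = project(X, basis)
        assert Phi.shape == (12, 12)
        np.testing.assert_array_equal(basis.indices, np.arange(12))
        # basis is all rows in order: the projection is the full Gram matrix
        np.testing.assert_allclose(Phi.diagonal(), 1.0)
        np.testing.assert_allclose(Phi, tanimoto_kernel(X, X))

    def test_projection_shape_and_range(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 16)) < 0.4).astype(np.uint8)
        basis = build_basis(X, h_requested=5, seed=3)
        row = project(X[:1], basis)
        assert row.shape == (1, 5)
        assert (row >= 0).all() and (row <= 1).all()


class TestEEMFit:
    def test_two_point_closed_form(self):
        """Point-mass classes at (1,0) and (0,1) with large C: the solve
        reduces to beta = C (m+ - m-), midpoint threshold 0."""
        Phi = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([True, False])
        beta, intercept = eem_fit(Phi, y, C=1e6, shrinkage=0.1)
        np.testing.assert_allclose(beta, [1e6, -1e6], rtol=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-6)
        scores = Phi @ beta - intercept
        assert scores[0] > 0 and scores[1] < 0

    def test_single_class_is_error(self):
        Phi = np.ones((4, 2))
        with pytest.raises(DegenerateDatasetError):
            eem_fit(Phi, np.ones(4, dtype=bool), C=1.0)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        Phi = rng.random((20, 6))
        y = np.arange(20) < 8
        b1, i1 = eem_fit(Phi, y, C=100.0)
        b2, i2 = eem_fit(np.repeat(Phi, 2, axis=0), np.repeat(y, 2), C=100.0)
        np.testing.assert_allclose(b1, b2, rtol=1e-10)
        assert i1 == pytest.approx(i2, rel=1e-10)


class TestEEMPredict:
    def _toy_model(self):
        basis = ProjectionBasis(
            indices=np.array([0]), h_requested=1, h_eff=1,
            fingerprints=np.array([[1, 1, 0, 0]], dtype=np.uint8),
        )
        return EEMModel(basis=basis, beta=np.array([1.0]), intercept=1.0, C=1.0)

    def test_zero_score_classifies_negative(self):
        model = self._toy_model()
        scores, labels = eem_predict(model, np.array([[1, 1, 0, 0]]))
        assert scores[0] == pytest.approx(0.0)
        assert labels[0] == "inactive"

    def test_row_permutation_permutes_scores(self):
        rng = np.random.default_rng(8)
        X = (rng.random((10, 24)) < 0.3).astype(np.uint8)
        y = np.array(["active"] * 5 + ["inactive"] * 5, dtype=object)
        clf = EEMClassifier(h=8, C=1e4, random_state=0).fit(X, y)
        scores = clf.decision_function(X)
        perm = rng.permutation(10)
        np.testing.assert_allclose(clf.decision_function(X[perm]), scores[perm])


class TestEEMClassifier:
    def test_recovers_separable_synthetic_data(self):
        cfg = SyntheticConfig(
            n_actives=100, n_true_inactives=100, n_pool=1,
            n_bits={"fp": 128}, n_scaffolds=2, flip_rate_active=0.02,
            flip_rate_inactive=0.02, pool_density=0.5,
            ambiguous_fraction=0.0, seed=21,
        )
        lib = generate_library(cfg)
        ds = assemble_dataset(lib, "fp", "true_inactives")
        train, test = split_dataset(ds, seed=0)
        clf = EEMClassifier(h=100, C=1e5, random_state=0).fit(train.X, train.y)
        assert score_predictions(test.y, clf.predict(test.X)) >= 0.95

    def test_memory_contract_no_full_gram(self):
        """With h < N, every intermediate is N x h or smaller."""
        rng = np.random.default_rng(12)
        X = (rng.random((100, 32)) < 0.3).astype(np.uint8)
        y = np.array(["active"] * 50 + ["inactive"] * 50, dtype=object)
        clf = EEMClassifier(h=20, C=1e4, random_state=0).fit(X, y)
        assert clf.h_eff_ == 20
        assert clf.model_.basis.fingerprints.shape == (20, 32)
        assert project(X, clf.model_.basis).shape == (100, 20)
        assert clf.model_.beta.shape == (20,)

    def test_h_capping_through_classifier(self):
        rng = np.random.default_rng(13)
        X = (rng.random((40, 16)) < 0.4).astype(np.uint8)
        y = np.array(["active"] * 20 + ["inactive"] * 20, dtype=object)
        clf = EEMClassifier(h=3000, C=1e4, random_state=0).fit(X, y)
        assert clf.h_eff_ == 40
        np.testing.assert_array_equal(clf.model_.basis.indices, np.arange(40))

    def test_refit_same_seed_reproducible(self):
        rng = np.random.default_rng(14)
        X = (rng.random((30, 24)) < 0.3).astype(np.uint8)
        y = np.array(["active"] * 15 + ["inactive"] * 15, dtype=object)
        a = EEMClassifier(h=10, C=1e4, random_state=5).fit(X, y)
        b = EEMClassifier(h=10, C=1e4, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.model_.basis.indices, b.model_.basis.indices)
        np.testing.assert_allclose(a.model_.beta, b.model_.beta)
        assert a.model_.intercept == b.model_.intercept

    def test_imbalance_robustness(self):
        """Duplicating the majority class 5x barely moves held-out balanced
        accuracy, because the equal-prior threshold is class-balanced."""
        cfg = SyntheticConfig(
            n_actives=60, n_true_inactives=60, n_pool=1, n_bits={"fp": 96},
            n_scaffolds=2, flip_rate_active=0.05, flip_rate_inactive=0.05,
            ambiguous_fraction=0.0, seed=31,
        )
        lib = generate_library(cfg)
        ds = assemble_dataset(lib, "fp", "true_inactives")
        train, test = split_dataset(ds, seed=1)
        balanced = EEMClassifier(h=40, C=1e4, random_state=0).fit(train.X, train.y)
        bac_balanced = score_predictions(test.y, balanced.predict(test.X))

        neg = train.y == "inactive"
        X_imb = np.vstack([train.X] + [train.X[neg]] * 4)
        y_imb = np.concatenate([train.y] + [train.y[neg]] * 4)
        imbalanced = EEMClassifier(h=40, C=1e4, random_state=0).fit(X_imb, y_imb)
        bac_imbalanced = score_predictions(test.y, imbalanced.predict(test.X))
        assert bac_balanced - bac_imbalanced < 0.05


def test_model_roundtrip(tmp_path):
    rng = np.random.default_rng(17)
    X = (rng.random((20, 16)) < 0.4).astype(np.uint8)
    y = np.array(["active"] * 10 + ["inactive"] * 10, dtype=object)
    clf = EEMClassifier(h=6, C=1e4, random_state=2).fit(X, y)
    save_model(clf.model_, tmp_path / "model")
    back = load_model(tmp_path / "model")
    np.testing.assert_array_equal(back.basis.fingerprints,
                                  clf.model_.basis.fingerprints)
    np.testing.assert_allclose(back.beta, clf.model_.beta)
    scores_a = eem_predict(clf.model_, X)[0]
    scores_b = eem_predict(back, X)[0]
    np.testing.assert_allclose(scores_a, scores_b)
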