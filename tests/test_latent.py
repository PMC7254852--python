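"""Latent-variable core: NIPALS PCA against an SVD oracle, Hotelling T²,
OPLS defining properties, VIP normalization, prediction consistency."""

import numpy as np
import pandas as pd
import pytest

from metopls import (
    NotCenteredError,
    OPLS,
    OPLSDA,
    PCA,
    ShapeError,
    DegenerateYError,
    opls_fit,
    pca_fit,
)
from metopls.latent import OPLSResults, table_hash


def _center(X):
    return X - X.mean(axis=0)


class TestPCA:
    def test_rank_one_data_single_component(self):
        X = _center(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        res = pca_fit(X, 1)
        assert res.r2x_per_component == pytest.approx([1.0])

    def test_matches_svd_oracle(self, rng):
        X = _center(rng.normal(size=(20, 15)))
        res = pca_fit(X, 15)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(15):
            t = res.scores.iloc[:, a].to_numpy()
            p = res.loadings.iloc[:, a].to_numpy()
            sign = np.sign(p @ Vt[a])
            np.testing.assert_allclose(p, sign * Vt[a], atol=1e-8)
            np.testing.assert_allclose(t, sign * U[:, a] * s[a], atol=1e-8)

    def test_r2x_sums_to_one_over_full_rank(self, rng):
        X = _center(rng.normal(size=(12, 8)))
        res = pca_fit(X, 8)
        assert sum(res.r2x_per_component) == pytest.approx(1.0, abs=1e-8)

    def test_scores_orthogonal_loadings_unit_norm(self, rng):
        X = _center(rng.normal(size=(15, 10)))
        res = pca_fit(X, 5)
        T = res.scores.to_numpy()
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.sqrt(np.outer(np.diag(G), np.diag(G))).max()
        np.testing.assert_allclose(
            np.linalg.norm(res.loadings.to_numpy(), axis=0), 1.0, rtol=1e-10
        )

    def test_sign_convention_largest_loading_positive(self, rng):
        X = _center(rng.normal(size=(10, 6)))
        res = pca_fit(X, 3)
        for a in range(3):
            p = res.loadings.iloc[:, a].to_numpy()
            assert p[np.argmax(np.abs(p))] > 0

    def test_non_centered_rejected(self):
        with pytest.raises(NotCenteredError):
            PCA(np.array([[1.0, 2.0], [3.0, 4.0], [9.0, 1.0]]))


class TestHotellingT2:
    def test_identical_scores_no_outliers(self):
        scores = pd.DataFrame(np.zeros((8, 2)), columns=["t1", "t2"])
        res = pca_fit(_center(np.vstack([np.eye(3), -np.eye(3), np.zeros((2, 3))])), 2)
        res.scores = scores  # degenerate score cloud
        t2, limit, flags = res.hotelling_t2()
        assert (t2 == 0).all() and not flags.any()

    def test_flags_invariant_to_sample_order(self, rng):
        X = _center(rng.normal(size=(20, 5)))
        res = pca_fit(X, 2)
        _, _, flags = res.hotelling_t2()
        perm = rng.permutation(20)
        res2 = pca_fit(X[perm], 2)
        _, _, flags2 = res2.hotelling_t2()
        assert flags.to_numpy()[perm].tolist() == flags2.to_numpy().tolist()

    def test_displaced_sample_flagged(self):
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 5))
            X[0, 0] += 10.0  # one sample 10 pooled-sd away
            res = pca_fit(_center(X), 2)
            _, _, flags = res.hotelling_t2(alpha=0.05)
            hits += bool(flags.iloc[0])
        assert hits >= int(0.9 * n_runs)


class TestOPLS:
    def test_zero_orth_equals_pls1_closed_form(self, rng):
        X = _center(rng.normal(size=(18, 7)))
        y = _center(rng.normal(size=18))
        res = opls_fit(X, y, n_orth=0)
        w = X.T @ y
        w /= np.linalg.norm(w)
        t = X @ w
        b = (t @ y) / (t @ t)
        np.testing.assert_allclose(res.w_pred.to_numpy(), w, atol=1e-12)
        np.testing.assert_allclose(res.t_pred.to_numpy(), t, atol=1e-12)
        assert res.b == pytest.approx(b, abs=1e-12)

    @staticmethod
    def _augmented_pair(rng, n=24, J=10, n_orth_dirs=1):
        """Base X driven by y, plus a structured y-orthogonal component whose
        loading overlaps the predictive loading (so OPLS must actually filter
        it rather than never seeing it)."""
        y = _center(rng.normal(size=n))
        c = rng.normal(size=J)
        c /= np.linalg.norm(c)
        X_base = np.outer(y, c)
        t_o = _center(rng.normal(size=n))
        t_o -= (t_o @ y) / (y @ y) * y  # exactly y-orthogonal
        p_o = rng.normal(size=J)
        p_o /= np.linalg.norm(p_o)
        p_o = 0.6 * c + 0.8 * (p_o - (p_o @ c) * c) / np.linalg.norm(p_o - (p_o @ c) * c)
        X_aug = X_base + 2.0 * np.outer(t_o, p_o)
        return _center(X_base), _center(X_aug), y

    def test_y_orthogonal_augmentation_leaves_predictions_unchanged(self, rng):
        X_base, X_aug, y = self._augmented_pair(rng)
        base = opls_fit(X_base, y, n_orth=0)
        aug = opls_fit(X_aug, y, n_orth=1)
        yhat_base = base.b * base.t_pred.to_numpy()
        yhat_aug = aug.b * aug.t_pred.to_numpy()
        np.testing.assert_allclose(yhat_aug, yhat_base, atol=1e-8)
        assert aug.r2x_orth > 0.1

    def test_orth_scores_uncorrelated_with_y(self, rng):
        X = _center(rng.normal(size=(20, 12)))
        y = _center(rng.normal(size=20))
        res = opls_fit(X, y, n_orth=3)
        for a in range(3):
            t_o = res.T_orth[:, a]
            assert abs(t_o @ y) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(y)

    def test_orth_weights_orthogonal_to_predictive(self, rng):
        X = _center(rng.normal(size=(20, 12)))
        y = _center(rng.normal(size=20))
        res = opls_fit(X, y, n_orth=3)
        w = res.w_pred.to_numpy()
        for a in range(3):
            assert abs(w @ res.W_orth[:, a]) < 1e-10

    def test_r2y_non_decreasing_in_orth_components(self, rng):
        X = _center(rng.normal(size=(20, 12)))
        y = _center(rng.normal(size=20))
        r2 = [opls_fit(X, y, n_orth=a).r2y for a in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_constant_y_rejected(self, rng):
        X = _center(rng.normal(size=(10, 4)))
        with pytest.raises(DegenerateYError):
            opls_fit(X, np.ones(10), 0)


class TestOPLSDA:
    def test_single_informative_metabolite_separable(self):
        X = np.zeros((8, 5))
        X[:4, 2] = 1.0  # class A elevated on metabolite 2 only
        X = _center(X)
        labels = ["A"] * 4 + ["B"] * 4
        res = OPLSDA(labels, X).fit()
        w = np.abs(res.w_pred.to_numpy())
        assert np.argmax(w) == 2
        assert res.classify(X) == labels

    def test_encoding_swap_flips_scores_keeps_vip(self, rng):
        X = _center(rng.normal(size=(12, 6)))
        labels = ["A"] * 6 + ["B"] * 6
        res1 = OPLSDA(labels, X, class_map={"A": 0.0, "B": 1.0}).fit()
        res2 = OPLSDA(labels, X, class_map={"A": 1.0, "B": 0.0}).fit()
        np.testing.assert_allclose(
            res1.t_pred.to_numpy(), -res2.t_pred.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(res1.vip(), res2.vip(), atol=1e-12)
        assert res1.classify(X) == res2.classify(X)

    def test_three_classes_rejected(self, rng):
        X = _center(rng.normal(size=(9, 4)))
        with pytest.raises(NotImplementedError):
            OPLSDA(["A", "B", "C"] * 3, X)

    def test_permuted_labels_lower_r2y(self, rng):
        n = 16
        y_sep = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        X = _center(np.outer(y_sep, np.ones(8)) + 0.3 * rng.normal(size=(n, 8)))
        labels = ["A"] * (n // 2) + ["B"] * (n // 2)
        true_r2 = OPLSDA(labels, X).fit().r2y
        worse = 0
        n_perm = 60
        for _ in range(n_perm):
            perm = rng.permutation(labels).tolist()
            worse += OPLSDA(perm, X).fit().r2y < true_r2
        assert worse >= int(0.9 * n_perm)


class TestVIP:
    def test_uniform_weights_give_unit_vip(self):
        res = opls_fit(
            _center(np.outer(np.arange(8.0), np.ones(4))), _center(np.arange(8.0)), 0
        )
        np.testing.assert_allclose(res.vip(), np.ones(4), atol=1e-10)

    def test_concentrated_weight_gives_sqrt_j(self):
        rngl = np.random.default_rng(5)
        y = _center(rngl.normal(size=12))
        X = np.zeros((12, 9))
        X[:, 0] = y
        res = opls_fit(_center(X), y, 0)
        vip = res.vip().to_numpy()
        assert vip[0] == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(vip[1:], 0.0, atol=1e-10)

    def test_mean_square_vip_is_one(self, rng):
        X = _center(rng.normal(size=(15, 11)))
        y = _center(rng.normal(size=15))
        vip = opls_fit(X, y, 2).vip().to_numpy()
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)


class TestPredict:
    def test_training_predictions_reproduced(self, rng):
        X = _center(rng.normal(size=(14, 6)))
        y = _center(rng.normal(size=14))
        res = opls_fit(X, y, 2)
        yhat, t_new = res.predict(X)
        np.testing.assert_allclose(
            yhat, res.b * res.t_pred.to_numpy() + res.y_mean, atol=1e-10
        )
        np.testing.assert_allclose(t_new, res.t_pred.to_numpy(), atol=1e-10)

    def test_duplicated_rows_identical_predictions(self, rng):
        X = _center(rng.normal(size=(10, 5)))
        y = _center(rng.normal(size=10))
        res = opls_fit(X, y, 1)
        yhat, _ = res.predict(np.vstack([X[3], X[3]]))
        assert yhat[0] == yhat[1]

    def test_mean_row_predicts_y_mean(self, rng):
        X = _center(rng.normal(size=(10, 5)))
        y = rng.normal(size=10)
        res = OPLS(y, X, 1).fit()
        yhat, _ = res.predict(np.zeros((1, 5)))
        assert yhat[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_column_mismatch_rejected(self, rng):
        X = _center(rng.normal(size=(10, 5)))
        res = opls_fit(X, _center(rng.normal(size=10)), 0)
        with pytest.raises(ShapeError):
            res.predict(np.zeros((2, 4)))


class TestSerialization:
    def test_json_round_trip(self, rng):
        X = _center(rng.normal(size=(10, 5)))
        y = _center(rng.normal(size=10))
        res = opls_fit(X, y, 2)
        back = OPLSResults.from_json(res.to_json(provenance=table_hash(pd.DataFrame(X))))
        np.testing.assert_allclose(back.w_pred, res.w_pred, atol=1e-15)
        np.testing.assert_allclose(back.W_orth, res.W_orth, atol=1e-15)
        yh1, _ = res.predict(X)
        yh2, _ = back.predict(X)
        np.testing.assert_allclose(yh1, yh2, atol=1e-12)
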