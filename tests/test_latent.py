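import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from metabloc.latent import (
    cross_validate_q2,
    fit_oplsda,
    fit_plsda,
    normality_threshold,
    permutation_test,
    predict,
    vip_scores,
    vip_table,
)
from metabloc.synthdata import SynthConfig, generate_dataset
from metabloc.preprocess import autoscale, pqn_normalize


def _binary_y(rng, n):
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    rng.shuffle(y)
    return y


class TestPlsda:
    def test_single_perfect_predictor(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        m = fit_plsda(X, y, n_components=1)
        assert m.r2y == pytest.approx(1.0)
        np.testing.assert_allclose(m.weights, [[1.0]])

    def test_first_weight_is_covariance_eigendirection(self, rng):
        """w1 equals the dominant eigenvector of X'yy'X (up to sign)."""
        X = rng.normal(size=(10, 4))
        y = _binary_y(rng, 10)
        m = fit_plsda(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        M = np.outer(Xc.T @ yc, yc @ Xc)
        vals, vecs = np.linalg.eigh(M)
        lead = vecs[:, np.argmax(vals)]
        lead = lead * np.sign(lead[np.argmax(np.abs(lead))])
        np.testing.assert_allclose(m.weights[:, 0], lead, atol=1e-10)

    def test_nipals_first_component_many_random_instances(self, rng):
        """Closed-form check over 100 random instances (oracle equivalence)."""
        for _ in range(100):
            X = rng.normal(size=(10, 10))
            y = _binary_y(rng, 10)
            m = fit_plsda(X, y, 1)
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            w = Xc.T @ yc
            w = w / np.linalg.norm(w)
            w = w * np.sign(w[np.argmax(np.abs(w))])
            assert np.max(np.abs(m.weights[:, 0] - w)) < 1e-8

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(16, 5))
        y = _binary_y(rng, 16)
        perm = rng.permutation(16)
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X[perm], y[perm], 2)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)
        np.testing.assert_allclose(m1.r2y, m2.r2y, atol=1e-12)

    def test_matches_sklearn_pls_regression(self, rng):
        X = rng.normal(size=(30, 8))
        y = _binary_y(rng, 30)
        m = fit_plsda(X, y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y.astype(float))
        for a in range(3):
            r = abs(np.corrcoef(m.scores[:, a], sk.x_scores_[:, a])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(predict(m, X), sk.predict(X).ravel(), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_plsda(np.random.default_rng(0).normal(size=(6, 3)), np.zeros(6), 1)

    def test_rank_bound_enforced(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array([0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, y, n_components=4)

    def test_predictive_scores_orthogonal(self, rng):
        X = rng.normal(size=(25, 10))
        y = _binary_y(rng, 25)
        m = fit_plsda(X, y, 4)
        gram = m.scores.T @ m.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()


class TestOplsda:
    def test_orthogonal_scores_perpendicular_to_t1(self, rng):
        X = rng.normal(size=(30, 8))
        y = _binary_y(rng, 30)
        m = fit_oplsda(X, y, n_orthogonal=2)
        for a in range(m.n_orthogonal):
            to = m.ortho_scores[:, a]
            if not np.any(to):
                continue
            denom = np.linalg.norm(m.t1) * np.linalg.norm(to)
            assert abs(m.t1 @ to) < 1e-8 * denom

    def test_no_orthogonal_structure_reduces_to_plsda(self, rng):
        """X built purely from the class axis: t_orth ~ 0 and t1 = PLS t1."""
        y = _binary_y(rng, 24)
        t = (y - y.mean()) + 0.01 * rng.normal(size=24)
        c = rng.normal(size=5)
        X = np.outer(t, c)
        m = fit_oplsda(X, y, 1)
        pls = fit_plsda(X, y, 1)
        assert np.linalg.norm(m.ortho_scores) < 1e-6 * np.linalg.norm(m.t1)
        r = abs(np.corrcoef(m.t1, pls.t1)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_r2y_equals_two_component_plsda(self, rng):
        """Known equivalence of total explained y-variation on a 20x6 instance."""
        X = rng.normal(size=(20, 6))
        y = _binary_y(rng, 20)
        assert fit_oplsda(X, y, 1).r2y == pytest.approx(fit_plsda(X, y, 2).r2y, abs=1e-10)

    def test_rank_deficient_x_degrades_to_zero_orthogonal(self):
        """Rank-1 X offers no orthogonal structure: components stay zero."""
        X = np.outer(np.arange(6.0), np.ones(4))
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_oplsda(X, y, n_orthogonal=2)
        assert not np.any(m.ortho_scores)
        assert m.r2y == pytest.approx(fit_plsda(X, y, 1).r2y, abs=1e-10)


class TestVip:
    def test_single_feature_is_unity(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        np.testing.assert_allclose(vip_scores(fit_plsda(X, y, 1)), [1.0])

    def test_one_component_closed_form(self):
        """w = (1, 0) gives VIP = (sqrt(2), 0)."""
        rng = np.random.default_rng(3)
        signal = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        X = np.column_stack([signal, np.full(6, 0.0)])
        X[:, 1] = 1e-12 * rng.normal(size=6)  # break exact zero variance
        y = np.array([0, 0, 0, 1, 1, 1])
        vip = vip_scores(fit_plsda(X, y, 1))
        np.testing.assert_allclose(vip, [np.sqrt(2), 0.0], atol=1e-5)

    def test_direct_formula_oracle(self, rng):
        X = rng.normal(size=(15, 3))
        y = _binary_y(rng, 15)
        m = fit_plsda(X, y, 2)
        ssy = m.y_loadings**2 * (m.scores**2).sum(axis=0)
        expected = np.sqrt(3 * (m.weights**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip_scores(m), expected, atol=1e-12)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_squared_scores_average_to_one(self, rng, n_components):
        X = rng.normal(size=(40, 12))
        y = _binary_y(rng, 40)
        vip = vip_scores(fit_plsda(X, y, n_components))
        assert (vip**2).sum() == pytest.approx(12, abs=1e-8)

    def test_manual_threshold_reproduces_study_settings(self, rng):
        X = rng.normal(size=(40, 20))
        y = _binary_y(rng, 40)
        m = fit_plsda(X, y, 2)
        for thr in (1.5, 1.4):
            table, used = vip_table(m, threshold=thr)
            assert used == thr
            assert (table["selected"] == (table["vip"] >= thr)).all()

    def test_planted_features_rank_above_null(self, default_pipeline_state):
        from sklearn.metrics import roc_auc_score

        st = default_pipeline_state
        m = fit_plsda(st["scaled"].data, st["y"], 2)
        vip = vip_scores(m)
        truth = st["ds"].truth.differential_flags.loc[vip.index]
        assert roc_auc_score(truth, vip) > 0.9


class TestQ2AndPermutation:
    def test_null_q2_is_nonpositive_on_average(self, rng):
        vals = []
        for _ in range(50):
            X = rng.normal(size=(24, 10))
            y = _binary_y(rng, 24)
            vals.append(cross_validate_q2(X, y, 2, seed=int(rng.integers(2**31))))
        assert np.mean(vals) <= 0.0

    def test_strong_planted_effect_gives_high_q2(self):
        ds = generate_dataset(SynthConfig(log2fc_magnitudes=(0.8, 1.5), seed=2))
        X = pqn_normalize(ds.features).normalized.data
        y = (ds.metadata["group"] == "Prem").astype(int).to_numpy()
        assert cross_validate_q2(X, y, 2, seed=1) > 0.5

    def test_sample_duplication_does_not_destroy_q2(self, rng):
        ds = generate_dataset(SynthConfig(n_term=30, n_prem=15, n_metabolites=30,
                                          n_blocks=5, n_prem_specific_edges=4, seed=8))
        X = pqn_normalize(ds.features).normalized.data.to_numpy()
        y = (ds.metadata["group"] == "Prem").astype(int).to_numpy()
        base = cross_validate_q2(X, y, 2, seed=3)
        dup = cross_validate_q2(np.vstack([X, X]), np.concatenate([y, y]), 2, seed=3)
        assert dup > base - 0.1

    def test_perfect_separation_gives_minimum_p(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 12 + [1] * 12)
        X = np.column_stack([y + 0.01 * rng.normal(size=24), rng.normal(size=24)])
        res = permutation_test(X, y, 1, n_permutations=200, seed=4)
        assert res.p_q2y == pytest.approx(1 / 201)
        assert res.p_r2y <= 5 / 201

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(20, 6))
        y = _binary_y(rng, 20)
        r1 = permutation_test(X, y, 2, n_permutations=30, seed=9)
        r2 = permutation_test(X, y, 2, n_permutations=30, seed=9)
        np.testing.assert_array_equal(r1.permuted_q2y, r2.permuted_q2y)
        assert r1.p_q2y == r2.p_q2y

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.normal(size=(10, 3)), _binary_y(rng, 10), 1, n_permutations=0)


class TestNormalityThreshold:
    def test_planted_outliers_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bulk = rng.normal(5.0, 1.0, size=200)
            outliers = rng.normal(12.0, 0.3, size=10)
            scores = np.concatenate([bulk, outliers])
            thr = normality_threshold(scores)
            selected = scores >= thr
            hits += selected.sum() == 10 and set(np.where(selected)[0]) == set(range(200, 210))
        assert hits >= 18

    def test_pure_normal_selects_nothing(self):
        rng = np.random.default_rng(12)
        thr = normality_threshold(rng.normal(5.0, 1.0, size=200))
        assert np.isinf(thr)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="manual"):
            normality_threshold(np.arange(5, dtype=float))

    def test_single_spike_among_zeros(self):
        scores = np.zeros(14)
        scores[-1] = 9.0
        thr = normality_threshold(scores)
        assert thr == pytest.approx(9.0)

    def test_all_zero_scores_select_nothing(self):
        assert np.isinf(normality_threshold(np.zeros(12)))
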