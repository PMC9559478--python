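"""NIPALS PLS-DA: oracle equivalences, VIP identities, component selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from grassmilk import simdata
from grassmilk.errors import EmptySubsetError, InputError, SchemaError
from grassmilk.plsda import (
    VipTable,
    compute_vip,
    fit_pls,
    load_model,
    reduce_by_vip,
    save_model,
    select_n_components,
)

from conftest import sparse_signal_schema


def _random_problem(seed, n=20, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (rng.normal(size=n) > 0).astype(float)
    return X, y


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_least_squares(self, seed):
        """With A = rank(X), PLS predictions are the least-squares solution."""
        X, y = _random_problem(seed)
        model = fit_pls(X, y, 5)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        b_ols = np.linalg.lstsq(
            np.column_stack([Xs, np.ones(len(y))]), y, rcond=None
        )[0][:5]
        assert np.abs(model.coefficients - b_ols).max() < 1e-8

    def test_first_weight_proportional_to_covariance(self):
        X, y = _random_problem(3)
        model = fit_pls(X, y, 1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = Xs.T @ (y - y.mean())
        cov /= np.linalg.norm(cov)
        assert np.allclose(model.W[:, 0], cov, atol=1e-10)

    def test_duplicated_column_matches_deduplicated_at_full_rank(self):
        X, y = _random_problem(1, n=30, p=4)
        X_dup = np.column_stack([X, X[:, 0]])
        m_dup = fit_pls(X_dup, y, 4)  # early-stops at the effective rank
        m_base = fit_pls(X, y, 4)
        pred_dup = m_dup.decision_scores(X_dup)
        pred_base = m_base.decision_scores(X)
        assert np.abs(pred_dup - pred_base).max() < 1e-8

    def test_constant_column_dropped_with_warning(self):
        X, y = _random_problem(2)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_pls(X, y, 3)
        assert len(model.predictor_names) == 4
        assert "x2" in model.dropped

    def test_component_count_exceeding_rank_limit_rejected(self):
        X, y = _random_problem(0, n=6, p=10)
        with pytest.raises(InputError):
            fit_pls(X, y, 8)  # > n - 1

    def test_scores_orthogonal_and_coefficient_identity(self):
        """ŷ from the (W, P, q) decomposition equals ŷ from b."""
        X, y = _random_problem(4, n=40, p=8)
        model = fit_pls(X, y, 6)
        Xs = (X - model.means) / model.scales
        T = Xs @ model.R  # scores in the undeflated basis
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        via_components = T @ model.q + model.y_mean
        via_b = model.decision_scores(X)
        assert np.abs(via_components - via_b).max() < 1e-8

    @pytest.mark.parametrize("a", [1, 2, 4])
    def test_matches_reference_pls_implementation(self, a):
        X, y = _random_problem(6, n=50, p=8)
        model = fit_pls(X, y, a)
        ref = PLSRegression(n_components=a, scale=True).fit(X, y)
        assert np.abs(
            ref.predict(X).ravel() - model.decision_scores(X)
        ).max() < 1e-10


class TestProbability:
    def test_two_class_probabilities_sum_to_one(self):
        X, y = _random_problem(5, n=60, p=6)
        model = fit_pls(X, y, 3)
        p_grass = model.predict_grass_probability(X)
        assert np.all((p_grass >= 0) & (p_grass <= 1))
        # NOGRASS probability is the complement; argmax = 0.5 threshold
        modality = model.predict_modality(X)
        assert np.array_equal(modality == "GRASS", p_grass >= 0.5)

    def test_maximal_score_row_is_grass(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(float)
        model = fit_pls(X, y, 2)
        scores = model.decision_scores(X)
        top = int(np.argmax(scores))
        assert model.predict_grass_probability(X)[top : top + 1] > 0.5
        assert model.predict_modality(X)[top] == "GRASS"

    def test_separation_on_simulated_records(self, small_dataset, schema):
        records, _, _ = small_dataset
        sub = records[records["latent_g"].isin([0.0]) | (records["latent_g"] > 0.95)]
        y = (sub["latent_g"] > 0.95).astype(float).to_numpy()
        model = fit_pls(sub[schema.names], y, 5)
        prob = model.predict_grass_probability(sub[schema.names])
        assert prob[y == 1].mean() - prob[y == 0].mean() > 0.5

    def test_missing_column_rejected(self):
        X, y = _random_problem(2)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(5)])
        model = fit_pls(df, y, 2)
        with pytest.raises(SchemaError, match="x4"):
            model.predict_grass_probability(df.drop(columns=["x4"]))


class TestSelection:
    def test_cap_respected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 40))
        y = (X[:, :5].sum(1) + rng.normal(size=300) > 0).astype(float)
        a_star, _ = select_n_components(X, y, max_components=30, k=5, seed=0)
        assert 1 <= a_star <= 30

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 20))
        y = (rng.normal(size=500) > 0).astype(float)
        a_star, curve = select_n_components(X, y, max_components=10, k=10, seed=2)
        assert 0.45 <= curve[a_star - 1] <= 0.6

    def test_perfect_predictor_selects_one_component(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        y = (rng.random(200) > 0.5).astype(float)
        # x0 separates the classes with a wide margin
        X[:, 0] = np.where(y == 1, 2.0, -2.0) + 0.3 * rng.normal(size=200)
        a_star, curve = select_n_components(X, y, max_components=6, k=5, seed=3)
        assert curve[0] == 1.0
        assert a_star == 1


class TestVip:
    def _orthonormal_fit(self, weights):
        """Fit whose first (only) weight vector is exactly ``weights``."""
        rng = np.random.default_rng(0)
        M = rng.normal(size=(64, 4))
        Q, _ = np.linalg.qr(M - M.mean(0))  # zero-mean orthonormal columns
        X = Q * np.sqrt(63)  # exactly unit sample variance
        w = np.asarray(weights, dtype=float)
        y = X @ w
        return fit_pls(X, y, 1)

    def test_symmetric_weights_give_unit_vip(self):
        model = self._orthonormal_fit([1.0, 1.0, 1.0, 1.0])
        vip = compute_vip(model)
        assert np.allclose(vip.raw, 1.0, atol=1e-8)

    def test_single_carrier_closed_form(self):
        model = self._orthonormal_fit([1.0, 0.0, 0.0, 0.0])
        vip = compute_vip(model)
        assert np.allclose(vip.raw, [2.0, 0.0, 0.0, 0.0], atol=1e-8)
        assert np.allclose(vip.scaled, [100.0, 0.0, 0.0, 0.0], atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_mean_square_normalization_identity(self, seed):
        X, y = _random_problem(seed, n=40, p=9)
        vip = compute_vip(fit_pls(X, y, 4))
        assert abs((vip.raw**2).mean() - 1.0) < 1e-8
        assert abs(vip.scaled.max() - 100.0) < 1e-8

    def test_permutation_equivariance(self):
        X, y = _random_problem(7, n=50, p=6)
        perm = np.array([3, 0, 5, 1, 4, 2])
        vip = compute_vip(fit_pls(X, y, 3))
        vip_p = compute_vip(fit_pls(X[:, perm], y, 3))
        assert np.allclose(vip.raw[perm], vip_p.raw, atol=1e-10)


class TestReduceByVip:
    def test_threshold_boundaries(self):
        X, y = _random_problem(0, n=40, p=8)
        vip = compute_vip(fit_pls(X, y, 3))
        assert len(reduce_by_vip(vip, 0.0)) == 8
        top = reduce_by_vip(vip, 100.0)
        assert top == [vip.predictor_names[int(np.argmax(vip.scaled))]]

    def test_empty_subset_rejected(self):
        vip = VipTable(["a", "b"], np.array([0.1, 0.2]), np.array([10.0, 20.0]))
        with pytest.raises(EmptySubsetError):
            reduce_by_vip(vip, 50.0)
        with pytest.raises(InputError):
            reduce_by_vip(vip, 120.0)

    def test_signal_predictors_survive_threshold_50(self):
        """Traits that respond to grass dominate the VIP ranking."""
        schema = sparse_signal_schema(n_signal=10, n_total=48)
        records, _, _ = simdata.generate_dataset(
            40, 2, archetype_mix={"extensive": 1.0}, schema=schema, seed=21
        )
        sub = records[records["month"].isin([7, 8, 1, 2])]
        y = sub["month"].isin([7, 8]).astype(float).to_numpy()
        model = fit_pls(sub[schema.names], y, 10)
        vip = compute_vip(model)
        retained = set(reduce_by_vip(vip, 50.0))
        signal = {f"t{j:02d}" for j in range(10)}
        assert signal <= retained


def test_model_serialization_roundtrip(tmp_path):
    X, y = _random_problem(9, n=40, p=6)
    model = fit_pls(X, y, 3)
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.predictor_names == model.predictor_names
    assert np.allclose(loaded.decision_scores(X), model.decision_scores(X))
    assert np.allclose(
        loaded.predict_grass_probability(X), model.predict_grass_probability(X)
    )
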