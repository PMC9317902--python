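"""Feature ranking, stepwise SVM fitting, validation metrics, and the AD rule."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qsarscreen as qs
from qsarscreen.chem import Dataset, MoleculeRecord
from qsarscreen.qsar import pve, rmse


def _dataset_from_matrix(X, y, endpoint="t"):
    records = [MoleculeRecord(f"r{i}", "C", "C") for i in range(len(y))]
    return Dataset(records=records, endpoint=endpoint,
                   y=np.asarray(y, float), X=np.asarray(X),
                   scheme="atompair", nbits=X.shape[1])


class TestMetrics:
    def test_pve_perfect_and_null(self):
        y = np.array([1.0, 2.0, 3.0])
        assert pve(y, y) == pytest.approx(1.0)
        assert pve(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_pve_hand_computed(self):
        assert pve([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_rmse_values(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [1, 1]) == pytest.approx(1.0)
        assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5774, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pve([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])   # constant y

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_pve_rmse_identity(self, seed):
        # PVE == 1 - n * RMSE^2 / SStot for any paired vectors
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        y = rng.normal(size=n)
        yhat = rng.normal(size=n)
        sstot = np.sum((y - y.mean()) ** 2)
        assert pve(y, yhat) == pytest.approx(
            1 - n * rmse(y, yhat) ** 2 / sstot, abs=1e-10)


class TestRankFeatures:
    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(40, 16)).astype(np.uint8)
        ds = _dataset_from_matrix(X, np.ones(40))
        with pytest.warns(UserWarning):
            ranking = qs.rank_features(ds, n_trees=20, seed=0)
        assert np.all(ranking.vi_scores == 0)
        np.testing.assert_array_equal(ranking.order, np.arange(16))

    def test_single_informative_bit_ranked_first(self):
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 2, size=(200, 32)).astype(np.uint8)
            y = 3.0 * X[:, 17] + rng.normal(0, 0.1, 200)
            ds = _dataset_from_matrix(X, y)
            ranking = qs.rank_features(ds, n_trees=80, seed=seed)
            hits += ranking.order[0] == 17
        assert hits >= 5   # first-ranked in nearly all seeds

    def test_independent_response_has_no_standout_importance(self):
        # with y unrelated to the bits, the top importance should be far
        # below what a genuinely informative bit earns on the same X
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(150, 32)).astype(np.uint8)
        y_null = rng.normal(size=150)
        y_info = 3.0 * X[:, 5] + rng.normal(0, 0.1, 150)
        vi_null = qs.rank_features(_dataset_from_matrix(X, y_null),
                                   n_trees=60, seed=0).vi_scores
        vi_info = qs.rank_features(_dataset_from_matrix(X, y_info),
                                   n_trees=60, seed=0).vi_scores
        assert vi_null.max() < 0.5 * vi_info[5]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(60, 24)).astype(np.uint8)
        y = X[:, 3] + rng.normal(0, 0.2, 60)
        ds = _dataset_from_matrix(X, y)
        a = qs.rank_features(ds, n_trees=30, seed=9)
        b = qs.rank_features(ds, n_trees=30, seed=9)
        np.testing.assert_array_equal(a.order, b.order)
        np.testing.assert_allclose(a.vi_scores, b.vi_scores)

    def test_too_few_rows_rejected(self):
        X = np.zeros((10, 8), dtype=np.uint8)
        ds = _dataset_from_matrix(X, np.arange(10.0))
        with pytest.raises(ValueError):
            qs.rank_features(ds, n_trees=10, seed=0)


class TestStepwiseFit:
    def test_identical_seed_identical_curve(self, small_bench):
        ranking = qs.rank_features(small_bench.train, n_trees=30, seed=4)
        c1, _ = qs.stepwise_fit(small_bench.train, ranking,
                                k_grid=[2, 8, 16], seed=4)
        c2, _ = qs.stepwise_fit(small_bench.train, ranking,
                                k_grid=[2, 8, 16], seed=4)
        assert c1.cv_rmse == c2.cv_rmse

    def test_selected_bits_prefix_of_ranking(self, small_model):
        curve, model = small_model
        np.testing.assert_array_equal(
            model.selected_bits, model.ranking.order[:curve.best_k])

    def test_best_k_tie_breaks_to_smaller_k(self):
        curve = qs.StepwiseCurve(k_values=[2, 5, 10], cv_rmse=[0.3, 0.2, 0.2])
        assert curve.best_k == 5

    def test_curve_invariant_to_tail_relabeling(self, small_bench):
        # bits never entering a prefix cannot influence the curve
        ranking = qs.rank_features(small_bench.train, n_trees=30, seed=4)
        shuffled = copy.deepcopy(ranking)
        rng = np.random.default_rng(0)
        tail = shuffled.order[16:].copy()
        shuffled.order[16:] = tail[rng.permutation(tail.size)]
        c1, _ = qs.stepwise_fit(small_bench.train, ranking,
                                k_grid=[2, 8, 16], seed=4)
        c2, _ = qs.stepwise_fit(small_bench.train, shuffled,
                                k_grid=[2, 8, 16], seed=4)
        assert c1.cv_rmse == pytest.approx(c2.cv_rmse)

    def test_k_grid_bounds_checked(self, small_bench):
        ranking = qs.rank_features(small_bench.train, n_trees=20, seed=0)
        with pytest.raises(ValueError):
            qs.stepwise_fit(small_bench.train, ranking, k_grid=[10_000])


class TestExternalValidation:
    def test_overlap_with_training_set_rejected(self, small_bench, small_model):
        _, model = small_model
        with pytest.raises(ValueError, match="overlap"):
            qs.external_validate(model, small_bench.train)

    def test_beats_permuted_control(self, small_bench, small_model):
        _, model = small_model
        real = qs.external_validate(model, small_bench.ivs)
        # same fingerprints, response permuted: model carries no information
        permuted = copy.deepcopy(small_bench.ivs)
        rng = np.random.default_rng(0)
        permuted.y = permuted.y[rng.permutation(len(permuted))]
        control = qs.external_validate(model, permuted)
        assert real.r2 > control.r2
        assert real.pve > 0.3

    def test_metrics_internally_consistent(self, small_bench, small_model):
        _, model = small_model
        m = qs.external_validate(model, small_bench.ivs)
        assert m.pve <= 1 and m.rmse >= 0 and 0 <= m.r2 <= 1
        assert m.n == len(small_bench.ivs)


class TestApplicabilityDomain:
    def _model_with_fps(self, fps):
        ds = _dataset_from_matrix(np.asarray(fps, dtype=np.uint8),
                                  np.arange(float(len(fps))))
        # minimal fitted model wrapper: reuse a tiny stepwise fit
        ranking = qs.FeatureRanking(order=np.arange(ds.X.shape[1]),
                                    vi_scores=np.zeros(ds.X.shape[1]),
                                    n_trees=0, seed=0)
        from sklearn.svm import SVR
        reg = SVR().fit(ds.X.astype(float), ds.y)
        return qs.QsarModel(endpoint="t", ranking=ranking,
                            selected_bits=np.arange(ds.X.shape[1]),
                            regressor=reg, train_fingerprints=ds.X,
                            train_smiles=[r.id for r in ds.records],
                            metadata={"scheme": "atompair"})

    def _bits(self, on, n=16):
        v = np.zeros(n, dtype=np.uint8)
        v[list(on)] = 1
        return v

    def test_exact_duplicate_in_domain(self):
        model = self._model_with_fps([self._bits({1, 2, 3}), self._bits({4, 5})])
        v = qs.applicability_domain(self._bits({1, 2, 3}), model)
        assert v.nn_similarity == 1.0 and v.in_domain

    def test_disjoint_bits_out_of_domain(self):
        model = self._model_with_fps([self._bits({1, 2, 3})])
        v = qs.applicability_domain(self._bits({10, 11}), model)
        assert v.nn_similarity == 0.0 and v.nn_distance == 1.0
        assert not v.in_domain

    def test_tanimoto_set_arithmetic(self):
        # {1,2,3,4} vs {2,3,4,5}: intersection 3, union 5 -> similarity 0.6
        model = self._model_with_fps([self._bits({2, 3, 4, 5})])
        v = qs.applicability_domain(self._bits({1, 2, 3, 4}), model)
        assert v.nn_similarity == pytest.approx(0.6)
        assert v.in_domain   # distance 0.4 <= 0.7

    def test_threshold_extremes(self):
        model = self._model_with_fps([self._bits({1, 2, 3})])
        near = self._bits({1, 2})
        dup = self._bits({1, 2, 3})
        assert not qs.applicability_domain(near, model, threshold=0.0).in_domain
        assert qs.applicability_domain(dup, model, threshold=0.0).in_domain
        far = self._bits({9})
        assert qs.applicability_domain(far, model, threshold=1.0).in_domain

    def test_similarity_rule_variant(self):
        model = self._model_with_fps([self._bits({2, 3, 4, 5})])
        q = self._bits({1, 2, 3, 4})   # similarity 0.6
        assert not qs.applicability_domain(q, model, 0.7, rule="similarity").in_domain
        assert qs.applicability_domain(q, model, 0.5, rule="similarity").in_domain


class TestPredict:
    def test_training_molecules_in_domain(self, small_bench, small_model):
        _, model = small_model
        table = qs.predict(model, small_bench.train.records[:10])
        assert table["in_domain"].all()
        assert len(table) == 10

    def test_empty_input(self, small_model):
        _, model = small_model
        assert len(qs.predict(model, [])) == 0

    def test_unparsable_flagged_not_dropped(self, small_model):
        _, model = small_model
        table = qs.predict(model, ["CCO", "???bad???"])
        assert len(table) == 2
        assert table.loc[1, "parse_error"] and np.isnan(table.loc[1, "prediction"])

    def test_rank_correlation_with_latent_truth(self, small_bench, small_model):
        from scipy import stats
        _, model = small_model
        table = qs.predict(model, small_bench.ivs.records)
        latent_by_smiles = dict(zip(small_bench.library.canonical_smiles,
                                    small_bench.truth.latent))
        latent = [latent_by_smiles[s] for s in table["smiles"]]
        rho = stats.spearmanr(table["prediction"], latent)
        assert rho.statistic > 0 and rho.pvalue < 0.01


class TestSerialization:
    def test_round_trip_predictions_exact(self, small_bench, small_model, tmp_path):
        _, model = small_model
        qs.save_model(model, tmp_path / "m")
        loaded = qs.load_model(tmp_path / "m")
        a = qs.predict(model, small_bench.ivs.records[:8])
        b = qs.predict(loaded, small_bench.ivs.records[:8])
        np.testing.assert_array_equal(a["prediction"].values, b["prediction"].values)
        assert loaded.endpoint == model.endpoint
        np.testing.assert_array_equal(loaded.selected_bits, model.selected_bits)
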