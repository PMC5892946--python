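"""KNN growth model: weights, pseudo-data, folds, occupancy, selection."""

import numpy as np
import pandas as pd
import pytest

import growthmap as gm
from growthmap.knn_growth import (
    CvResult,
    KnnGrowthModel,
    SelectionConfig,
    cross_validate,
    forward_select,
    knn_weights,
    log_occupation_ratio,
    make_noise_profiles,
    make_pseudocounts,
    occupancy_log_ratio,
    predict_growth,
    predict_many,
    residual_score,
    stratified_folds,
)
from growthmap.synthetic_data import DEFAULT_NOISE


class TestKnnWeights:
    def test_equidistant_neighbors_split_evenly(self):
        w = knn_weights(np.array([0.0, 0.0]), np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert np.allclose(w, [0.5, 0.5])

    def test_distances_one_and_two(self):
        w = knn_weights(np.array([0.0]), np.array([[1.0], [2.0]]))
        assert np.allclose(w, [0.8, 0.2])

    def test_exact_match_takes_all_weight(self):
        w = knn_weights(np.array([1.0]), np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(w, [1.0, 0.0, 0.0])

    def test_empty_neighbors_rejected(self):
        with pytest.raises(ValueError):
            knn_weights(np.array([0.0]), np.empty((0, 1)))

    def test_weights_nonnegative_and_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = knn_weights(rng.normal(size=3), rng.normal(size=(6, 3)))
            assert w.min() >= 0
            assert w.sum() == pytest.approx(1.0)


class TestPredictGrowth:
    def test_shared_growth_is_returned_exactly(self):
        model = KnnGrowthModel(np.arange(8.0)[:, None], np.full(8, 0.77), k=4)
        assert predict_growth(np.array([2.3]), model) == pytest.approx(0.77)

    def test_training_point_returns_its_growth(self):
        model = KnnGrowthModel(np.arange(5.0)[:, None], np.arange(5.0) / 10, k=3)
        assert predict_growth(np.array([3.0]), model) == pytest.approx(0.3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 4))
        growth = rng.uniform(0, 1, 30)
        model = KnnGrowthModel(coords, growth, k=8)
        for _ in range(10):
            q = rng.normal(size=4)
            d2 = ((coords - q) ** 2).sum(axis=1)
            nearest = np.argsort(d2, kind="stable")[:8]
            inv = 1.0 / d2[nearest]
            expected = float((inv / inv.sum()) @ growth[nearest])
            assert predict_growth(q, model) == pytest.approx(expected, abs=1e-12)

    def test_prediction_within_neighbor_growth_range(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(20, 2))
        growth = rng.uniform(0.2, 0.9, 20)
        model = KnnGrowthModel(coords, growth, k=5)
        preds = predict_many(rng.normal(size=(15, 2)), model)
        assert (preds >= growth.min() - 1e-12).all()
        assert (preds <= growth.max() + 1e-12).all()

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError):
            KnnGrowthModel(np.ones((3, 1)), np.ones(3), k=5)


class TestResidualScore:
    def test_examples_and_oracle(self):
        assert residual_score([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert residual_score([1.5], [1.0]) == pytest.approx(0.25)
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 40))
        assert residual_score(a, b) == pytest.approx(sum((x - y) ** 2 for x, y in zip(a, b)))
        with pytest.raises(ValueError):
            residual_score([1.0], [1.0, 2.0])


class TestNoiseProfiles:
    def test_count_is_multiplier_times_m(self, small_compendium):
        matrix, growth = small_compendium
        annotated = matrix.subset_samples(list(growth["sample_id"]))
        pseudo, pg, parents = make_noise_profiles(
            annotated, growth["rate_per_h"].to_numpy(), multiplier=4, seed=0
        )
        assert pseudo.n_samples == 4 * annotated.n_samples
        assert pg.size == 4 * annotated.n_samples

    def test_growth_inherited_and_parent_indexing(self, small_compendium):
        matrix, growth = small_compendium
        annotated = matrix.subset_samples(list(growth["sample_id"]))
        rates = growth["rate_per_h"].to_numpy()
        pseudo, pg, parents = make_noise_profiles(annotated, rates, multiplier=3, seed=1)
        assert np.allclose(pg, rates[parents])
        assert pseudo.values.min() >= 0.0

    def test_zero_mean_genes_stay_zero(self):
        m = gm.ExpressionMatrix(["g0", "g1"], ["s0"], np.array([[0.0], [10.0]]))
        pseudo, _, _ = make_noise_profiles(m, np.array([0.5]), multiplier=5, seed=2)
        assert np.all(pseudo.values[0] == 0.0)


class TestPseudocounts:
    def test_one_dimensional_pair(self):
        points = make_pseudocounts(np.array([[0.0], [2.0]]), seed=0)
        assert sorted(points.ravel()) == pytest.approx([-1.0, 3.0])

    def test_all_points_on_shell(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(12, 3))
        points = make_pseudocounts(coords, seed=1)
        center = coords.mean(axis=0)
        d = max(
            np.linalg.norm(a - b) for a in coords for b in coords
        )
        radii = np.linalg.norm(points - center, axis=1)
        assert np.allclose(radii, d, atol=1e-8)

    def test_pair_budget_floor(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(10, 2))
        points = make_pseudocounts(coords, seed=2)
        # floor(10*9/16) = 5 pairs, two intersection points each
        assert points.shape[0] == 10

    def test_degenerate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            make_pseudocounts(np.zeros((5, 2)), seed=0)


class TestStratifiedFolds:
    def test_balanced_sizes(self):
        folds = stratified_folds(np.arange(10.0), 5, seed=0)
        assert np.bincount(folds).tolist() == [2, 2, 2, 2, 2]

    def test_fold_means_close_to_global(self):
        rng = np.random.default_rng(6)
        growth = rng.uniform(0, 1, 60)
        folds = stratified_folds(growth, 5, seed=1)
        spacing = np.diff(np.sort(growth)).max()
        for f in range(5):
            assert abs(growth[folds == f].mean() - growth.mean()) < 5 * spacing

    def test_stratification_beats_random_splits(self):
        """Each stratified fold tracks the full growth distribution more
        closely (KS distance) than the bulk of unstratified random splits."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(7)
        growth = rng.gamma(3.0, 0.2, 50)
        folds = stratified_folds(growth, 5, seed=2)
        strat_ks = max(
            ks_2samp(growth[folds == f], growth).statistic for f in range(5)
        )
        random_ks = []
        for _ in range(100):
            perm = rng.permutation(50) % 5
            random_ks.append(
                max(ks_2samp(growth[perm == f], growth).statistic for f in range(5))
            )
        assert strat_ks <= np.percentile(random_ks, 5)

    def test_errors(self):
        with pytest.raises(ValueError):
            stratified_folds([1.0, 2.0], 1)
        with pytest.raises(ValueError):
            stratified_folds([1.0, 2.0], 3)


class TestOccupancy:
    def test_fully_occupied_grid_plug_in(self):
        # one eigengene with 10 bins, 13 growth bins, all 130 cells occupied
        assert log_occupation_ratio(130, 13, [10]) == pytest.approx(np.log(10))

    def test_sparse_occupancy_is_negative(self):
        assert log_occupation_ratio(1, 2, [2]) == pytest.approx(-3 * np.log(2))

    def test_merge_rule_reduces_bins(self):
        """Projections concentrated in a narrow band merge their deciles."""
        rng = np.random.default_rng(8)
        growth = rng.uniform(0, 1, 130)
        tight = 1000.0 + rng.normal(0, 1e-4, 130)  # deciles nearly coincide
        spread = rng.normal(0, 5.0, 130)
        cfg = SelectionConfig()
        l_tight = occupancy_log_ratio(tight[:, None], growth, cfg)
        l_spread = occupancy_log_ratio(spread[:, None], growth, cfg)
        # merged bins mean fewer occupied cells and fewer N_i for the tight case
        assert l_tight < l_spread

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            occupancy_log_ratio(np.empty((0, 1)), [])


class TestCrossValidate:
    def test_every_sample_predicted_once(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(30, 2))
        growth = rng.uniform(0.1, 1.0, 30)
        result = cross_validate(coords, growth, k=4, seed=0)
        assert isinstance(result, CvResult)
        assert np.isfinite(result.predictions).all()
        assert np.bincount(result.folds).sum() == 30

    def test_noise_free_linear_structure_high_r2(self):
        rng = np.random.default_rng(10)
        coords = rng.uniform(-1, 1, size=(60, 1))
        growth = 0.6 + 0.25 * coords.ravel()
        result = cross_validate(coords, growth, k=4, seed=1)
        assert result.r2 >= 0.99

    def test_shuffled_labels_destroy_signal(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-1, 1, size=(60, 1))
        growth = 0.6 + 0.25 * coords.ravel()
        shuffled = rng.permutation(growth)
        result = cross_validate(coords, shuffled, k=4, seed=1)
        assert result.r2 < 0.2

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(25, 2))
        growth = rng.uniform(0.1, 1.0, 25)
        a = cross_validate(coords, growth, k=3, seed=7)
        b = cross_validate(coords, growth, k=3, seed=7)
        assert np.array_equal(a.predictions, b.predictions)


class TestForwardSelect:
    @staticmethod
    def _planted(seed=13, n=80, noise=0.02):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 6))
        growth = np.clip(0.6 + 0.3 * coords[:, 2] + rng.normal(0, noise, n), 0, None)
        return coords, growth

    def test_first_selection_is_informative_dimension(self):
        coords, growth = self._planted()
        model, history = forward_select(coords, growth, k=4, seed=0)
        assert history.iloc[0]["added"] == 2
        assert 2 in model.selected_indices

    def test_parsimony_on_planted_data(self):
        coords, growth = self._planted()
        model, history = forward_select(coords, growth, k=4, seed=0)
        assert len(model.selected_indices) <= 3

    def test_lambda_zero_reduces_to_residual_objective(self):
        coords, growth = self._planted()
        cfg = SelectionConfig(lam=0.0)
        _, history = forward_select(coords, growth, k=4, cfg=cfg, seed=0)
        assert np.allclose(history["objective"], history["r"])

    def test_bitwise_deterministic(self):
        coords, growth = self._planted()
        m1, h1 = forward_select(coords, growth, k=4, seed=3)
        m2, h2 = forward_select(coords, growth, k=4, seed=3)
        assert m1.selected_indices == m2.selected_indices
        assert np.array_equal(m1.coords, m2.coords)
        pd.testing.assert_frame_equal(h1, h2)


class TestModelPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        model = KnnGrowthModel(
            rng.normal(size=(20, 3)), rng.uniform(0, 1, 20), k=5,
            selected_indices=[4, 0, 2],
        )
        model.save(tmp_path / "model")
        back = KnnGrowthModel.load(tmp_path / "model")
        assert back.k == 5
        assert back.selected_indices == [4, 0, 2]
        q = rng.normal(size=3)
        assert predict_growth(q, back) == pytest.approx(predict_growth(q, model))


class TestTrainingCorpus:
    def test_combined_counts(self):
        corpus = gm.TrainingCorpus(
            n_curated_with_growth=10, n_curated_without_growth=5,
            n_measured_with_growth=2,
        )
        assert corpus.n_with_growth == 12
        assert corpus.n_profiles == 17
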