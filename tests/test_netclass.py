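"""Grid features, penalized multinomial fits, bagging, ROC, predictors."""
import warnings

import numpy as np
import pytest
from scipy import stats

from mousefc import _lasso, netclass
from mousefc.netclass import GridSpec


def _block_mean_oracle(vals, spec):
    """Brute-force per-cube loop the vectorized extractor must match."""
    feats = []
    for cd in spec.cube_dims:
        nx, ny, nz = [-(-d // c) for d, c in zip(spec.map_dims, cd)]
        # x-fastest ordering
        for lin in range(nx * ny * nz):
            ix = lin % nx
            iy = (lin // nx) % ny
            iz = lin // (nx * ny)
            block = vals[ix * cd[0]:(ix + 1) * cd[0],
                         iy * cd[1]:(iy + 1) * cd[1],
                         iz * cd[2]:(iz + 1) * cd[2]]
            finite = block[np.isfinite(block)]
            feats.append(finite.mean() if finite.size else 0.0)
    return np.array(feats)


class TestGridSpec:
    def test_default_spec_feature_count(self):
        spec = GridSpec(map_dims=(96, 48, 12))
        assert spec.counts == [9216, 1152, 144]
        assert spec.n_features == 10512

    def test_cube_larger_than_map_rejected(self):
        with pytest.raises(ValueError, match="larger than map"):
            GridSpec(map_dims=(4, 4, 2), cube_dims=((8, 2, 1),))

    def test_feature_info_is_bijective(self):
        spec = GridSpec(map_dims=(6, 4, 2), cube_dims=((3, 2, 1), (6, 4, 2)))
        seen = set()
        for i in range(spec.n_features):
            res, idx, slices = spec.feature_info(i)
            seen.add((res, idx))
        assert len(seen) == spec.n_features


class TestGridFeatures:
    def test_constant_map(self):
        spec = GridSpec(map_dims=(6, 4, 2), cube_dims=((3, 2, 1),))
        fv = netclass.grid_features(np.full((6, 4, 2), 0.7), spec)
        assert np.allclose(fv.values, 0.7)
        assert not fv.missing.any()

    @pytest.mark.parametrize("dims,cubes", [
        ((6, 4, 2), ((3, 2, 1),)),
        ((5, 3, 2), ((2, 2, 1),)),             # non-divisible: padded
        ((6, 4, 2), ((3, 2, 1), (6, 4, 2))),
    ])
    def test_matches_bruteforce_oracle(self, rng, dims, cubes):
        vals = rng.normal(size=dims)
        vals[0, 0, 0] = np.nan
        spec = GridSpec(map_dims=dims, cube_dims=cubes)
        fv = netclass.grid_features(vals, spec)
        assert np.allclose(fv.values, _block_mean_oracle(vals, spec))

    def test_all_nan_cube_flagged_zero(self):
        vals = np.full((4, 2, 1), np.nan)
        vals[2:, :, :] = 1.0
        spec = GridSpec(map_dims=(4, 2, 1), cube_dims=((2, 2, 1),))
        fv = netclass.grid_features(vals, spec)
        assert fv.values[0] == 0.0
        assert fv.missing[0]
        assert fv.values[1] == 1.0
        assert not fv.missing[1]


class TestLogisticLasso:
    def _toy(self, rng, n=36, p=8, informative=2, sep=2.5, classes=3):
        y = np.arange(n) % classes
        X = rng.normal(size=(n, p))
        for k in range(classes):
            X[y == k, :informative] += sep * (np.arange(informative) % classes == k)
        return X, y

    def test_full_shrinkage_recovers_class_proportions(self, rng):
        X, y = self._toy(rng)
        y = np.array(["a"] * 10 + ["b"] * 20 + ["c"] * 6)
        fit = netclass.fit_logistic_lasso(X, y, lam=1e6)
        assert np.allclose(fit.coef, 0.0)
        probs = fit.predict_proba(X[:1])[0]
        assert np.allclose(probs, [10 / 36, 20 / 36, 6 / 36], atol=1e-3)

    def test_unpenalized_separable_fits_training_data(self, rng):
        X, y = self._toy(rng, classes=2, sep=4.0)
        fit = netclass.fit_logistic_lasso(X, y, lam=0.0, max_outer=100)
        pred = fit.predict_proba(X).argmax(axis=1)
        assert (pred == y).all()

    def test_objective_beats_grid_oracle(self, rng):
        # 2-class, 2-feature: penalized objective at the fit must be at
        # least as good as an exhaustive coefficient-grid search
        n = 30
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 2))
        X[y == 1, 0] += 1.5
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 2.0
        fit = netclass.fit_logistic_lasso(Xs, y, lam=lam, tol=1e-8)
        onehot = np.eye(2)[y]
        ours = _lasso.penalized_objective(Xs, onehot, fit.coef,
                                          fit.intercept, lam)
        best = np.inf
        grid = np.linspace(-2.0, 2.0, 41)
        for w0 in grid:
            for w1 in grid:
                for b in np.linspace(-1.0, 1.0, 21):
                    W = np.array([[0.0, 0.0], [w0, w1]])
                    bb = np.array([0.0, b])
                    best = min(best, _lasso.penalized_objective(
                        Xs, onehot, W, bb, lam))
        assert ours <= best + 1e-4

    def test_agrees_with_saga_reference(self, rng):
        X, y = self._toy(rng, n=30, p=10, sep=2.0)
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 1.5
        fit = netclass.fit_logistic_lasso(Xs, y, lam=lam, tol=1e-8)
        onehot = np.eye(3)[y]
        ours = _lasso.penalized_objective(Xs, onehot, fit.coef,
                                          fit.intercept, lam)
        from sklearn.linear_model import LogisticRegression
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(penalty="l1", solver="saga",
                                     C=1.0 / lam, tol=1e-9,
                                     max_iter=100000).fit(Xs, y)
        theirs = _lasso.penalized_objective(Xs, onehot, clf.coef_,
                                            clf.intercept_, lam)
        assert ours == pytest.approx(theirs, abs=1e-5)

    def test_sparsity_nonincreasing_along_path(self, rng):
        X, y = self._toy(rng, n=40, p=20, informative=6, sep=1.5)
        nnz = []
        for lam in [0.1, 0.5, 1.5, 4.0, 12.0, 40.0]:
            fit = netclass.fit_logistic_lasso(X, y, lam=lam)
            nnz.append(int((fit.coef != 0).any(axis=0).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_single_class_and_nonfinite_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            netclass.fit_logistic_lasso(X, np.zeros(10), lam=1.0)
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            netclass.fit_logistic_lasso(Xbad, np.arange(10) % 2, lam=1.0)

    def test_ovr_mode_classifies_separable_data(self, rng):
        X, y = self._toy(rng, sep=4.0, informative=3)
        fit = netclass.fit_logistic_lasso(X, y, lam=0.5, method="ovr")
        assert (fit.predict_proba(X).argmax(axis=1) == y).all()


class TestSelectLambda:
    def test_single_grid_value_returned(self, rng):
        X, y = np.random.default_rng(0).normal(size=(20, 4)), np.arange(20) % 2
        assert netclass.select_lambda(X, y, lam_grid=[3.3]) == 3.3

    def test_pure_noise_selects_null_model(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 15))
            y = np.arange(30) % 3
            grid = netclass.default_lambda_grid(X, y, n=5)
            lam = netclass.select_lambda(X, y, folds=3, lam_grid=grid)
            hits += lam == grid.max()
        assert hits >= 8  # null model wins on >= 80% of noise datasets

    def test_informative_data_keeps_a_predictor(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.arange(30) % 3
        for k in range(3):
            X[y == k, 0] += 4.0 * (k == 0)
            X[y == k, 1] += 4.0 * (k == 1)
        lam = netclass.select_lambda(X, y, folds=3)
        fit = netclass.fit_logistic_lasso(X, y, lam=lam)
        assert (fit.coef != 0).any()

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="stratified"):
            netclass.select_lambda(X, y, folds=3)


class TestBagging:
    def _data(self, rng, n=45):
        y = np.array((["control"] * 15 + ["mutant"] * 15
                      + ["treated"] * 15)[:n])
        X = rng.normal(size=(n, 12))
        X[y == "mutant", 0] -= 3.0
        X[y == "treated", 1] += 3.0
        return X, y

    def test_published_subsample_arithmetic(self, rng):
        X, y = self._data(rng)
        ens = netclass.bag_ensemble(X, y, B=2, frac=0.8, rng_seed=0,
                                    lambda_strategy="fixed", lam=1.0)
        assert all(len(idx) == 36 for idx in ens.subsample_indices)

    def test_single_full_bootstrap_equals_plain_fit(self, rng):
        X, y = self._data(rng)
        ens = netclass.bag_ensemble(X, y, B=1, frac=1.0, rng_seed=0,
                                    lambda_strategy="fixed", lam=2.0,
                                    replace=False, tol=1e-8)
        direct = netclass.fit_logistic_lasso(X, y, lam=2.0, tol=1e-8)
        assert np.allclose(ens.averaged.coef, direct.coef, atol=1e-5)
        assert np.allclose(ens.averaged.intercept, direct.intercept,
                           atol=1e-5)

    def test_deterministic_subsamples(self, rng):
        X, y = self._data(rng)
        e1 = netclass.bag_ensemble(X, y, B=5, rng_seed=3,
                                   lambda_strategy="fixed", lam=1.0)
        e2 = netclass.bag_ensemble(X, y, B=5, rng_seed=3,
                                   lambda_strategy="fixed", lam=1.0)
        for a, b in zip(e1.subsample_indices, e2.subsample_indices):
            assert np.array_equal(a, b)

    def test_subsamples_are_stratified(self, rng):
        X, y = self._data(rng)
        ens = netclass.bag_ensemble(X, y, B=3, frac=0.8, rng_seed=1,
                                    lambda_strategy="fixed", lam=1.0)
        for idx in ens.subsample_indices:
            labels, counts = np.unique(y[idx], return_counts=True)
            assert len(labels) == 3
            assert counts.tolist() == [12, 12, 12]

    def test_informative_feature_selected_most(self, rng):
        X, y = self._data(rng)
        ens = netclass.bag_ensemble(X, y, B=20, frac=0.8, rng_seed=5,
                                    lambda_strategy="fixed", lam=3.0)
        assert ens.selection_freq[0] > ens.selection_freq[2:].max()
        assert ens.selection_freq[1] > ens.selection_freq[2:].max()


class TestEnsemblePredict:
    def test_identical_models_equal_single_model(self, rng):
        X = rng.normal(size=(45, 12))
        y = np.repeat(["a", "b", "c"], 15)
        ens = netclass.bag_ensemble(X, y, B=3, frac=1.0, rng_seed=0,
                                    lambda_strategy="fixed", lam=2.0,
                                    replace=False)
        probs = netclass.ensemble_predict(ens, X)
        single = ens.models[0].predict_proba(X)
        assert np.allclose(probs, single, atol=1e-8)

    def test_opposed_certain_models_average_to_half(self):
        from mousefc.netclass import BaggedEnsemble, LassoFit
        classes = np.array(["a", "b"])
        big = 50.0
        m1 = LassoFit(coef=np.zeros((2, 1)),
                      intercept=np.array([big, -big]), classes=classes,
                      lam=0.0)
        m2 = LassoFit(coef=np.zeros((2, 1)),
                      intercept=np.array([-big, big]), classes=classes,
                      lam=0.0)
        ens = BaggedEnsemble(models=[m1, m2], selection_freq=np.zeros(1),
                             averaged=m1, classes=classes, B=2, frac=1.0,
                             subsample_indices=[], lambdas=np.zeros(2),
                             rng_seed=0)
        probs = netclass.ensemble_predict(ens, np.zeros((3, 1)))
        assert np.allclose(probs, 0.5)

    def test_three_model_hand_average(self, rng):
        from mousefc.netclass import BaggedEnsemble, LassoFit
        classes = np.array([0, 1])
        models = [LassoFit(coef=rng.normal(size=(2, 2)),
                           intercept=rng.normal(size=2), classes=classes,
                           lam=0.1) for _ in range(3)]
        ens = BaggedEnsemble(models=models, selection_freq=np.zeros(2),
                             averaged=models[0], classes=classes, B=3,
                             frac=1.0, subsample_indices=[],
                             lambdas=np.zeros(3), rng_seed=0)
        X = rng.normal(size=(4, 2))
        expected = np.mean([m.predict_proba(X) for m in models], axis=0)
        assert np.allclose(netclass.ensemble_predict(ens, X), expected)

    def test_feature_mismatch_rejected(self, rng):
        X = rng.normal(size=(45, 12))
        y = np.repeat(["a", "b", "c"], 15)
        ens = netclass.bag_ensemble(X, y, B=1, rng_seed=0,
                                    lambda_strategy="fixed", lam=1.0)
        with pytest.raises(ValueError, match="mismatch"):
            netclass.ensemble_predict(ens, X[:, :5])


class TestROC:
    def test_perfect_separation(self):
        y = np.array(["a", "a", "b", "b"])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        res = netclass.roc_auc(probs, y)
        assert all(r.auc == 1.0 for r in res)

    def test_uninformative_probabilities(self, rng):
        n = 400
        y = rng.choice(["a", "b"], size=n)
        p = rng.uniform(size=n)
        probs = np.column_stack([p, 1 - p])
        res = netclass.roc_auc(probs, y)
        assert abs(res[0].auc - 0.5) < 0.1

    def test_matches_pair_counting_oracle_with_ties(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        score = np.array([0.9, 0.6, 0.6, 0.6, 0.3, 0.1])
        probs = np.column_stack([1 - score, score])
        res = netclass.roc_auc(probs, y, classes=[0, 1])
        wins = ties = 0
        for sp in score[y == 1]:
            for sn in score[y == 0]:
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / 9.0
        assert res[1].auc == pytest.approx(expected)
        # curve integrates to the same area
        auc_trap = np.trapezoid(res[1].tpr, res[1].fpr)
        assert auc_trap == pytest.approx(expected)

    def test_absent_class_flagged(self):
        y = np.array(["a", "a", "a"])
        probs = np.full((3, 2), 0.5)
        res = netclass.roc_auc(probs, y, classes=["a", "b"])
        assert np.isnan(res[1].auc)
        assert "absent" in res[1].flagged

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            netclass.roc_auc(np.array([[0.9, 0.9]]), np.array(["a"]))


class TestCombine:
    def _fitted(self, rng, shift=0.0):
        X = rng.normal(size=(30, 6))
        y = np.repeat(["a", "b", "c"], 10)
        X[y == "b", 0] += 3.0 + shift
        X[y == "c", 1] += 3.0 + shift
        ens = netclass.bag_ensemble(X, y, B=2, rng_seed=0,
                                    lambda_strategy="fixed", lam=1.0)
        return X, y, ens

    def test_single_seed_equals_that_ensemble(self, rng):
        X, y, ens = self._fitted(rng)
        probs, classes = netclass.combine_ensembles({"ACAr": ens},
                                                    {"ACAr": X})
        assert np.allclose(probs, netclass.ensemble_predict(ens, X))

    def test_identical_seeds_unchanged(self, rng):
        X, y, ens = self._fitted(rng)
        probs, _ = netclass.combine_ensembles(
            {"ACAr": ens, "CAr": ens}, {"ACAr": X, "CAr": X})
        assert np.allclose(probs, netclass.ensemble_predict(ens, X))

    def test_sample_mismatch_rejected(self, rng):
        X, y, ens = self._fitted(rng)
        with pytest.raises(ValueError, match="sample sets"):
            netclass.combine_ensembles({"ACAr": ens, "CAr": ens},
                                       {"ACAr": X, "CAr": X[:10]})

    def test_stack_refits_on_concatenated_features(self, rng):
        X, y, ens = self._fitted(rng)
        probs, classes = netclass.combine_ensembles(
            {"ACAr": ens, "CAr": ens}, {"ACAr": X, "CAr": X},
            method="stack", y=y, B=2, rng_seed=0,
            lambda_strategy="fixed", lam=1.0)
        assert probs.shape == (len(y), 3)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (np.array(classes) == np.unique(y)).all()


class TestSignificantPredictors:
    def _setup(self, rng):
        from mousefc import synth
        atlas, table = synth.build_synthetic_atlas(dims=(6, 4, 2),
                                                   n_regions=4, rng_seed=1)
        spec = GridSpec(map_dims=(6, 4, 2), cube_dims=((3, 2, 1),))
        n = 30
        y = np.repeat(["control", "mutant", "treated"], 10)
        X = rng.normal(size=(n, spec.n_features))
        X[:, 3] = 0.5  # identical across cohorts
        X[y == "mutant", 0] -= 5.0  # cleanly separated predictor
        return atlas, table, spec, X, y

    def test_separated_feature_reported_identical_excluded(self, rng):
        atlas, table, spec, X, y = self._setup(rng)
        ens = netclass.bag_ensemble(X, y, B=10, frac=0.8, rng_seed=2,
                                    lambda_strategy="fixed", lam=2.0)
        report = netclass.significant_predictors(
            ens, X, y, spec, atlas, table, seed_acronym="ACAr")
        assert 0 in report["feature"].tolist()
        assert 3 not in report["feature"].tolist()
        row = report[report.feature == 0].iloc[0]
        assert row.p_value < 0.001
        assert row.direction == "lower in mutant"
        assert row.predictor_acronym  # maps onto at least one region

    def test_no_candidates_gives_empty_report(self, rng):
        atlas, table, spec, X, y = self._setup(rng)
        ens = netclass.bag_ensemble(X, y, B=4, frac=0.8, rng_seed=2,
                                    lambda_strategy="fixed", lam=1e5)
        report = netclass.significant_predictors(
            ens, X, y, spec, atlas, table, seed_acronym="ACAr")
        assert report.empty
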