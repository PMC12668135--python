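"""Feature-type ranking, meta-feature assembly and stacked models."""

import numpy as np
import pytest
from scipy import stats as sstats

import mmstack as ms
from mmstack.base import FoldPrediction, PredictionStore
from mmstack.stacking import (MetaFeatureMatrix, build_meta_features,
                              rank_feature_types, stacked_predict)

from conftest import FAST_ENET, FAST_RF


def _stub_store(train_preds: dict, n_train: int = 40, n_test: int = 10,
                seed: int = 0):
    """Store with one fold and crafted nested training predictions."""
    n = n_train + n_test
    fam = np.array([f"f{i}" for i in range(n)])
    splits = ms.make_family_folds(fam, folds=5, repeats=1, seed=seed)
    store = PredictionStore(splits)
    rng = np.random.default_rng(seed)
    tr = np.arange(n_train)
    te = np.arange(n_train, n)
    y_tr = rng.normal(size=n_train)
    y_te = rng.normal(size=n_test)
    for name, fn in train_preds.items():
        store.add(name, 0, 0, FoldPrediction(
            test_idx=te, test_pred=rng.normal(size=n_test), test_obs=y_te,
            train_idx=tr, train_nested_pred=fn(y_tr), train_obs=y_tr,
            hyperparams={}))
    store.fold_targets[(0, 0)] = (y_tr, y_te)
    return store, y_tr, y_te


def test_ranking_sorts_by_training_accuracy():
    rng = np.random.default_rng(1)
    store, y_tr, _ = _stub_store({
        "A": lambda y: y.copy(),                       # corr 1
        "B": lambda y: -y,                             # corr -1
        "C": lambda y: y + rng.normal(size=y.size),    # corr mid
    })
    assert rank_feature_types(store, 0, 0, "pearson_r") == ["A", "C", "B"]


def test_exact_tie_breaks_alphabetically():
    store, _, _ = _stub_store({"B": lambda y: y.copy(),
                               "A": lambda y: y.copy(),
                               "C": lambda y: -y})
    assert rank_feature_types(store, 0, 0, "pearson_r") == ["A", "B", "C"]


def test_metric_switch_can_change_order():
    # A: perfectly correlated but rescaled (corr 1, COD 0);
    # B: slightly noisy but well calibrated (corr < 1, COD > 0)
    rng = np.random.default_rng(2)
    store, y_tr, _ = _stub_store({
        "A": lambda y: 2.0 * y,
        "B": lambda y: y + 0.3 * rng.normal(size=y.size),
    })
    by_corr = rank_feature_types(store, 0, 0, "pearson_r")
    by_cod = rank_feature_types(store, 0, 0, "cod")
    assert by_corr == ["A", "B"]
    assert by_cod == ["B", "A"]


def test_meta_features_follow_ranking_order():
    store, y_tr, y_te = _stub_store({
        "A": lambda y: y.copy(), "B": lambda y: -y, "C": lambda y: 0.5 * y})
    ranking = rank_feature_types(store, 0, 0, "pearson_r")
    full = build_meta_features(store, ranking, 3, 0, 0)
    assert full.columns == ranking
    assert full.train_x.shape == (40, 3)
    top2 = build_meta_features(store, ranking, 2, 0, 0)
    assert top2.columns == ranking[:2]
    np.testing.assert_array_equal(top2.train_x, full.train_x[:, :2])
    with pytest.raises(ValueError, match="exceeds"):
        build_meta_features(store, ranking, 4, 0, 0)


def test_training_rows_immune_to_posthoc_test_permutation():
    store, _, _ = _stub_store({"A": lambda y: y.copy(), "B": lambda y: -y})
    ranking = rank_feature_types(store, 0, 0, "pearson_r")
    before = build_meta_features(store, ranking, 2, 0, 0).train_x.copy()
    for m in ("A", "B"):
        e = store.get(m, 0, 0)
        e.test_obs = np.random.default_rng(3).permutation(e.test_obs)
    after = build_meta_features(store, ranking, 2, 0, 0).train_x
    np.testing.assert_array_equal(before, after)


def _meta(train_x, train_y, test_x, test_y):
    n_tr = len(train_y)
    return MetaFeatureMatrix(
        columns=[f"c{i}" for i in range(train_x.shape[1])],
        train_x=train_x, test_x=test_x, train_y=train_y, test_y=test_y,
        train_idx=np.arange(n_tr),
        test_idx=np.arange(n_tr, n_tr + len(test_y)))


def test_perfect_meta_feature_is_reproduced():
    rng = np.random.default_rng(4)
    y_tr, y_te = rng.normal(size=200), rng.normal(size=50)
    grid = ms.RFGrid(n_estimators=(100,), max_depths=(None,),
                     max_features=(1.0,))
    pred = stacked_predict(_meta(y_tr[:, None], y_tr, y_te[:, None], y_te),
                           grid, seed=0)
    assert ms.cod_accuracy(y_te, pred) >= 0.95


def test_pure_noise_meta_features_do_not_predict():
    cods = []
    grid = ms.RFGrid(n_estimators=(25,), max_depths=(3,), max_features=(1.0,))
    for seed in range(20):
        rng = np.random.default_rng(seed)
        meta = _meta(rng.normal(size=(100, 3)), rng.normal(size=100),
                     rng.normal(size=(30, 3)), rng.normal(size=30))
        cods.append(ms.cod_accuracy(meta.test_y,
                                    stacked_predict(meta, grid, seed=seed)))
    cods = np.asarray(cods)
    se = cods.std(ddof=1) / np.sqrt(len(cods))
    assert cods.mean() <= 2 * se  # <= 0 within Monte-Carlo CI


def test_complementary_meta_features_beat_single_columns():
    """Two meta-features each explaining half the variance: stacking both
    outperforms either alone (paired over seeds)."""
    grid = ms.RFGrid(n_estimators=(50,), max_depths=(None,),
                     max_features=(1.0,))
    both, single = [], []
    for seed in range(8):
        rng = np.random.default_rng(100 + seed)
        a_tr, b_tr = rng.normal(size=200), rng.normal(size=200)
        a_te, b_te = rng.normal(size=60), rng.normal(size=60)
        y_tr, y_te = a_tr + b_tr, a_te + b_te
        m2 = _meta(np.column_stack([a_tr, b_tr]), y_tr,
                   np.column_stack([a_te, b_te]), y_te)
        m1 = _meta(a_tr[:, None], y_tr, a_te[:, None], y_te)
        both.append(ms.cod_accuracy(y_te, stacked_predict(m2, grid, seed)))
        single.append(ms.cod_accuracy(y_te, stacked_predict(m1, grid, seed)))
    t = sstats.ttest_rel(both, single, alternative="greater")
    assert t.pvalue < 0.05


def test_constant_single_meta_column_refused():
    meta = _meta(np.ones((50, 1)), np.random.default_rng(5).normal(size=50),
                 np.ones((10, 1)), np.random.default_rng(6).normal(size=10))
    with pytest.raises(ValueError, match="constant"):
        stacked_predict(meta, FAST_RF, seed=0)


def test_curve_has_all_levels_for_both_metrics(fitted_small_model):
    _, res = fitted_small_model
    curve = res.curve
    n_models = len(res.store.models)
    assert curve.levels == list(range(1, n_models + 1))
    for metric in ("pearson_r", "cod"):
        assert curve.fold_matrix(metric).shape == (5, n_models)


def test_level1_equals_top_ranked_base_model(fitted_small_model):
    _, res = fitted_small_model
    curve, store = res.curve, res.store
    for (r, f), ranking in curve.rankings.items():
        top = store.get(ranking[0], r, f)
        expected = ms.pearson_accuracy(top.test_obs, top.test_pred)
        got = curve.frame.query("level == 1 and repeat == @r and fold == @f")
        assert got["pearson_r"].iloc[0] == pytest.approx(expected)


def test_single_source_signal_gives_flat_curve():
    """Signal in one block only: no level is significantly better than 1."""
    spec = ms.CohortSpec(
        n_subjects=200, folds_hint=5, informative=("fc_rest",),
        signal_r2=0.5, confound_r2=0.0,
        blocks=(ms.BlockSpec("fc_rest", "connectivity_vector", "rest",
                             region_count=10),
                ms.BlockSpec("fc_task", "connectivity_vector", "task",
                             region_count=10),
                ms.BlockSpec("morph", "region_map", "struct", n_features=30)))
    model = ms.MultimodalStacking.from_synthetic(
        spec, seed=31, repeats=1, folds=10, enet_grid=FAST_ENET,
        rf_grid=FAST_RF)
    res = model.fit(seed=0)
    p = ms.pairwise_level_comparison(res.curve, "pearson_r", "none")
    best = res.best_level()
    assert float(p.loc[1, best]) >= 0.05 or best == 1


def test_complementary_signal_rewards_integration():
    """Disjoint signal in two blocks: stacking beats the best single block
    (paired over folds, alpha=0.05)."""
    spec = ms.CohortSpec(
        n_subjects=300, folds_hint=5, informative=("fc_rest", "morph"),
        signal_r2=0.6, confound_r2=0.0, latent_sharing=0.0,
        blocks=(ms.BlockSpec("fc_rest", "connectivity_vector", "rest",
                             region_count=10),
                ms.BlockSpec("fc_task", "connectivity_vector", "task",
                             region_count=10),
                ms.BlockSpec("morph", "region_map", "struct", n_features=30)))
    model = ms.MultimodalStacking.from_synthetic(
        spec, seed=32, repeats=2, folds=5, enet_grid=FAST_ENET,
        rf_grid=FAST_RF)
    res = model.fit(seed=0)
    fm = res.curve.fold_matrix("pearson_r")
    stacked_best = fm[:, 1:].mean(axis=0).max()
    level2 = fm[:, 1]
    t = sstats.ttest_rel(level2, fm[:, 0], alternative="greater")
    assert t.pvalue < 0.05
    assert stacked_best > fm[:, 0].mean()
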