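"""Stacked (integrated-features set) models at increasing integration levels.

Within each cross-validation cell, feature types (the confound model
included) are ranked by their training-split accuracy computed from the
nested-CV predictions, so no test-subject information enters the ranking.
For level k, the top-k models' predictions form the meta-feature matrix:
training rows come from the nested-CV predictions and test rows from the
outer-fold predictions.  A Random Forest regressor (Friedman-MSE split
criterion), tuned by an inner 5-fold grid search, maps meta-features to the
target.  Level 1 is defined as the top-ranked base model itself, making the
level series complete from 1 to the number of rankable models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .accuracy import AccuracyRecord, accuracy_record
from .base import PredictionStore, derive_seed
from .splits import SplitScheme, inner_folds


@dataclass
class RFGrid:
    """Random-Forest grid searched in the inner 5-fold CV of the meta-model."""

    n_estimators: tuple = (100, 500)
    max_depths: tuple = (None, 2, 5, 10)
    max_features: tuple = (1.0, "sqrt", 0.3333333333333333)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.n_estimators or not self.max_depths or not self.max_features:
            raise ValueError("RF grid must be nonempty")
        if any(int(n) <= 0 for n in self.n_estimators):
            raise ValueError("tree counts must be positive")

    @property
    def combos(self):
        return [(n, d, f) for n in self.n_estimators
                for d in self.max_depths for f in self.max_features]


def rank_feature_types(store: PredictionStore, repeat: int, fold: int,
                       metric: str = "pearson_r",
                       models: list[str] | None = None) -> list[str]:
    """Order models by training-split accuracy, best first.

    Exact ties are broken by block name (alphabetical), which keeps the
    ranking deterministic.
    """
    models = models if models is not None else store.models
    accs = {m: store.train_accuracy(m, repeat, fold, metric) for m in models}
    return sorted(models, key=lambda m: (-accs[m], m))


@dataclass
class MetaFeatureMatrix:
    """Leakage-free meta-features for one (repeat, fold, level)."""

    columns: list[str]
    train_x: np.ndarray
    test_x: np.ndarray
    train_y: np.ndarray
    test_y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray


def build_meta_features(store: PredictionStore, ranking: list[str], level: int,
                        repeat: int, fold: int) -> MetaFeatureMatrix:
    """Assemble the top-``level`` models' predictions in ranking order.

    Training-row values are the nested-CV predictions (produced without the
    test subjects), test-row values the outer-fold predictions.
    """
    if level > len(ranking):
        raise ValueError(f"level {level} exceeds {len(ranking)} ranked models")
    top = ranking[:level]
    first = store.get(top[0], repeat, fold)
    train_cols, test_cols = [], []
    for m in top:
        e = store.get(m, repeat, fold)
        if e.train_nested_pred is None:
            raise ValueError(f"model {m!r} lacks nested training predictions")
        train_cols.append(e.train_nested_pred)
        test_cols.append(e.test_pred)
    if (repeat, fold) not in store.fold_targets:
        raise ValueError("no residualised fold target stored; run at least "
                         "one feature-wise model first")
    y_tr, y_te = store.fold_targets[(repeat, fold)]
    return MetaFeatureMatrix(columns=list(top),
                             train_x=np.column_stack(train_cols),
                             test_x=np.column_stack(test_cols),
                             train_y=y_tr, test_y=y_te,
                             train_idx=first.train_idx,
                             test_idx=first.test_idx)


def stacked_predict(meta: MetaFeatureMatrix, grid: RFGrid, seed: int,
                    families: np.ndarray | None = None) -> np.ndarray:
    """Inner grid search + refit of the Random-Forest meta-model.

    Deterministic under ``seed``; returns test-row predictions.
    """
    if meta.train_x.shape[1] == 1 and np.ptp(meta.train_x) == 0:
        raise ValueError("single constant meta-feature column: nothing to fit")
    fam = (families[meta.train_idx] if families is not None
           else np.arange(len(meta.train_idx)))

    def make_rf(n, d, f, s):
        # split quality: MSE with Friedman's improvement score; in forest
        # regressors this criterion is computationally identical to
        # squared_error, which scikit-learn >=1.9 requires spelling out
        return RandomForestRegressor(
            n_estimators=int(n), max_depth=d, max_features=f,
            criterion="squared_error", random_state=s, n_jobs=None)

    combos = grid.combos
    if len(combos) > 1:  # a single combination needs no inner search
        inner_ids = inner_folds(fam, grid.inner_folds, derive_seed(seed, 1))
        mse = np.zeros(len(combos))
        for i in np.unique(inner_ids):
            itr, ite = inner_ids != i, inner_ids == i
            for c, (n, d, f) in enumerate(combos):
                rf = make_rf(n, d, f, derive_seed(seed, 2, c, int(i)))
                rf.fit(meta.train_x[itr], meta.train_y[itr])
                resid = rf.predict(meta.train_x[ite]) - meta.train_y[ite]
                mse[c] += float(resid @ resid)
        best = int(np.argmin(mse))
    else:
        best = 0
    n, d, f = combos[best]
    rf = make_rf(n, d, f, derive_seed(seed, 3))
    rf.fit(meta.train_x, meta.train_y)
    return rf.predict(meta.test_x)


@dataclass
class IntegrationCurve:
    """Fold-wise accuracies for every multimodal integration level."""

    frame: pd.DataFrame               # level, repeat, fold, pearson_r, cod
    rankings: dict                    # (repeat, fold) -> ordered model list
    splits: SplitScheme
    ranking_metric: str

    @property
    def levels(self) -> list[int]:
        return sorted(self.frame["level"].unique())

    def mean_accuracy(self, metric: str) -> pd.Series:
        return self.frame.groupby("level")[metric].mean()

    def fold_matrix(self, metric: str) -> np.ndarray:
        """J x L matrix of fold accuracies, rows ordered by (repeat, fold)."""
        wide = self.frame.pivot_table(index=["repeat", "fold"],
                                      columns="level", values=metric,
                                      sort=True)
        return wide.to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("pearson_r", "cod"):
            stats = self.frame.groupby("level")[metric].agg(["mean", "std"])
            for level, row in stats.iterrows():
                rows.append((metric, int(level), row["mean"], row["std"]))
        return pd.DataFrame(rows, columns=["metric", "level", "mean", "sd"])


def integration_series(store: PredictionStore, splits: SplitScheme,
                       rf_grid: RFGrid, *, metric: str = "pearson_r",
                       seed: int = 0, models: list[str] | None = None,
                       max_level: int | None = None) -> IntegrationCurve:
    """Build the full level series 1..F for one target.

    Level 1 copies the per-fold top-ranked base model's test accuracies;
    levels 2..F fit stacked Random-Forest models on growing meta-feature
    sets.  All levels share the split scheme, so accuracies are paired.
    """
    models = models if models is not None else store.models
    missing = [(m, r, f) for m in models
               for r, f, _, _ in splits.iter_folds()
               if (m, r, f) not in store.entries]
    if missing:
        raise ValueError(f"missing base-model folds: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    top_level = min(max_level or len(models), len(models))
    rows, rankings = [], {}
    for repeat, fold, tr, te in splits.iter_folds():
        ranking = rank_feature_types(store, repeat, fold, metric, models)
        rankings[(repeat, fold)] = ranking
        top_entry = store.get(ranking[0], repeat, fold)
        rec1 = accuracy_record("level1", repeat, fold,
                               top_entry.test_obs, top_entry.test_pred)
        rows.append((1, repeat, fold, rec1.pearson_r, rec1.cod))
        for k in range(2, top_level + 1):
            meta = build_meta_features(store, ranking, k, repeat, fold)
            pred = stacked_predict(meta, rf_grid,
                                   derive_seed(seed, repeat, fold, k),
                                   families=splits.family_ids)
            rec = accuracy_record(f"level{k}", repeat, fold,
                                  meta.test_y, pred)
            rows.append((k, repeat, fold, rec.pearson_r, rec.cod))
    frame = pd.DataFrame(rows, columns=["level", "repeat", "fold",
                                        "pearson_r", "cod"])
    return IntegrationCurve(frame=frame, rankings=rankings, splits=splits,
                            ranking_metric=metric)
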