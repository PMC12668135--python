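"""Feature-wise prediction models under repeated nested cross-validation.

Each feature-type block gets its own elastic-net model per outer fold:
confounds are regressed from the target with training-only coefficients,
features are z-scored with training-fold statistics, the L1 ratio and alpha
are chosen by an inner 5-fold grid search minimising mean squared error,
and the refit model predicts the held-out subjects.  The same inner CV
additionally yields leakage-free predictions for every *training* subject
(each predicted by the chosen-combination model that did not see it), which
downstream stacking uses as meta-features and for feature-type ranking.

The confound model is the same machinery with the eight confounding
variables as features and no confound regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .accuracy import AccuracyRecord, accuracy_record, pearson_accuracy, cod_accuracy
from .cohort import FeatureBlock
from .confounds import confound_apply, confound_fit
from .splits import SplitScheme, inner_folds

CONFOUND_MODEL_NAME = "confounds"


def derive_seed(seed: int, *keys: int) -> int:
    """Stable sub-seed below 2**31 for a (repeat, fold, ...) task."""
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class HyperparamGrid:
    """Elastic-net grid searched in the inner 5-fold CV."""

    l1_ratios: tuple = (0.1, 0.5, 0.7, 0.9, 0.95, 1.0)
    alphas: tuple = tuple(float(a) for a in np.logspace(-3, 1, 10))
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not self.l1_ratios or not self.alphas:
            raise ValueError("grid must be nonempty")
        if any(a <= 0 for a in self.alphas):
            raise ValueError("alphas must be positive")
        if any(not 0 <= l <= 1 for l in self.l1_ratios):
            raise ValueError("L1 ratios must be in [0, 1]")

    @property
    def combos(self) -> list[tuple[float, float]]:
        return [(l, a) for l in self.l1_ratios for a in self.alphas]


@dataclass
class FoldPrediction:
    """Out-of-sample and nested-CV predictions for one (model, repeat, fold)."""

    test_idx: np.ndarray
    test_pred: np.ndarray
    test_obs: np.ndarray
    train_idx: np.ndarray
    train_nested_pred: np.ndarray | None
    train_obs: np.ndarray
    hyperparams: dict


class PredictionStore:
    """Per (model, repeat, fold) predictions for one target, one split scheme."""

    def __init__(self, splits: SplitScheme, target_name: str = "score"):
        self.splits = splits
        self.target_name = target_name
        self.entries: dict[tuple[str, int, int], FoldPrediction] = {}
        self.records: list[AccuracyRecord] = []
        # fold-level residualised target, shared by all feature-wise models
        self.fold_targets: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def models(self) -> list[str]:
        return sorted({m for (m, _, _) in self.entries})

    def add(self, model: str, repeat: int, fold: int,
            entry: FoldPrediction) -> None:
        key = (model, repeat, fold)
        self.entries[key] = entry
        self.records.append(accuracy_record(
            model, repeat, fold, entry.test_obs, entry.test_pred))

    def get(self, model: str, repeat: int, fold: int) -> FoldPrediction:
        key = (model, repeat, fold)
        if key not in self.entries:
            raise KeyError(f"no predictions stored for {key}")
        return self.entries[key]

    def train_accuracy(self, model: str, repeat: int, fold: int,
                       metric: str) -> float:
        """Training-split accuracy from the nested-CV predictions."""
        e = self.get(model, repeat, fold)
        if e.train_nested_pred is None:
            raise ValueError(f"model {model!r} has no nested predictions")
        fn = pearson_accuracy if metric == "pearson_r" else cod_accuracy
        return fn(e.train_obs, e.train_nested_pred)

    def test_records(self, model: str) -> list[AccuracyRecord]:
        return [r for r in self.records if r.model == model]

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def predictions_frame(self, model: str) -> pd.DataFrame:
        """Long-format predictions for persistence (one TSV per model)."""
        rows = []
        for (m, r, f), e in sorted(self.entries.items()):
            if m != model:
                continue
            for i, p in zip(e.test_idx, e.test_pred):
                rows.append((r, f, int(i), "test", float(p)))
            if e.train_nested_pred is not None:
                for i, p in zip(e.train_idx, e.train_nested_pred):
                    rows.append((r, f, int(i), "train_nested", float(p)))
        return pd.DataFrame(rows, columns=["repeat", "fold", "subject",
                                           "role", "prediction"])


class FoldwiseBlock:
    """A feature block derived per fold with training-only parameter fitting.

    ``builder(train_idx, test_idx)`` must return the (train, test) feature
    matrices, fitting any group-level parameters (gradient template,
    morphometric-covariance standardisation, ...) on the training rows only.
    """

    def __init__(self, name: str, builder, modality_tag: str = "rest"):
        self.name = name
        self.builder = builder
        self.modality_tag = modality_tag

    def build(self, train_idx: np.ndarray, test_idx: np.ndarray):
        return self.builder(train_idx, test_idx)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _fit_enet(x, y, l1_ratio, alpha):
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=3000,
                       tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x, y)
    return model


def _grid_search_fold(x_tr, y_tr, inner_ids, grid: HyperparamGrid):
    """Inner-CV grid search; returns (best combo, nested train predictions).

    For every combination the inner held-out predictions are collected; the
    chosen combination's held-out predictions double as the leakage-free
    nested predictions for the training subjects.
    """
    combos = grid.combos
    n = len(y_tr)
    preds = np.zeros((len(combos), n))
    for i in np.unique(inner_ids):
        itr, ite = inner_ids != i, inner_ids == i
        xi_tr, xi_te = _standardize(x_tr[itr], x_tr[ite])
        yi = y_tr[itr]
        for c, (l1, alpha) in enumerate(combos):
            preds[c, ite] = _fit_enet(xi_tr, yi, l1, alpha).predict(xi_te)
    mse = np.mean((preds - y_tr[None, :]) ** 2, axis=1)
    best = int(np.argmin(mse))  # ties: first in grid order
    return combos[best], preds[best].copy()


def featurewise_predict(block, target: np.ndarray, splits: SplitScheme,
                        grid: HyperparamGrid, confounds: np.ndarray, *,
                        seed: int = 0, confound_mode: str = "target",
                        store: PredictionStore | None = None,
                        compute_nested: bool = True,
                        model_name: str | None = None
                        ) -> tuple[PredictionStore, list[AccuracyRecord]]:
    """Fit one feature-type's elastic-net models across all CV cells.

    ``confound_mode``: ``'target'`` (default) residualises the target
    against the eight confounds with training-only coefficients;
    ``'both'`` additionally residualises the features; ``'none'`` skips
    deconfounding (used by the confound model).
    """
    if confound_mode not in ("target", "both", "none"):
        raise ValueError(f"unknown confound_mode {confound_mode!r}")
    name = model_name or block.name
    y = np.asarray(target, dtype=float)
    if store is None:
        store = PredictionStore(splits)
    records: list[AccuracyRecord] = []
    families = splits.family_ids

    static = isinstance(block, FeatureBlock)
    if static and not np.isfinite(block.matrix).all():
        i, j = np.argwhere(~np.isfinite(block.matrix))[0]
        raise ValueError(f"block {block.name!r}: non-finite feature at row "
                         f"{i}, column {j}")

    for repeat, fold, tr, te in splits.iter_folds():
        if static:
            x_tr_raw, x_te_raw = block.matrix[tr], block.matrix[te]
        else:
            x_tr_raw, x_te_raw = block.build(tr, te)

        if confound_mode == "none":
            y_tr, y_te = y[tr], y[te]
        else:
            coefs = confound_fit(confounds[tr], y[tr])
            y_tr = confound_apply(confounds[tr], y[tr], coefs)
            y_te = confound_apply(confounds[te], y[te], coefs)
            if confound_mode == "both":
                fcoefs = confound_fit(confounds[tr], x_tr_raw)
                x_tr_raw = confound_apply(confounds[tr], x_tr_raw, fcoefs)
                x_te_raw = confound_apply(confounds[te], x_te_raw, fcoefs)
            store.fold_targets.setdefault((repeat, fold), (y_tr, y_te))

        if len(grid.combos) == 1 and not compute_nested:
            # nothing to select and no nested predictions wanted
            (l1, alpha), nested = grid.combos[0], None
        else:
            inner_seed = derive_seed(seed, repeat, fold)
            inner_ids = inner_folds(families[tr], grid.inner_folds, inner_seed)
            (l1, alpha), nested = _grid_search_fold(x_tr_raw, y_tr,
                                                    inner_ids, grid)

        x_tr, x_te = _standardize(x_tr_raw, x_te_raw)
        model = _fit_enet(x_tr, y_tr, l1, alpha)
        test_pred = model.predict(x_te)

        entry = FoldPrediction(
            test_idx=te, test_pred=test_pred, test_obs=y_te,
            train_idx=tr,
            train_nested_pred=nested if compute_nested else None,
            train_obs=y_tr,
            hyperparams={"l1_ratio": l1, "alpha": alpha})
        store.add(name, repeat, fold, entry)
        records.append(store.records[-1])
    return store, records


def confound_model_predict(confounds: np.ndarray, target: np.ndarray,
                           splits: SplitScheme, grid: HyperparamGrid, *,
                           seed: int = 0,
                           store: PredictionStore | None = None,
                           compute_nested: bool = True
                           ) -> tuple[PredictionStore, list[AccuracyRecord]]:
    """The confound model: confounds as features, no confound regression."""
    block = FeatureBlock(name=CONFOUND_MODEL_NAME, matrix=confounds,
                         modality_tag="confound", shape_kind="region_map")
    return featurewise_predict(block, target, splits, grid, confounds,
                               seed=seed, confound_mode="none", store=store,
                               compute_nested=compute_nested)
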