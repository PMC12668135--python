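"""Model/Results interface for multimodal stacked prediction.

`MultimodalStacking` bundles a cohort, its feature blocks and one target
into a model object; `fit()` runs the full protocol — family-aware repeated
nested CV, elastic-net feature-wise models, in-fold confound regression,
the confound model, Random-Forest stacking at every integration level, and
saturation inference — and returns a results object carrying the
integration curve, the best/necessary feature sets and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .accuracy import METRICS
from .base import (CONFOUND_MODEL_NAME, HyperparamGrid, PredictionStore,
                   confound_model_predict, derive_seed, featurewise_predict)
from .cohort import CohortTable, FeatureBlock, check_alignment
from .saturation import SaturationResult, saturate, validity_filter
from .splits import make_family_folds
from .stacking import IntegrationCurve, RFGrid, integration_series
from .synthetic import CohortSpec, generate_cohort


class MultimodalStacking:
    """Stacked multimodal prediction model for one psychometric target.

    Parameters
    ----------
    cohort
        Per-subject table with confounds and targets.
    blocks
        Feature-type blocks (rows aligned with the cohort) and/or
        fold-wise blocks whose group parameters are fitted per fold.
    target
        Name of the psychometric target column; defaults to the first.
    repeats, folds
        Outer cross-validation scheme (default 10 x 10, family-aware).
    include_confound_model
        Whether the eight confounding variables compete as a rankable
        model of their own.
    confound_mode
        'target' regresses confounds from the target only (default),
        'both' also residualises the features, 'none' disables it.
    """

    def __init__(self, cohort: CohortTable, blocks: list, target: str | None = None,
                 *, repeats: int = 10, folds: int = 10,
                 enet_grid: HyperparamGrid | None = None,
                 rf_grid: RFGrid | None = None,
                 ranking_metric: str = "pearson_r",
                 confound_mode: str = "target",
                 include_confound_model: bool = True,
                 alpha: float = 0.05, correction: str = "holm",
                 max_level: int | None = None):
        static = [b for b in blocks if isinstance(b, FeatureBlock)]
        check_alignment(cohort, static)
        if ranking_metric not in METRICS:
            raise ValueError(f"ranking_metric must be one of {METRICS}")
        names = [b.name for b in blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        if include_confound_model and CONFOUND_MODEL_NAME in names:
            raise ValueError(f"{CONFOUND_MODEL_NAME!r} is reserved")
        self.cohort = cohort
        self.blocks = list(blocks)
        self.target = target or cohort.target_names[0]
        self.repeats = repeats
        self.folds = folds
        self.enet_grid = enet_grid or HyperparamGrid()
        self.rf_grid = rf_grid or RFGrid()
        self.ranking_metric = ranking_metric
        self.confound_mode = confound_mode
        self.include_confound_model = include_confound_model
        self.alpha = alpha
        self.correction = correction
        self.max_level = max_level
        self.manifest = None  # set by from_synthetic

    @classmethod
    def from_synthetic(cls, spec: CohortSpec | None = None, seed: int = 0,
                       **kwargs) -> "MultimodalStacking":
        """Build a model on a generated cohort with known planted structure."""
        spec = spec or CohortSpec()
        cohort, blocks, manifest = generate_cohort(spec, seed)
        model = cls(cohort, blocks, spec.target_name, **kwargs)
        model.manifest = manifest
        return model

    def fit(self, seed: int = 0) -> "MultimodalStackingResults":
        """Run the full protocol; deterministic under ``seed``."""
        cohort = self.cohort
        splits = make_family_folds(cohort.family_ids, self.folds,
                                   self.repeats, derive_seed(seed, 11))
        confounds = cohort.confound_matrix()
        y = cohort.target(self.target)
        store = PredictionStore(splits, self.target)
        base_seed = derive_seed(seed, 23)  # shared: same inner folds per model
        for block in self.blocks:
            featurewise_predict(block, y, splits, self.enet_grid, confounds,
                                seed=base_seed,
                                confound_mode=self.confound_mode, store=store)
        if self.include_confound_model:
            confound_model_predict(confounds, y, splits, self.enet_grid,
                                   seed=base_seed, store=store)
        curve = integration_series(store, splits, self.rf_grid,
                                   metric=self.ranking_metric,
                                   seed=derive_seed(seed, 37),
                                   max_level=self.max_level)
        sat = {m: saturate(curve, metric=m, alpha=self.alpha,
                           method=self.correction) for m in METRICS}
        return MultimodalStackingResults(self, splits, store, curve, sat,
                                         seed)


@dataclass
class MultimodalStackingResults:
    """Fitted integration curve, saturation inference and diagnostics."""

    model: MultimodalStacking
    splits: object
    store: PredictionStore
    curve: IntegrationCurve
    saturation: dict[str, SaturationResult]
    seed: int

    @property
    def integration_frame(self) -> pd.DataFrame:
        return self.curve.frame

    def mean_accuracy(self, metric: str = "pearson_r") -> pd.Series:
        return self.curve.mean_accuracy(metric)

    def best_level(self, metric: str = "pearson_r") -> int:
        return self.saturation[metric].best_level

    def necessary_level(self, metric: str = "pearson_r") -> int:
        return self.saturation[metric].necessary_level

    def composition(self, metric: str = "pearson_r") -> pd.Series:
        return self.saturation[metric].composition

    @property
    def valid(self) -> bool:
        return self.saturation["cod"].valid

    def summary(self, metric: str = "pearson_r") -> str:
        sat = self.saturation[metric]
        means_r = self.curve.mean_accuracy("pearson_r")
        means_cod = self.curve.mean_accuracy("cod")
        header = [
            ("Target:", self.model.target),
            ("Subjects:", str(self.model.cohort.n_subjects)),
            ("CV scheme:", f"{self.splits.repeats} x {self.splits.folds}"
                           " (family-aware)"),
            ("Rankable models:", str(len(self.store.models))),
            ("Metric:", metric),
            ("Best level:", f"{sat.best_level} "
                            f"(mean {means_r.loc[sat.best_level]:.3f} R, "
                            f"{means_cod.loc[sat.best_level]:.3f} COD)"),
            ("Necessary level:", f"{sat.necessary_level} "
                                 f"(mean {means_r.loc[sat.necessary_level]:.3f} R, "
                                 f"{means_cod.loc[sat.necessary_level]:.3f} COD)"),
            ("Validity (COD>0):", str(sat.valid)),
            ("Seed:", str(self.seed)),
        ]
        head_tbl = SimpleTable([[k, v] for k, v in header],
                               title="Multimodal Stacking Results")
        comp = sat.composition.sort_values(ascending=False)
        comp_rows = [[name, f"{freq:.2f}"] for name, freq in comp.items()]
        comp_tbl = SimpleTable(comp_rows,
                               headers=["feature type", "necessary-set freq"])
        return str(head_tbl) + "\n" + str(comp_tbl)

    def plot_integration_curve(self, metric: str = "pearson_r", ax=None):
        """Mean accuracy vs integration level, fold scatter behind."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        frame = self.curve.frame
        ax.plot(frame["level"], frame[metric], ".", color="0.7", ms=3,
                alpha=0.5, zorder=1)
        means = self.curve.mean_accuracy(metric)
        ax.plot(means.index, means.values, "o-", color="C1", zorder=2)
        sat = self.saturation[metric]
        ax.axvline(sat.necessary_level, ls="--", color="C0", lw=1,
                   label=f"necessary = {sat.necessary_level}")
        ax.axvline(sat.best_level, ls=":", color="C3", lw=1,
                   label=f"best = {sat.best_level}")
        ax.set_xlabel("multimodal integration level")
        ax.set_ylabel({"pearson_r": "correlation accuracy (R)",
                       "cod": "COD accuracy (R$^2$)"}[metric])
        ax.legend(frameon=False, fontsize=8)
        return ax

    def to_summary_dict(self) -> dict:
        """JSON-serialisable run summary (deterministic key order)."""
        out = {"target": self.model.target, "seed": int(self.seed),
               "repeats": int(self.splits.repeats),
               "folds": int(self.splits.folds), "metrics": {}}
        for metric, sat in sorted(self.saturation.items()):
            out["metrics"][metric] = {
                "best_level": int(sat.best_level),
                "necessary_level": int(sat.necessary_level),
                "mean_accuracy": {int(k): round(float(v), 10)
                                  for k, v in sat.mean_accuracy.items()},
                "necessary_mean_cod": round(float(sat.necessary_mean_cod), 10),
                "valid": sat.valid,
                "composition": {k: round(float(v), 10)
                                for k, v in sat.composition.items()},
            }
        return out
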