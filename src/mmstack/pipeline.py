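"""Run configuration, orchestration and reporting.

A run is driven by a single config (YAML or `RunConfig`), executes
simulate -> features -> base -> stack -> saturate -> report, persists every
stage's outputs as diff-able TSV/JSON under the output directory, and can
resume from any completed stage.  The archived config plus the seed make a
run exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import features as feat
from .accuracy import METRICS
from .base import (CONFOUND_MODEL_NAME, FoldPrediction, HyperparamGrid,
                   PredictionStore, confound_model_predict, derive_seed,
                   featurewise_predict)
from .cohort import CohortTable, FeatureBlock, check_alignment
from .saturation import saturate, validity_filter
from .splits import make_family_folds
from .stacking import IntegrationCurve, RFGrid, integration_series
from .synthetic import BlockSpec, CohortSpec, export_manifest, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    out_dir: str
    seed: int = 0
    # inputs: either paths to existing artefacts ...
    cohort_path: str | None = None
    block_paths: list = field(default_factory=list)
    # ... or a synthetic cohort specification (kwargs of CohortSpec;
    # 'blocks' entries are kwargs of BlockSpec)
    synthetic: dict | None = None
    timeseries_dir: str | None = None
    timeseries_blocks: list = field(default_factory=list)
    targets: list | None = None
    repeats: int = 10
    folds: int = 10
    enet_grid: dict = field(default_factory=dict)
    rf_grid: dict = field(default_factory=dict)
    ranking_metric: str = "pearson_r"
    correction: str = "holm"
    alpha: float = 0.05
    confound_mode: str = "target"
    include_confound_model: bool = True
    max_level: int | None = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.cohort_path is None and self.synthetic is None:
            raise ValueError("config needs either cohort_path or synthetic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def make_grids(self) -> tuple[HyperparamGrid, RFGrid]:
        eg = {k: tuple(v) if isinstance(v, list) else v
              for k, v in self.enet_grid.items()}
        rg = {k: tuple(v) if isinstance(v, list) else v
              for k, v in self.rf_grid.items()}
        return HyperparamGrid(**eg), RFGrid(**rg)


def _audit(out: Path, action: str, path) -> None:
    with open(out / "audit.log", "a") as fh:
        fh.write(f"{action}\t{Path(path).as_posix()}\n")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending item."""


# ---------------------------------------------------------------- simulate

def stage_simulate(cfg: RunConfig, out: Path):
    """Load or generate the cohort and feature blocks; persist them."""
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    cohort_file = inputs / "cohort.tsv"
    try:
        if cohort_file.exists():
            cohort = CohortTable.from_tsv(cohort_file)
            blocks = [FeatureBlock.from_tsv(p)
                      for p in sorted(inputs.glob("block_*.tsv"))]
            for p in sorted(inputs.glob("block_*.tsv")):
                _audit(out, "read", p)
        elif cfg.cohort_path:
            cohort = CohortTable.from_tsv(cfg.cohort_path)
            _audit(out, "read", cfg.cohort_path)
            blocks = []
            for p in cfg.block_paths:
                blocks.append(FeatureBlock.from_tsv(p))
                _audit(out, "read", p)
            cohort.to_tsv(cohort_file)
            for b in blocks:
                b.to_tsv(inputs / f"block_{b.name}.tsv")
        else:
            syn = dict(cfg.synthetic)
            if "blocks" in syn:
                syn["blocks"] = tuple(BlockSpec(**b) for b in syn["blocks"])
            for key in ("informative", "effect_weights", "age_range"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            spec = CohortSpec(**syn)
            cohort, blocks, manifest = generate_cohort(spec, cfg.seed)
            cohort.to_tsv(cohort_file)
            for b in blocks:
                b.to_tsv(inputs / f"block_{b.name}.tsv")
                _audit(out, "write", inputs / f"block_{b.name}.tsv")
            export_manifest(manifest, inputs / "manifest.json")
            _audit(out, "write", inputs / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - stage-name context
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    check_alignment(cohort, blocks)
    return cohort, blocks


# ---------------------------------------------------------------- features

def derive_blocks_from_timeseries(ts_dir, subject_ids, which,
                                  region_count: int | None = None
                                  ) -> list[FeatureBlock]:
    """Derive subject-wise feature blocks from per-subject timeseries TSVs.

    ``which`` is a subset of {'model_free_fc', 'time_varying_fc',
    'network_statistics'}; each subject's file is ``<ts_dir>/<id>.tsv``
    (region x time).  Group-parameterised features (gradients, morphometric
    covariance) are deliberately not derived here: they are fitted per fold
    inside the prediction stage via fold-wise blocks.
    """
    ts_dir = Path(ts_dir)
    rows = {w: [] for w in which}
    for sid in subject_ids:
        ts = np.loadtxt(ts_dir / f"{sid}.tsv", delimiter="\t", ndmin=2)
        if "model_free_fc" in which:
            rows["model_free_fc"].append(feat.model_free_fc(ts))
        if "time_varying_fc" in which:
            rows["time_varying_fc"].append(feat.time_varying_fc(ts))
        if "network_statistics" in which:
            fc = feat.fc_matrix_from_timeseries(ts)
            rows["network_statistics"].append(feat.network_statistics(fc))
    out = []
    for w in which:
        mat = np.stack(rows[w])
        if w == "model_free_fc":
            r = int((1 + np.sqrt(1 + 8 * mat.shape[1])) / 2)
            out.append(FeatureBlock(w, mat, "rest", "connectivity_vector",
                                    region_count=r))
        else:
            out.append(FeatureBlock(w, mat, "rest", "region_map"))
    return out


def stage_features(cfg: RunConfig, out: Path, cohort: CohortTable,
                   blocks: list) -> list:
    if not cfg.timeseries_dir:
        return blocks
    inputs = out / "inputs"
    which = cfg.timeseries_blocks or ["model_free_fc"]
    existing = [inputs / f"block_{w}.tsv" for w in which]
    if all(p.exists() for p in existing):
        derived = [FeatureBlock.from_tsv(p) for p in existing]
    else:
        try:
            derived = derive_blocks_from_timeseries(
                cfg.timeseries_dir, cohort.subject_ids, which)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage features failed: {exc}") from exc
        for b in derived:
            b.to_tsv(inputs / f"block_{b.name}.tsv")
            _audit(out, "write", inputs / f"block_{b.name}.tsv")
    return blocks + derived


# ---------------------------------------------------------------- base

def _save_store(store: PredictionStore, d: Path) -> None:
    d.mkdir(parents=True, exist_ok=True)
    for model in store.models:
        rows = []
        for (m, r, f), e in sorted(store.entries.items()):
            if m != model:
                continue
            for i, p, o in zip(e.test_idx, e.test_pred, e.test_obs):
                rows.append((r, f, int(i), "test", float(p), float(o)))
            for i, p, o in zip(e.train_idx, e.train_nested_pred, e.train_obs):
                rows.append((r, f, int(i), "train_nested", float(p), float(o)))
        pd.DataFrame(rows, columns=["repeat", "fold", "subject", "role",
                                    "prediction", "observed"]).to_csv(
            d / f"pred_{model}.tsv", sep="\t", index=False)
    store.accuracy_frame().to_csv(d / "accuracies.tsv", sep="\t", index=False)
    (d / "base.done").write_text("ok\n")


def _load_store(d: Path, splits) -> PredictionStore:
    store = PredictionStore(splits)
    for path in sorted(d.glob("pred_*.tsv")):
        model = path.stem[len("pred_"):]
        df = pd.read_csv(path, sep="\t")
        for (r, f), g in df.groupby(["repeat", "fold"], sort=True):
            te = g[g["role"] == "test"].sort_values("subject")
            tr = g[g["role"] == "train_nested"].sort_values("subject")
            entry = FoldPrediction(
                test_idx=te["subject"].to_numpy(),
                test_pred=te["prediction"].to_numpy(),
                test_obs=te["observed"].to_numpy(),
                train_idx=tr["subject"].to_numpy(),
                train_nested_pred=tr["prediction"].to_numpy(),
                train_obs=tr["observed"].to_numpy(),
                hyperparams={})
            store.add(model, int(r), int(f), entry)
            if model != CONFOUND_MODEL_NAME:
                store.fold_targets.setdefault(
                    (int(r), int(f)),
                    (entry.train_obs, entry.test_obs))
    return store


def stage_base(cfg: RunConfig, out: Path, cohort: CohortTable, blocks: list,
               target: str, splits) -> PredictionStore:
    d = out / "base" / target
    if (d / "base.done").exists():
        _audit(out, "read", d)
        return _load_store(d, splits)
    enet_grid, _ = cfg.make_grids()
    confounds = cohort.confound_matrix()
    y = cohort.target(target)
    seed = derive_seed(cfg.seed, 23)

    def run_block(block):
        s = PredictionStore(splits, target)
        featurewise_predict(block, y, splits, enet_grid, confounds,
                            seed=seed, confound_mode=cfg.confound_mode,
                            store=s)
        return s

    try:
        stores = Parallel(n_jobs=cfg.n_jobs)(
            delayed(run_block)(b) for b in blocks)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(
            f"stage base failed for target {target!r}: {exc}") from exc
    store = PredictionStore(splits, target)
    for s in stores:  # deterministic block order regardless of workers
        for (m, r, f), e in sorted(s.entries.items()):
            store.add(m, r, f, e)
        store.fold_targets.update(s.fold_targets)
    if cfg.include_confound_model:
        confound_model_predict(confounds, y, splits, enet_grid, seed=seed,
                               store=store)
    _save_store(store, d)
    _audit(out, "write", d)
    return store


# ---------------------------------------------------------------- stack

def stage_stack(cfg: RunConfig, out: Path, store: PredictionStore,
                target: str, splits) -> IntegrationCurve:
    d = out / "stack" / target
    curve_file, rank_file = d / "curve.tsv", d / "rankings.json"
    if curve_file.exists() and rank_file.exists():
        _audit(out, "read", curve_file)
        frame = pd.read_csv(curve_file, sep="\t")
        rankings = {tuple(map(int, k.split(","))): v
                    for k, v in json.loads(rank_file.read_text()).items()}
        return IntegrationCurve(frame=frame, rankings=rankings,
                                splits=splits,
                                ranking_metric=cfg.ranking_metric)
    d.mkdir(parents=True, exist_ok=True)
    _, rf_grid = cfg.make_grids()
    try:
        curve = integration_series(store, splits, rf_grid,
                                   metric=cfg.ranking_metric,
                                   seed=derive_seed(cfg.seed, 37),
                                   max_level=cfg.max_level)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(
            f"stage stack failed for target {target!r}: {exc}") from exc
    curve.frame.to_csv(curve_file, sep="\t", index=False)
    rank_file.write_text(json.dumps(
        {f"{r},{f}": v for (r, f), v in sorted(curve.rankings.items())},
        indent=2, sort_keys=True))
    _audit(out, "write", curve_file)
    return curve


# ---------------------------------------------------------------- saturate

def stage_saturate(cfg: RunConfig, out: Path, curve: IntegrationCurve,
                   target: str) -> dict:
    d = out / "saturate"
    d.mkdir(parents=True, exist_ok=True)
    results = {}
    try:
        for metric in METRICS:
            results[metric] = saturate(curve, metric=metric, alpha=cfg.alpha,
                                       method=cfg.correction)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(
            f"stage saturate failed for target {target!r}: {exc}") from exc
    payload = {}
    for metric, sat in sorted(results.items()):
        payload[metric] = {
            "best_level": sat.best_level,
            "necessary_level": sat.necessary_level,
            "necessary_mean_cod": round(sat.necessary_mean_cod, 10),
            "valid": sat.valid,
            "mean_accuracy": {str(k): round(float(v), 10)
                              for k, v in sat.mean_accuracy.items()},
            "composition": {k: round(float(v), 10)
                            for k, v in sat.composition.items()},
        }
    (d / f"{target}.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))
    _audit(out, "write", d / f"{target}.json")
    return results


# ---------------------------------------------------------------- report

def stage_report(out: Path, curves: dict, saturations: dict) -> None:
    """Numeric tables (source of truth) plus a decorative figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = out / "report"
    d.mkdir(parents=True, exist_ok=True)
    if not curves:
        log.warning("report: no completed targets")
        return
    summary_rows, size_rows = [], []
    comp: dict[str, pd.Series] = {}
    for target, curve in sorted(curves.items()):
        sf = curve.summary_frame()
        sf.insert(0, "target", target)
        summary_rows.append(sf)
        for metric, sat in sorted(saturations[target].items()):
            size_rows.append((target, metric, sat.best_level,
                              sat.necessary_level, sat.valid))
        comp[target] = saturations[target]["pearson_r"].composition
    pd.concat(summary_rows).to_csv(d / "curve_summary.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(size_rows, columns=["target", "metric", "best_level",
                                     "necessary_level", "valid"]).to_csv(
        d / "set_sizes.tsv", sep="\t", index=False)
    pd.DataFrame(comp).rename_axis("block").to_csv(
        d / "composition.tsv", sep="\t")

    fig, axes = plt.subplots(1, len(curves), squeeze=False,
                             figsize=(4 * len(curves), 3))
    for ax, (target, curve) in zip(axes[0], sorted(curves.items())):
        for metric, style in (("pearson_r", "o-"), ("cod", "s--")):
            means = curve.mean_accuracy(metric)
            ax.plot(means.index, means.values, style, label=metric, ms=3)
        ax.set_title(target, fontsize=9)
        ax.set_xlabel("integration level")
        ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(d / "integration_curves.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------- run

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns {target: {metric: SaturationResult}}."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    cohort, blocks = stage_simulate(cfg, out)
    blocks = stage_features(cfg, out, cohort, blocks)
    targets = cfg.targets or cohort.target_names
    splits = make_family_folds(cohort.family_ids, cfg.folds, cfg.repeats,
                               derive_seed(cfg.seed, 11))
    log.info("fold sizes: mean train/test = %s", splits.mean_fold_sizes())
    curves, saturations = {}, {}
    for target in targets:
        store = stage_base(cfg, out, cohort, blocks, target, splits)
        curve = stage_stack(cfg, out, store, target, splits)
        curves[target] = curve
        saturations[target] = stage_saturate(cfg, out, curve, target)
    stage_report(out, curves, saturations)
    summary = {
        "seed": int(cfg.seed), "repeats": cfg.repeats, "folds": cfg.folds,
        "targets": {
            t: {m: {"best_level": s.best_level,
                    "necessary_level": s.necessary_level,
                    "necessary_mean_cod": round(s.necessary_mean_cod, 10),
                    "valid": s.valid}
                for m, s in sorted(sats.items())}
            for t, sats in sorted(saturations.items())},
        "valid_targets": sorted(validity_filter(
            {t: s["cod"] for t, s in saturations.items()})),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return saturations
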