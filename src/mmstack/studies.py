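"""Self-contained evaluation studies on synthetic cohorts.

Each function runs one protocol end to end — generating data, fitting
models, measuring an outcome — and returns plain numbers.  They are used
both by the test suite and by the reproduction script, so the conditions
(sample sizes, replicate counts, planted effect sizes) live here in one
place.  Problem sizes are desk-scale: compact feature blocks and small
hyperparameter grids keep a full study in minutes on one CPU while leaving
every protocol step (family-aware CV, in-fold deconfounding, nested
predictions, stacking, corrected testing) identical to a full-size run.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sstats

from .base import HyperparamGrid, PredictionStore, derive_seed, featurewise_predict
from .model import MultimodalStacking
from .saturation import (composition_frequency, corrected_resampled_ttest,
                         naive_paired_ttest, pairwise_level_comparison)
from .splits import make_family_folds
from .stacking import RFGrid
from .synthetic import BlockSpec, CohortSpec, generate_cohort

# compact grids used throughout the synthetic studies
STUDY_ENET = HyperparamGrid(l1_ratios=(0.5,), alphas=(0.01, 0.1, 1.0))
STUDY_RF = RFGrid(n_estimators=(50,), max_depths=(3,), max_features=(1.0,))


def study_blocks():
    """Six compact blocks: four connectivity vectors, two region maps."""
    conn = [("fc_rest", "rest"), ("fc_task", "task"), ("ec_rest", "rest"),
            ("sc_count", "diff")]
    return tuple(
        [BlockSpec(n, "connectivity_vector", t, region_count=12)
         for n, t in conn] +
        [BlockSpec(n, "region_map", "struct", n_features=40)
         for n in ("morph_gmv", "morph_ct")])


# ------------------------------------------------------------ statistical

def ttest_formula_max_error(n_inputs: int = 1000, seed: int = 0) -> float:
    """Max |implementation - direct formula| over random paired inputs.

    The oracle evaluates t = dbar / sqrt((1/J + n_test/n_train) s^2) and the
    Student-t tail directly, independent of the implementation.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_inputs):
        j = int(rng.integers(2, 120))
        a = rng.normal(0.3, 0.15, size=j)
        b = rng.normal(0.3, 0.15, size=j)
        n_train = float(rng.integers(50, 500))
        n_test = float(rng.integers(5, 100))
        res = corrected_resampled_ttest(a, b, n_train, n_test)
        d = a - b
        s2 = d.var(ddof=1)
        if s2 == 0:
            continue
        t = d.mean() / np.sqrt((1.0 / j + n_test / n_train) * s2)
        p = 2.0 * sstats.t.sf(abs(t), j - 1)
        worst = max(worst, abs(res.t - t), abs(res.p - p))
    return worst


def holm_max_error(grid=None) -> float:
    """Max deviation from a hand-stepped Holm oracle over 3-element p-sets."""
    from statsmodels.stats.multitest import multipletests

    grid = grid if grid is not None else np.array(
        [0.001, 0.003, 0.01, 0.02, 0.04, 0.1, 0.5, 1.0])

    def oracle(ps):
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 0.0
        for i, idx in enumerate(order):
            running = max(running, (m - i) * ps[idx])
            adj[idx] = min(running, 1.0)
        return adj

    worst = 0.0
    for ps in itertools.product(grid, repeat=3):
        ps = np.asarray(ps)
        got = multipletests(ps, method="holm")[1]
        worst = max(worst, np.max(np.abs(got - oracle(ps))))
    return worst


# ------------------------------------------------------------ calibration

def calibration_study(n_replicates: int = 200, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Type-I error of the corrected test under a true null.

    Two equally informative blocks (same planted strength) are compared by
    fold-wise correlation accuracy under 2x5 CV at N=300.  Because the two
    models have identical generating accuracy, every rejection is a false
    positive.  The uncorrected paired t-test runs on the same folds as a
    control: fold overlap makes it over-reject, which is why the correction
    exists.
    """
    grid = HyperparamGrid(l1_ratios=(0.5,), alphas=(0.1,))
    rej_corr, rej_naive = 0, 0
    blocks = (BlockSpec("fc_a", "connectivity_vector", "rest",
                        region_count=10),
              BlockSpec("fc_b", "connectivity_vector", "rest",
                        region_count=10))
    for i in range(n_replicates):
        rep_seed = derive_seed(seed, 101, i)
        spec = CohortSpec(n_subjects=300, folds_hint=5, blocks=blocks,
                          informative=("fc_a", "fc_b"), signal_r2=0.4,
                          confound_r2=0.0)
        cohort, bl, _ = generate_cohort(spec, rep_seed)
        splits = make_family_folds(cohort.family_ids, 5, 2,
                                   derive_seed(rep_seed, 1))
        store = PredictionStore(splits)
        y = cohort.target("score")
        conf = cohort.confound_matrix()
        for b in bl:
            featurewise_predict(b, y, splits, grid, conf,
                                seed=derive_seed(rep_seed, 2), store=store,
                                compute_nested=False)
        acc_a = np.array([r.pearson_r for r in store.test_records("fc_a")])
        acc_b = np.array([r.pearson_r for r in store.test_records("fc_b")])
        n_train, n_test = splits.mean_fold_sizes()
        rej_corr += corrected_resampled_ttest(acc_a, acc_b, n_train,
                                              n_test).p < alpha
        rej_naive += naive_paired_ttest(acc_a, acc_b).p < alpha
    return {"corrected_rate": rej_corr / n_replicates,
            "naive_rate": rej_naive / n_replicates,
            "n_replicates": n_replicates}


# ------------------------------------------------------------ recovery

def recovery_study(m: int, n_runs: int = 20, seed: int = 0) -> dict:
    """Necessary-set recovery with signal planted in m of 6 blocks.

    Total planted target variance is R^2 = 0.4, shared across the m blocks
    (latent sharing 0.5).  Each run fits the full protocol under 10-fold CV
    and reports the necessary level plus whether every planted block
    out-ranks every noise block in top-m composition frequency.
    """
    planted = [b.name for b in study_blocks()][:m]
    necessary_levels, recovered = [], 0
    for i in range(n_runs):
        run_seed = derive_seed(seed, 202, m, i)
        spec = CohortSpec(n_subjects=200, folds_hint=10,
                          blocks=study_blocks(), informative=tuple(planted),
                          signal_r2=0.4, confound_r2=0.0)
        model = MultimodalStacking.from_synthetic(
            spec, seed=run_seed, repeats=1, folds=10,
            enet_grid=STUDY_ENET, rf_grid=STUDY_RF)
        res = model.fit(seed=derive_seed(run_seed, 1))
        necessary_levels.append(res.necessary_level("pearson_r"))
        top_m = composition_frequency(res.curve.rankings, m)
        noise = top_m.drop(planted)
        recovered += float(top_m[planted].min()) > float(noise.max())
    return {"median_necessary": float(np.median(necessary_levels)),
            "necessary_levels": necessary_levels,
            "recovery_fraction": recovered / n_runs,
            "n_runs": n_runs}


# ------------------------------------------------------------ leakage

LEAKAGE_BLOCKS = (
    BlockSpec("fc_rest", "connectivity_vector", "rest", region_count=10),
    BlockSpec("fc_task", "connectivity_vector", "task", region_count=10),
    BlockSpec("morph", "region_map", "struct", n_features=30),
)


def leakage_study(n_permutations: int = 50, seed: int = 0) -> dict:
    """Permutation null for every model class at N=200.

    The cohort carries real planted signal, but the target is freshly
    permuted before each fit, destroying all subject-level association.  A
    leakage-free pipeline must then score COD <= 0 in expectation for
    feature-wise, confound and stacked models at every level.
    Returns per-class mean COD and Monte-Carlo standard errors.
    """
    spec = CohortSpec(n_subjects=200, folds_hint=5, blocks=LEAKAGE_BLOCKS,
                      informative=("fc_rest", "morph"), signal_r2=0.4,
                      confound_r2=0.1)
    cohort, blocks, _ = generate_cohort(spec, derive_seed(seed, 303))
    rng = np.random.default_rng(derive_seed(seed, 304))
    cods: dict[str, list] = {}
    for i in range(n_permutations):
        shuffled = cohort.table.copy()
        shuffled["score"] = rng.permutation(shuffled["score"].to_numpy())
        from .cohort import CohortTable

        model = MultimodalStacking(
            CohortTable(shuffled), list(blocks), "score", repeats=1, folds=5,
            enet_grid=STUDY_ENET, rf_grid=STUDY_RF)
        res = model.fit(seed=derive_seed(seed, 305, i))
        for rec in res.store.records:
            cods.setdefault(rec.model, []).append(rec.cod)
        for level, grp in res.curve.frame.groupby("level"):
            cods.setdefault(f"stacked_level{level}", []).extend(
                grp["cod"].tolist())
    out = {}
    for name, values in cods.items():
        v = np.asarray(values)
        out[name] = {"mean_cod": float(v.mean()),
                     "se": float(v.std(ddof=1) / np.sqrt(v.size))}
    return out


def heldout_mutation_check(seed: int = 0) -> bool:
    """Bit-level check that scrambling held-out subjects leaves the
    training-side fit (hyperparameters, nested predictions) unchanged."""
    from .cohort import FeatureBlock

    spec = CohortSpec(n_subjects=120, folds_hint=3,
                      blocks=(BlockSpec("b", "region_map", "rest",
                                        n_features=20),),
                      informative=("b",), signal_r2=0.4, confound_r2=0.0)
    cohort, blocks, _ = generate_cohort(spec, derive_seed(seed, 306))
    splits = make_family_folds(cohort.family_ids, 3, 1, derive_seed(seed, 307))
    y = cohort.target("score")
    conf = cohort.confound_matrix()
    s1, _ = featurewise_predict(blocks[0], y, splits, STUDY_ENET, conf,
                                seed=0)
    te = splits.test_indices(0, 0)
    rng = np.random.default_rng(derive_seed(seed, 308))
    mutated = FeatureBlock("b", blocks[0].matrix.copy(), "rest", "region_map")
    mutated.matrix[te] = rng.normal(size=(len(te), 20))
    y2 = y.copy()
    y2[te] = rng.normal(size=len(te))
    s2, _ = featurewise_predict(mutated, y2, splits, STUDY_ENET, conf,
                                seed=0)
    e1, e2 = s1.get("b", 0, 0), s2.get("b", 0, 0)
    return (e1.hyperparams == e2.hyperparams
            and np.array_equal(e1.train_nested_pred, e2.train_nested_pred))


# ------------------------------------------------------------ shape

def shape_study(seed: int = 0) -> dict:
    """Demo run: complementary signal in 3 of 6 blocks (N=200, 2x5 CV).

    The three planted blocks carry disjoint shares of a joint R^2 = 0.6, so
    integrating them should raise accuracy over any single block before the
    curve flattens.
    """
    planted = ("fc_rest", "fc_task", "morph_gmv")
    spec = CohortSpec(n_subjects=200, folds_hint=5, blocks=study_blocks(),
                      informative=planted, signal_r2=0.6, confound_r2=0.1,
                      latent_sharing=0.0)
    model = MultimodalStacking.from_synthetic(
        spec, seed=derive_seed(seed, 404), repeats=2, folds=5,
        enet_grid=STUDY_ENET, rf_grid=STUDY_RF)
    res = model.fit(seed=derive_seed(seed, 405))
    means_r = res.mean_accuracy("pearson_r")
    out = {"level_means_r": {int(k): float(v) for k, v in means_r.items()},
           "level1_mean_r": float(means_r.loc[1]),
           "best_mean_r": float(means_r.max()),
           "last_mean_r": float(means_r.iloc[-1]),
           "n_subjects": spec.n_subjects}
    for metric in ("pearson_r", "cod"):
        sat = res.saturation[metric]
        out[f"best_level_{metric}"] = sat.best_level
        out[f"necessary_level_{metric}"] = sat.necessary_level
        out[f"valid_{metric}"] = sat.valid
    return out


# ------------------------------------------------------------ feature oracles

def _brute_force_paths(w: np.ndarray):
    """All-pairs shortest 1/weight paths by exhaustive enumeration."""
    n = w.shape[0]
    best = np.full((n, n), np.inf)
    for i in range(n):
        for jj in range(n):
            if i == jj:
                continue
            others = [x for x in range(n) if x not in (i, jj)]
            for k in range(n - 1):
                for mid in itertools.permutations(others, k):
                    path = (i, *mid, jj)
                    if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                        length = sum(1.0 / w[a, b]
                                     for a, b in zip(path, path[1:]))
                        best[i, jj] = min(best[i, jj], length)
    off = best[~np.eye(n, dtype=bool)]
    cpl = off[np.isfinite(off)].mean()
    geff = float(np.mean(np.where(np.isfinite(off), 1.0 / off, 0.0)))
    return cpl, geff


def _brute_force_modularity(w: np.ndarray) -> float:
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / two_m
    best = -np.inf

    def rec(labels, mx):
        nonlocal best
        if len(labels) == n:
            lab = np.asarray(labels)
            best = max(best, float(b[lab[:, None] == lab[None, :]].sum())
                       / two_m)
            return
        for c in range(mx + 2):
            rec(labels + [c], max(mx, c))

    rec([0], 0)
    return best


def graph_metric_max_error(n_seeds: int = 100, seed: int = 0) -> float:
    """Worst deviation of path/efficiency/modularity from brute force on
    random weighted graphs with at most 8 nodes."""
    from .features import network_statistics

    worst = 0.0
    rng = np.random.default_rng(seed)
    done = 0
    while done < n_seeds:
        n = int(rng.integers(4, 9))
        w = rng.uniform(-0.3, 1.0, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        wc = np.where(w > 0, w, 0.0)
        if not np.any(wc > 0):
            continue
        stats = network_statistics(w, seed=done)
        cpl, geff = _brute_force_paths(wc)
        q = _brute_force_modularity(wc)
        worst = max(worst, abs(stats[0] - cpl), abs(stats[1] - geff),
                    abs(stats[2] - q))
        done += 1
    return worst


def ar_recovery_max_error(timepoints: int = 10_000, seed: int = 0) -> float:
    """Entrywise VAR(1) recovery error at long T, worst of signal and null."""
    from .features import time_varying_fc

    rng = np.random.default_rng(seed)
    a = np.array([[0.5, 0.2, 0.0], [0.0, 0.4, 0.1], [0.1, 0.0, 0.3]])
    x = np.zeros((3, timepoints))
    for t in range(1, timepoints):
        x[:, t] = a @ x[:, t - 1] + rng.normal(size=3)
    err_signal = np.max(np.abs(time_varying_fc(x).reshape(3, 3) - a))
    null = rng.normal(size=(3, timepoints))
    err_null = np.max(np.abs(time_varying_fc(null)))
    return float(max(err_signal, err_null))


def gradient_separates_blocks(seed: int = 0) -> bool:
    """First diffusion gradient splits a two-block FC by sign, exactly."""
    from .features import gradient_fit

    r = 12
    fc = np.full((r, r), 0.2)
    fc[:r // 2, :r // 2] = 0.9
    fc[r // 2:, r // 2:] = 0.9
    np.fill_diagonal(fc, 1.0)
    g1 = gradient_fit(fc, components=3, sparsity_quantile=0.5).loadings[:, 0]
    return (len(set(np.sign(g1[:r // 2]))) == 1
            and len(set(np.sign(g1[r // 2:]))) == 1
            and np.sign(g1[0]) != np.sign(g1[-1]))


def morphometry_formula_max_error() -> float:
    """Hand-computed SA/GMV/CT normalisations."""
    from .features import normalize_morphometry

    errs = [
        abs(normalize_morphometry(np.array([100.0]), 1000.0, "SA")[0] - 1.0),
        abs(normalize_morphometry(np.array([3.0]), 2.0, "GMV")[0] - 1.5),
        np.max(np.abs(normalize_morphometry(np.array([2.0, 4.0]), 1.0, "CT")
                      - np.array([2.0 / 3.0, 4.0 / 3.0]))),
    ]
    return float(max(errs))


def morphcov_identity_max_error(seed: int = 0) -> float:
    """Training-mean identity: mean subject edge = Pearson r * (n-1)/n."""
    from .features import morphcov_apply, morphcov_fit

    rng = np.random.default_rng(seed)
    train = rng.normal(size=(40, 6))
    model = morphcov_fit(train)
    edges = np.stack([morphcov_apply(row, model) for row in train])
    iu = np.triu_indices(6, k=1)
    corr = np.corrcoef(train.T)[iu]
    n = train.shape[0]
    return float(np.max(np.abs(edges.mean(axis=0) - corr * (n - 1) / n)))
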