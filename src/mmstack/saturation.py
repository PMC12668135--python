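"""Saturation inference: which integration level is enough?

Fold-wise accuracies from repeated cross-validation are not independent
(training sets overlap), so a naive paired t-test over folds badly
over-rejects.  The corrected resampled t-test inflates the variance by the
test/train size ratio:

    t = d_bar / sqrt((1/J + n_test/n_train) * s^2),   df = J - 1

with J the number of (repeat, fold) cells, d_bar and s^2 the mean and
sample variance of the fold-wise accuracy differences.  All level pairs are
compared two-sidedly and corrected for multiple comparisons; the "best"
level maximises mean accuracy, and the "necessary" level is the lowest one
statistically comparable (corrected p >= alpha) to the best — the point
where adding more feature types stops paying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

CORRECTION_METHODS = {"holm": "holm", "bonferroni": "bonferroni",
                      "fdr_bh": "fdr_bh", "none": None}


@dataclass
class TTestResult:
    mean_diff: float
    var_diff: float
    rho: float            # n_test / n_train correction factor
    j: int
    t: float
    df: int
    p: float


def corrected_resampled_ttest(acc_a, acc_b, n_train: float,
                              n_test: float) -> TTestResult:
    """Corrected resampled t-test on paired fold-wise accuracies.

    ``acc_a`` and ``acc_b`` must be paired by (repeat, fold).  Degenerate
    zero-variance differences give t=0, p=1 when the means agree and
    p=0 otherwise.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("accuracy vectors must be equal-length 1-D")
    j = a.size
    if j < 2:
        raise ValueError("need at least 2 paired folds")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("fold sizes must be positive")
    d = a - b
    dbar = float(d.mean())
    s2 = float(d.var(ddof=1))
    rho = float(n_test) / float(n_train)
    if s2 == 0.0:
        t = 0.0 if dbar == 0.0 else np.inf * np.sign(dbar)
        p = 1.0 if dbar == 0.0 else 0.0
    else:
        t = dbar / np.sqrt((1.0 / j + rho) * s2)
        p = 2.0 * float(sstats.t.sf(abs(t), j - 1))
    return TTestResult(mean_diff=dbar, var_diff=s2, rho=rho, j=j,
                       t=float(t), df=j - 1, p=p)


def naive_paired_ttest(acc_a, acc_b) -> TTestResult:
    """Uncorrected paired t-test (control; over-rejects on CV folds)."""
    r = corrected_resampled_ttest(acc_a, acc_b, n_train=1.0, n_test=1.0)
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    d = a - b
    j = d.size
    s2 = float(d.var(ddof=1))
    if s2 == 0.0:
        return r
    t = float(d.mean() / np.sqrt(s2 / j))
    p = 2.0 * float(sstats.t.sf(abs(t), j - 1))
    return TTestResult(mean_diff=r.mean_diff, var_diff=s2, rho=0.0, j=j,
                       t=t, df=j - 1, p=p)


def pairwise_level_comparison(curve, metric: str = "pearson_r",
                              method: str = "holm") -> pd.DataFrame:
    """Corrected two-sided p-values for every pair of integration levels.

    Returns a symmetric levels x levels matrix with unit diagonal; with
    ``method='none'`` the raw p-values pass through (diagnostics).
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"method must be one of {sorted(CORRECTION_METHODS)}")
    levels = curve.levels
    if len(levels) < 2:
        raise ValueError("need at least 2 levels to compare")
    folds = curve.fold_matrix(metric)
    n_train, n_test = curve.splits.mean_fold_sizes()
    pairs = [(i, j) for i in range(len(levels)) for j in range(len(levels))
             if i < j]
    raw = np.array([
        corrected_resampled_ttest(folds[:, i], folds[:, j],
                                  n_train, n_test).p
        for i, j in pairs])
    if CORRECTION_METHODS[method] is None:
        corrected = raw
    else:
        corrected = multipletests(raw, method=CORRECTION_METHODS[method])[1]
    mat = np.ones((len(levels), len(levels)))
    for (i, j), p in zip(pairs, corrected):
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=levels, columns=levels)


@dataclass
class SaturationResult:
    """Best/necessary integration levels and supporting evidence."""

    metric: str
    alpha: float
    best_level: int
    necessary_level: int
    mean_accuracy: pd.Series          # per level, in `metric`
    necessary_mean_cod: float
    p_matrix: pd.DataFrame
    composition: pd.Series            # block -> necessary-set frequency
    fold_best_sets: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        """Validity filter: necessary-level mean COD strictly above 0."""
        return bool(self.necessary_mean_cod > 0.0)


def best_and_necessary(curve, p_matrix: pd.DataFrame, alpha: float = 0.05,
                       metric: str = "pearson_r") -> tuple[int, int]:
    """Select the best (max mean accuracy, lowest level on ties) and
    necessary (lowest level with corrected p >= alpha vs best) levels."""
    means = curve.mean_accuracy(metric)
    best = int(means.idxmax())  # idxmax returns the first (lowest) on ties
    if best == 1:
        return 1, 1
    necessary = best
    for level in sorted(l for l in curve.levels if l <= best):
        if float(p_matrix.loc[level, best]) >= alpha:
            necessary = int(level)
            break
    return best, necessary


def composition_frequency(rankings: dict, level: int,
                          models: list[str] | None = None) -> pd.Series:
    """Fraction of CV cells whose top-``level`` ranking contains each block.

    Per cell exactly ``level`` memberships are counted, so the frequencies
    sum to ``level`` across blocks.
    """
    counts: dict[str, int] = {}
    for ranking in rankings.values():
        for m in ranking[:level]:
            counts[m] = counts.get(m, 0) + 1
    names = models if models is not None else sorted(
        {m for r in rankings.values() for m in r})
    n = len(rankings)
    return pd.Series({m: counts.get(m, 0) / n for m in names},
                     name="frequency").sort_index()


def saturate(curve, *, metric: str = "pearson_r", alpha: float = 0.05,
             method: str = "holm") -> SaturationResult:
    """Full saturation inference for one target and one metric."""
    p_matrix = pairwise_level_comparison(curve, metric, method)
    best, necessary = best_and_necessary(curve, p_matrix, alpha, metric)
    cod_means = curve.mean_accuracy("cod")
    composition = composition_frequency(curve.rankings, necessary)
    fold_best = {key: ranking[:best]
                 for key, ranking in curve.rankings.items()}
    return SaturationResult(
        metric=metric, alpha=alpha, best_level=best,
        necessary_level=necessary,
        mean_accuracy=curve.mean_accuracy(metric),
        necessary_mean_cod=float(cod_means.loc[necessary]),
        p_matrix=p_matrix, composition=composition,
        fold_best_sets=fold_best)


def validity_filter(results: dict[str, SaturationResult]
                    ) -> dict[str, SaturationResult]:
    """Keep targets whose necessary-level mean COD is strictly positive."""
    return {k: v for k, v in results.items() if v.valid}
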