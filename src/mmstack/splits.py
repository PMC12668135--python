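"""Family-aware repeated k-fold split schemes.

Whole families are assigned to folds so related subjects never straddle a
train/test boundary; every model in a run shares one scheme so fold-wise
accuracies are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class SplitScheme:
    """Repeat x subject fold assignment, family-respecting."""

    assignment: np.ndarray  # (repeats, n_subjects) int fold ids
    folds: int
    seed: int
    family_ids: np.ndarray

    @property
    def repeats(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.assignment.shape[1]

    def iter_folds(self):
        """Yield (repeat, fold, train_idx, test_idx) over all cells."""
        for r in range(self.repeats):
            for f in range(self.folds):
                test = np.nonzero(self.assignment[r] == f)[0]
                train = np.nonzero(self.assignment[r] != f)[0]
                yield r, f, train, test

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment[repeat] == fold)[0]

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment[repeat] != fold)[0]

    def mean_fold_sizes(self) -> tuple[float, float]:
        """Average (n_train, n_test) across cells; used by the corrected t."""
        n = self.n_subjects
        n_test = n / self.folds
        return n - n_test, n_test


def assign_families(family_sizes: dict, folds: int,
                    rng: np.random.Generator) -> dict:
    """Greedy balanced assignment: families (shuffled, then largest first)
    go to the currently smallest fold."""
    names = list(family_sizes)
    order = rng.permutation(len(names))
    shuffled = [names[i] for i in order]
    shuffled.sort(key=lambda f: -family_sizes[f])  # stable: ties keep shuffle
    loads = np.zeros(folds)
    out = {}
    for fam in shuffled:
        k = int(np.argmin(loads))
        out[fam] = k
        loads[k] += family_sizes[fam]
    if loads.max() - loads.min() > max(family_sizes.values()):
        log.info("fold imbalance %d exceeds largest family",
                 int(loads.max() - loads.min()))
    return out


def make_family_folds(families, folds: int, repeats: int,
                      seed: int) -> SplitScheme:
    """Build a repeated family-aware k-fold scheme, deterministic under seed.

    Parameters
    ----------
    families
        Per-subject family identifiers, aligned with the cohort row order.
    """
    fam = np.asarray(families)
    unique, counts = np.unique(fam, return_counts=True)
    if len(unique) < folds:
        raise ValueError(
            f"{len(unique)} families cannot fill {folds} folds")
    sizes = dict(zip(unique.tolist(), counts.tolist()))
    rng = np.random.default_rng(seed)
    assignment = np.empty((repeats, len(fam)), dtype=int)
    for r in range(repeats):
        fam_fold = assign_families(sizes, folds, rng)
        assignment[r] = [fam_fold[f] for f in fam]
    return SplitScheme(assignment=assignment, folds=folds, seed=seed,
                       family_ids=fam)


def inner_folds(train_families, n_folds: int, seed: int) -> np.ndarray:
    """Family-aware fold ids for an inner (nested) CV over training rows."""
    scheme = make_family_folds(train_families, n_folds, 1, seed)
    return scheme.assignment[0]
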