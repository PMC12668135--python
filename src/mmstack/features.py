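"""Connectome-style feature derivations from parcellated timeseries and
region-wise morphometry.

All subject-level derivations here are deterministic functions of a single
subject's data.  The two group-level derivations (diffusion-map gradients
and morphometric covariance) follow a fit/apply split: parameters are
estimated on training subjects only and then applied unchanged to test
subjects, so they can be used inside cross-validation without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "model_free_fc", "time_varying_fc", "network_statistics",
    "GradientTemplate", "gradient_fit", "gradient_project",
    "normalize_morphometry", "MorphCovModel", "morphcov_fit", "morphcov_apply",
    "fc_matrix_from_timeseries",
]

_CLAMP = 1.0 - 1e-7


class DegenerateInputError(ValueError):
    """A region or matrix is degenerate for the requested derivation."""


def fc_matrix_from_timeseries(ts: np.ndarray) -> np.ndarray:
    """Pearson FC matrix (region x region, unit diagonal) from region x time."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise DegenerateInputError("need a region x time matrix with >= 3 timepoints")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        region = int(np.nonzero(sd == 0)[0][0])
        raise DegenerateInputError(f"region {region} has constant timeseries")
    fc = np.corrcoef(ts)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return (fc + fc.T) / 2.0


def model_free_fc(ts: np.ndarray) -> np.ndarray:
    """Fisher-z upper triangle of the Pearson FC matrix.

    Correlations are clamped to +/-(1 - 1e-7) before arctanh so duplicated
    regions yield a finite (large) z rather than infinity.
    """
    fc = fc_matrix_from_timeseries(ts)
    iu = np.triu_indices(fc.shape[0], k=1)
    r = np.clip(fc[iu], -_CLAMP, _CLAMP)
    return np.arctanh(r)


def time_varying_fc(ts: np.ndarray, *, ridge: float = 0.0) -> np.ndarray:
    """First-order autoregressive coefficient matrix, flattened row-major.

    Solves ``x_t ~ A x_{t-1}`` by least squares on per-region demeaned data;
    the full R x R matrix (diagonal included) is returned.  ``ridge`` adds
    an L2 penalty (lambda * I on the Gram matrix) for near-singular designs.
    """
    ts = np.asarray(ts, dtype=float)
    r, t = ts.shape
    if t < r + 2:
        raise DegenerateInputError(
            f"need at least R+2={r + 2} timepoints for the AR(1) fit, got {t}")
    past, present = ts[:, :-1], ts[:, 1:]
    # demean each regression window separately (equivalent to an intercept),
    # so a noiseless x_t = a x_{t-1} recovers a exactly
    past = past - past.mean(axis=1, keepdims=True)
    present = present - present.mean(axis=1, keepdims=True)
    gram = past @ past.T
    if ridge > 0:
        gram = gram + ridge * np.eye(r)
    elif np.linalg.matrix_rank(gram) < r:
        raise DegenerateInputError(
            "rank-deficient AR regressor matrix; add timepoints or pass "
            "ridge=1e-6")
    coef = np.linalg.solve(gram, past @ present.T).T
    return coef.reshape(-1)


#: Graphs up to this many nodes get exact maximum-modularity partitions.
EXACT_MODULARITY_NODES = 8


def _exact_communities(w: np.ndarray) -> list[set]:
    """Global maximum-modularity partition by exhaustive enumeration.

    Feasible only for tiny graphs (Bell(8) = 4140 partitions); larger
    graphs fall back to the Louvain heuristic, which is not guaranteed to
    reach the global optimum.
    """
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / two_m

    best_q, best_labels = -np.inf, None

    def rec(labels: list[int], mx: int) -> None:
        nonlocal best_q, best_labels
        if len(labels) == n:
            lab = np.asarray(labels)
            same = lab[:, None] == lab[None, :]
            q = float(b[same].sum()) / two_m
            if q > best_q:
                best_q, best_labels = q, lab
            return
        for c in range(mx + 2):  # restricted growth strings
            rec(labels + [c], max(mx, c))

    rec([0], 0)
    return [set(np.nonzero(best_labels == c)[0].tolist())
            for c in np.unique(best_labels)]


def _detect_communities(graph: nx.Graph, w: np.ndarray, seed: int,
                        restarts: int) -> list[set]:
    if w.shape[0] <= EXACT_MODULARITY_NODES:
        return _exact_communities(w)
    best, best_q = None, -np.inf
    for k in range(restarts):
        comms = nx.community.louvain_communities(
            graph, weight="weight", seed=seed + k)
        q = nx.community.modularity(graph, comms, weight="weight")
        if q > best_q:
            best, best_q = comms, q
    return [set(c) for c in best]


def network_statistics(fc: np.ndarray, *, negative_mode: str = "zero",
                       seed: int = 0, restarts: int = 20) -> np.ndarray:
    """Weighted graph metrics of an FC matrix.

    Returns ``[characteristic path length, global efficiency, modularity,
    participation_1..R]``.  Negative weights are zeroed (``negative_mode
    ='zero'``) or absolute-valued (``'abs'``) first; path-based metrics use
    length 1/weight; communities maximise modularity (exact enumeration up
    to 8 nodes, seeded Louvain restarts beyond), and participation
    coefficients are computed against that partition.
    """
    w = np.asarray(fc, dtype=float).copy()
    if not np.allclose(w, w.T, atol=1e-12):
        raise DegenerateInputError("FC matrix must be symmetric")
    np.fill_diagonal(w, 0.0)
    if negative_mode == "zero":
        w = np.where(w > 0, w, 0.0)
    elif negative_mode == "abs":
        w = np.abs(w)
    else:
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    r = w.shape[0]
    if not np.any(w > 0):
        raise DegenerateInputError("all-zero graph after negative-weight handling")

    graph = nx.from_numpy_array(w)
    for _, _, d in graph.edges(data=True):
        d["length"] = 1.0 / d["weight"]

    # characteristic path length & global efficiency on 1/weight lengths
    dist = dict(nx.all_pairs_dijkstra_path_length(graph, weight="length"))
    pairs = [(i, j) for i in range(r) for j in range(r) if i != j]
    dvals = np.array([dist[i].get(j, np.inf) for i, j in pairs])
    finite = np.isfinite(dvals)
    cpl = float(dvals[finite].mean()) if finite.any() else np.inf
    geff = float(np.mean(np.where(finite, 1.0 / dvals, 0.0)))

    comms = _detect_communities(graph, w, seed=seed, restarts=restarts)
    q = float(nx.community.modularity(graph, comms, weight="weight"))

    membership = np.empty(r, dtype=int)
    for ci, c in enumerate(comms):
        for node in c:
            membership[node] = ci
    strength = w.sum(axis=1)
    part = np.zeros(r)
    for i in range(r):
        if strength[i] <= 0:
            continue
        acc = 0.0
        for ci in range(len(comms)):
            k_is = w[i, membership == ci].sum()
            acc += (k_is / strength[i]) ** 2
        part[i] = 1.0 - acc
    return np.concatenate([[cpl, geff, q], part])


@dataclass
class GradientTemplate:
    """Diffusion-map embedding fitted on a training-group-average FC.

    Holds everything needed for Nystrom-style out-of-sample projection:
    the sparsified reference rows, the anisotropic-normalisation degrees,
    and the diffusion-operator eigenvectors/eigenvalues.  Loadings are the
    eigenvectors scaled by their eigenvalues, with sign fixed so the
    largest-magnitude entry of each component is positive.
    """

    reference_rows: np.ndarray       # sparsified training-average FC rows
    degrees: np.ndarray              # anisotropic kernel degrees d_i
    eigenvalues: np.ndarray          # descending, trivial component dropped
    eigenvectors: np.ndarray         # R x C
    components: int
    sparsity_quantile: float
    alpha: float
    fitted_on_training: bool = True

    @property
    def loadings(self) -> np.ndarray:
        return self.eigenvectors * self.eigenvalues


def _sparsify_rows(fc: np.ndarray, quantile: float) -> np.ndarray:
    out = fc.copy()
    np.fill_diagonal(out, 0.0)
    thresh = np.quantile(out, quantile, axis=1, keepdims=True)
    out[out < thresh] = 0.0
    return out


def _cosine_affinity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    aff = (a / na) @ (b / nb).T
    return np.clip(aff, 0.0, None)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for c in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, c]))
        if out[k, c] < 0:
            out[:, c] = -out[:, c]
    return out


def gradient_fit(training_fc_mean: np.ndarray, components: int = 10, *,
                 sparsity_quantile: float = 0.9,
                 alpha: float = 0.5) -> GradientTemplate:
    """Fit a diffusion-map gradient template on a training-average FC.

    Rows are sparsified to their top ``1 - sparsity_quantile`` entries,
    a nonnegative cosine affinity kernel is built, anisotropically
    normalised with exponent ``alpha``, row-normalised to a diffusion
    operator, and eigendecomposed.  The trivial constant component is
    dropped and signs are fixed deterministically.
    """
    fc = np.asarray(training_fc_mean, dtype=float)
    r = fc.shape[0]
    if components >= r:
        raise ValueError(f"components={components} must be < regions={r}")
    rows = _sparsify_rows(fc, sparsity_quantile)
    aff = _cosine_affinity(rows, rows)
    n_comp, _ = connected_components(aff > 0, directed=False)
    if n_comp > 1:
        raise DegenerateInputError(
            f"affinity graph is disconnected ({n_comp} components); lower "
            "the sparsity quantile")
    d = aff.sum(axis=1) ** alpha
    w = aff / np.outer(d, d)
    degrees = w.sum(axis=1)
    m = w / degrees[:, None]
    evals, evecs = np.linalg.eig(m)
    order = np.argsort(-evals.real)
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    # drop the trivial stationary component (eigenvalue 1, constant vector)
    evals, evecs = evals[1:components + 1], evecs[:, 1:components + 1]
    if np.ptp(evals) < 1e-10:
        warnings.warn("flat diffusion spectrum: gradients are not well "
                      "separated", RuntimeWarning, stacklevel=2)
    evecs = _fix_signs(evecs)
    return GradientTemplate(reference_rows=rows, degrees=degrees,
                            eigenvalues=evals, eigenvectors=evecs,
                            components=components,
                            sparsity_quantile=sparsity_quantile, alpha=alpha)


def gradient_project(fc: np.ndarray, template: GradientTemplate) -> np.ndarray:
    """Nystrom projection of a subject FC onto a fitted gradient template.

    Projecting the training-average FC itself reproduces the template
    loadings (M V = V Lambda, so the row-normalised kernel against the
    reference maps eigenvectors onto eigenvalue-scaled eigenvectors).
    Returns the C region-loading vectors flattened (R*C,).
    """
    if not template.fitted_on_training:
        raise ValueError("template must be fitted before projection")
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != template.reference_rows.shape[0]:
        raise ValueError(
            f"region count mismatch: subject {fc.shape[0]} vs template "
            f"{template.reference_rows.shape[0]}")
    rows = _sparsify_rows(fc, template.sparsity_quantile)
    aff = _cosine_affinity(rows, template.reference_rows)
    d_new = aff.sum(axis=1) ** template.alpha
    d_new[d_new == 0] = 1.0
    # anisotropic normalisation identical to fit: divide by d_new^a * d_ref^a
    d_ref = _cosine_affinity(template.reference_rows,
                             template.reference_rows).sum(axis=1) ** template.alpha
    w = aff / np.outer(d_new, d_ref)
    row_sum = w.sum(axis=1)
    row_sum[row_sum == 0] = 1.0
    m = w / row_sum[:, None]
    return (m @ template.eigenvectors).reshape(-1, order="F").reshape(-1)


def normalize_morphometry(values: np.ndarray, icv: float,
                          measure_kind: str) -> np.ndarray:
    """Brain-size adjustment of region-wise morphometry.

    Surface area is divided by ICV^(2/3), grey-matter volume by ICV, and
    cortical thickness by its mean across regions.
    """
    v = np.asarray(values, dtype=float)
    kind = measure_kind.upper()
    if kind in ("SA", "GMV"):
        if icv <= 0:
            raise ValueError(f"icv must be positive, got {icv}")
        return v / icv ** (2.0 / 3.0) if kind == "SA" else v / icv
    if kind == "CT":
        m = v.mean()
        if m == 0:
            raise ValueError("cortical thickness mean is zero")
        return v / m
    raise ValueError(f"unknown measure_kind {measure_kind!r}; use SA/GMV/CT")


@dataclass
class MorphCovModel:
    """Training mean/sd of one morphometry measure, per region."""

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray  # bool mask of zero-variance regions


def morphcov_fit(training_measures: np.ndarray) -> MorphCovModel:
    """Fit per-region standardisation parameters on training subjects only."""
    x = np.asarray(training_measures, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a subjects x regions matrix with >= 3 training "
                         "subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) with zero training variance; "
            "their edges are set to 0", RuntimeWarning, stacklevel=2)
        sd = np.where(degenerate, 1.0, sd)
    return MorphCovModel(mean=mean, sd=sd, degenerate=degenerate)


def gradient_foldwise_block(name: str, subject_fcs: np.ndarray,
                            components: int = 10, *,
                            sparsity_quantile: float = 0.9,
                            alpha: float = 0.5, modality_tag: str = "rest"):
    """Fold-wise gradient-loading block over per-subject FC matrices.

    The diffusion-map template is fitted on the *training* subjects' average
    FC in each fold and projected onto everyone, so no test information
    shapes the embedding.  ``subject_fcs`` is (subjects, R, R).
    """
    from .base import FoldwiseBlock

    fcs = np.asarray(subject_fcs, dtype=float)

    def build(train_idx, test_idx):
        template = gradient_fit(fcs[train_idx].mean(axis=0), components,
                                sparsity_quantile=sparsity_quantile,
                                alpha=alpha)
        x_tr = np.stack([gradient_project(fcs[i], template)
                         for i in train_idx])
        x_te = np.stack([gradient_project(fcs[i], template)
                         for i in test_idx])
        return x_tr, x_te

    return FoldwiseBlock(name, build, modality_tag=modality_tag)


def morphcov_foldwise_block(name: str, measures: np.ndarray, *,
                            modality_tag: str = "struct"):
    """Fold-wise morphometric-covariance block (training-only z-scoring)."""
    from .base import FoldwiseBlock

    x = np.asarray(measures, dtype=float)

    def build(train_idx, test_idx):
        model = morphcov_fit(x[train_idx])
        x_tr = np.stack([morphcov_apply(x[i], model) for i in train_idx])
        x_te = np.stack([morphcov_apply(x[i], model) for i in test_idx])
        return x_tr, x_te

    return FoldwiseBlock(name, build, modality_tag=modality_tag)


def morphcov_apply(subject_measures: np.ndarray,
                   model: MorphCovModel | None) -> np.ndarray:
    """Subject-level morphometric-covariance edges.

    Edge (i, j) is the product of the subject's training z-scores
    ``z_i * z_j``; averaged over the training subjects this recovers the
    training Pearson correlation of regions i and j up to the (n-1)/n
    factor.  Returns the upper triangle.
    """
    if not isinstance(model, MorphCovModel):
        raise ValueError("morphcov_apply requires a fitted MorphCovModel; "
                         "call morphcov_fit first")
    v = np.asarray(subject_measures, dtype=float)
    z = (v - model.mean) / model.sd
    z = np.where(model.degenerate, 0.0, z)
    edges = np.outer(z, z)
    iu = np.triu_indices(len(v), k=1)
    return edges[iu]
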