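"""Feature-derivation oracles: hand-computed and brute-force checks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mmstack import features as ft


# ------------------------------------------------------------- model-free FC

def _series_with_exact_correlation(r: float, t: int = 40):
    """Two zero-mean series whose sample correlation is exactly r."""
    rng = np.random.default_rng(0)
    u = rng.normal(size=t)
    v = rng.normal(size=t)
    u -= u.mean()
    v -= v.mean() + u @ v / (u @ u) * u  # orthogonalise v against u
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    return np.vstack([u, r * u + np.sqrt(1 - r ** 2) * v])


def test_fisher_z_of_exact_half_correlation():
    ts = _series_with_exact_correlation(0.5)
    z = ft.model_free_fc(ts)
    assert z.shape == (1,)
    assert abs(z[0] - np.arctanh(0.5)) < 1e-10  # 0.5493...


def test_duplicated_region_is_clamped_finite():
    rng = np.random.default_rng(1)
    row = rng.normal(size=100)
    z = ft.model_free_fc(np.vstack([row, row]))
    assert np.isfinite(z[0])
    assert abs(z[0] - np.arctanh(1 - 1e-7)) < 1e-9


def test_independent_noise_gives_near_zero_z():
    rng = np.random.default_rng(2)
    z = ft.model_free_fc(rng.normal(size=(2, 5000)))
    assert abs(z[0]) < 0.05


def test_constant_region_error_names_region():
    ts = np.vstack([np.ones(50), np.random.default_rng(3).normal(size=50)])
    with pytest.raises(ft.DegenerateInputError, match="region 0"):
        ft.model_free_fc(ts)


def test_fc_invariant_to_regionwise_affine_rescaling():
    rng = np.random.default_rng(4)
    ts = rng.normal(size=(5, 200))
    scaled = ts * rng.uniform(0.5, 3.0, size=(5, 1)) + \
        rng.normal(size=(5, 1)) * 10
    np.testing.assert_allclose(ft.model_free_fc(ts),
                               ft.model_free_fc(scaled), atol=1e-10)


# ------------------------------------------------------------- AR(1)

def test_noiseless_ar_identity():
    x = 10 * np.cumprod(np.full(60, 0.9))[None, :]
    assert abs(ft.time_varying_fc(x)[0] - 0.9) < 1e-10


def test_var_parameter_recovery():
    rng = np.random.default_rng(5)
    a = np.array([[0.5, 0.2], [0.0, 0.4]])
    x = np.zeros((2, 6000))
    for t in range(1, 6000):
        x[:, t] = a @ x[:, t - 1] + rng.normal(size=2)
    ahat = ft.time_varying_fc(x).reshape(2, 2)
    assert np.max(np.abs(ahat - a)) < 0.05


def test_white_noise_gives_null_coefficients():
    rng = np.random.default_rng(6)
    ahat = ft.time_varying_fc(rng.normal(size=(3, 8000))).reshape(3, 3)
    assert np.max(np.abs(ahat)) < 0.05


def test_ar_estimator_error_shrinks_with_length():
    """Consistency: median recovery error decreases over T grid."""
    a = 0.6
    med_errs = []
    for t_len in (500, 2000, 8000):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.zeros(t_len)
            for t in range(1, t_len):
                x[t] = a * x[t - 1] + rng.normal()
            errs.append(abs(ft.time_varying_fc(x[None, :])[0] - a))
        med_errs.append(np.median(errs))
    assert med_errs[0] > med_errs[1] > med_errs[2]


def test_rank_deficient_design_advises_ridge():
    row = np.random.default_rng(7).normal(size=30)
    dup = np.vstack([row, row, row])  # identical regions: singular Gram
    with pytest.raises(ft.DegenerateInputError, match="ridge"):
        ft.time_varying_fc(dup)
    out = ft.time_varying_fc(dup, ridge=1e-6)
    assert np.all(np.isfinite(out))


# ------------------------------------------------------------- graph metrics

def brute_force_path_metrics(w: np.ndarray):
    """All-pairs shortest paths by exhaustive path enumeration (<= 8 nodes)."""
    n = w.shape[0]
    best = np.full((n, n), np.inf)
    nodes = range(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            for k in range(n - 1):
                for mid in itertools.permutations(
                        [m for m in nodes if m not in (i, j)], k):
                    path = (i, *mid, j)
                    ok = all(w[a, b] > 0 for a, b in zip(path, path[1:]))
                    if ok:
                        length = sum(1.0 / w[a, b]
                                     for a, b in zip(path, path[1:]))
                        best[i, j] = min(best[i, j], length)
    finite = np.isfinite(best[~np.eye(n, dtype=bool)])
    offdiag = best[~np.eye(n, dtype=bool)]
    cpl = offdiag[np.isfinite(offdiag)].mean()
    geff = np.mean(np.where(np.isfinite(offdiag), 1.0 / offdiag, 0.0))
    return cpl, geff


def brute_force_modularity(w: np.ndarray):
    """Global maximum modularity by exhaustive partition search."""
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)

    def modularity(labels):
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += w[i, j] - k[i] * k[j] / two_m
        return q / two_m

    best = -np.inf
    # restricted-growth strings enumerate all set partitions
    def rec(labels, mx):
        nonlocal best
        if len(labels) == n:
            best = max(best, modularity(labels))
            return
        for c in range(mx + 2):
            rec(labels + [c], max(mx, c))
    rec([0], 0)
    return best


def test_chain_characteristic_path_length():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    stats = ft.network_statistics(w)
    assert abs(stats[0] - 4.0 / 3.0) < 1e-12


def test_single_community_participation_zero():
    w = np.ones((5, 5)) - np.eye(5)
    stats = ft.network_statistics(w)
    part = stats[3:]
    np.testing.assert_allclose(part, 0.0, atol=1e-12)


def test_two_clique_modularity_matches_exhaustive_search():
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    w[3, 4] = w[4, 3] = 0.1
    q = ft.network_statistics(w)[2]
    assert abs(q - brute_force_modularity(w)) < 1e-10


def test_random_small_graphs_match_brute_force():
    """Path metrics and modularity vs exhaustive oracles, several seeds."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        w = rng.uniform(-0.3, 1.0, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        wc = np.where(w > 0, w, 0.0)
        if not np.any(wc > 0):
            continue
        stats = ft.network_statistics(w, seed=seed)
        cpl, geff = brute_force_path_metrics(wc)
        assert abs(stats[0] - cpl) < 1e-10
        assert abs(stats[1] - geff) < 1e-10
        assert abs(stats[2] - brute_force_modularity(wc)) < 1e-10


def test_all_negative_graph_refused():
    w = -np.ones((4, 4))
    with pytest.raises(ft.DegenerateInputError):
        ft.network_statistics(w)


def test_absolute_value_mode_differs():
    rng = np.random.default_rng(8)
    w = rng.uniform(-1, 1, size=(6, 6))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    s_zero = ft.network_statistics(w, negative_mode="zero")
    s_abs = ft.network_statistics(w, negative_mode="abs")
    assert not np.allclose(s_zero[:2], s_abs[:2])


# ------------------------------------------------------------- gradients

def _two_block_fc(r: int = 10, within: float = 0.9, across: float = 0.2):
    fc = np.full((r, r), across)
    h = r // 2
    fc[:h, :h] = within
    fc[h:, h:] = within
    np.fill_diagonal(fc, 1.0)
    return fc


def test_first_gradient_separates_two_blocks():
    fc = _two_block_fc()
    tpl = ft.gradient_fit(fc, components=3, sparsity_quantile=0.5)
    g1 = tpl.loadings[:, 0]
    assert len(set(np.sign(g1[:5]))) == 1
    assert len(set(np.sign(g1[5:]))) == 1
    assert np.sign(g1[0]) != np.sign(g1[5])


def test_flat_spectrum_warns_but_returns():
    fc = np.eye(8) + 1e-6
    with pytest.warns(RuntimeWarning, match="flat"):
        tpl = ft.gradient_fit(fc, components=3, sparsity_quantile=0.0)
    assert tpl.eigenvalues.shape == (3,)


def test_gradient_refit_is_deterministic():
    fc = _two_block_fc()
    t1 = ft.gradient_fit(fc, components=4, sparsity_quantile=0.5)
    t2 = ft.gradient_fit(fc, components=4, sparsity_quantile=0.5)
    np.testing.assert_array_equal(t1.loadings, t2.loadings)


def test_projection_of_training_mean_reproduces_loadings():
    fc = _two_block_fc()
    tpl = ft.gradient_fit(fc, components=4, sparsity_quantile=0.5)
    proj = ft.gradient_project(fc, tpl)
    expected = tpl.loadings.reshape(-1, order="F")
    np.testing.assert_allclose(proj, expected, atol=1e-6)


def test_identical_subjects_get_identical_loadings():
    fc = _two_block_fc()
    tpl = ft.gradient_fit(fc, components=3, sparsity_quantile=0.5)
    rng = np.random.default_rng(9)
    sub = np.clip(fc + 0.05 * rng.normal(size=fc.shape), -1, 1)
    sub = (sub + sub.T) / 2
    np.fill_diagonal(sub, 1.0)
    np.testing.assert_array_equal(ft.gradient_project(sub, tpl),
                                  ft.gradient_project(sub.copy(), tpl))


def test_projection_is_continuous_in_perturbation():
    fc = _two_block_fc()
    tpl = ft.gradient_fit(fc, components=3, sparsity_quantile=0.5)
    base = ft.gradient_project(fc, tpl)
    errs = []
    for eps in (1e-4, 1e-3, 1e-2):
        pert = fc + eps * np.ones_like(fc)
        np.fill_diagonal(pert, 1.0)
        errs.append(np.max(np.abs(ft.gradient_project(pert, tpl) - base)))
    assert errs[0] < errs[1] < errs[2]
    assert errs[0] < 1e-2


def test_gradient_region_mismatch_and_disconnected():
    fc = _two_block_fc()
    tpl = ft.gradient_fit(fc, components=3, sparsity_quantile=0.5)
    with pytest.raises(ValueError, match="mismatch"):
        ft.gradient_project(np.eye(6), tpl)
    disconnected = _two_block_fc(within=0.9, across=0.0)
    with pytest.raises(ft.DegenerateInputError, match="disconnected"):
        ft.gradient_fit(disconnected, components=3, sparsity_quantile=0.9)


# ------------------------------------------------------------- morphometry

def test_morphometry_normalisation_formulas():
    np.testing.assert_allclose(
        ft.normalize_morphometry(np.array([100.0]), 1000.0, "SA"), [1.0])
    np.testing.assert_allclose(
        ft.normalize_morphometry(np.array([3.0, 6.0]), 2.0, "GMV"),
        [1.5, 3.0])
    np.testing.assert_allclose(
        ft.normalize_morphometry(np.array([2.0, 4.0]), 999.0, "CT"),
        [2.0 / 3.0, 4.0 / 3.0])


def test_morphometry_constant_ct_and_identity_gmv():
    np.testing.assert_allclose(
        ft.normalize_morphometry(np.full(4, 2.5), 1.0, "CT"), np.ones(4))
    v = np.array([1.0, 2.0])
    np.testing.assert_array_equal(
        ft.normalize_morphometry(v, 1.0, "GMV"), v)
    with pytest.raises(ValueError):
        ft.normalize_morphometry(v, -1.0, "SA")


def test_morphcov_centering_and_correlation_identity():
    rng = np.random.default_rng(10)
    train = rng.normal(size=(30, 4))
    train[:, 1] = train[:, 0] * 2 + 3          # perfectly correlated pair
    model = ft.morphcov_fit(train)
    # subject at the training mean -> all edges zero
    np.testing.assert_allclose(ft.morphcov_apply(model.mean, model), 0.0,
                               atol=1e-12)
    # mean subject edge equals training correlation up to (n-1)/n
    n = train.shape[0]
    edges = np.stack([ft.morphcov_apply(row, model) for row in train])
    corr = np.corrcoef(train.T)
    iu = np.triu_indices(4, k=1)
    np.testing.assert_allclose(edges.mean(axis=0),
                               corr[iu] * (n - 1) / n, atol=1e-10)


def test_morphcov_apply_before_fit_and_degenerate_region():
    with pytest.raises(ValueError, match="fit"):
        ft.morphcov_apply(np.ones(3), None)
    train = np.random.default_rng(11).normal(size=(10, 3))
    train[:, 2] = 5.0                           # zero-variance region
    with pytest.warns(RuntimeWarning, match="zero training variance"):
        model = ft.morphcov_fit(train)
    edges = ft.morphcov_apply(train[0], model)
    assert edges[1] == 0.0 and edges[2] == 0.0  # edges (0,2), (1,2)


# ------------------------------------------------------------- fold-wise

def test_foldwise_blocks_fit_on_training_rows_only():
    """Mutating test-subject data must not change training-row features."""
    rng = np.random.default_rng(12)
    n, r = 20, 8
    fcs = np.zeros((n, r, r))
    for i in range(n):
        a = rng.normal(size=(r, 60))
        fcs[i] = np.corrcoef(a)
    train, test = np.arange(12), np.arange(12, 20)
    gb = ft.gradient_foldwise_block("grad", fcs, components=3,
                                    sparsity_quantile=0.5)
    x_tr1, _ = gb.build(train, test)
    fcs_mut = fcs.copy()
    fcs_mut[test] = np.corrcoef(rng.normal(size=(r, 60)))
    gb2 = ft.gradient_foldwise_block("grad", fcs_mut, components=3,
                                     sparsity_quantile=0.5)
    x_tr2, _ = gb2.build(train, test)
    np.testing.assert_array_equal(x_tr1, x_tr2)

    measures = rng.normal(size=(n, 6))
    mb = ft.morphcov_foldwise_block("mcov", measures)
    m_tr1, _ = mb.build(train, test)
    measures_mut = measures.copy()
    measures_mut[test] += 99.0
    m_tr2, _ = ft.morphcov_foldwise_block("mcov", measures_mut).build(
        train, test)
    np.testing.assert_array_equal(m_tr1, m_tr2)
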