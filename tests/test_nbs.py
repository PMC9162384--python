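import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmnbs import (ExtendedNBS, binarize, components, edgewise_stats,
                   permutation_test, pooled_ttest, threshold_sweep)
from mmnbs.nbs import DifferenceNetwork, _max_component_size


def _oracle_components_exhaustive(adj):
    """Components via exhaustive subset enumeration (feasible for <= 8 nodes)."""
    n = adj.shape[0]
    nodes = list(range(n))

    def connected(subset):
        if len(subset) == 1:
            return True
        seen = {subset[0]}
        frontier = [subset[0]]
        sset = set(subset)
        while frontier:
            u = frontier.pop()
            for v in sset - seen:
                if adj[u, v]:
                    seen.add(v)
                    frontier.append(v)
        return seen == sset

    comps = []
    for size in range(n, 0, -1):
        for subset in itertools.combinations(nodes, size):
            if any(set(subset) <= set(c) for c in comps):
                continue
            if connected(subset):
                comps.append(subset)
    # keep only components with at least one edge
    with_edge = [c for c in comps
                 if any(adj[i, j] for i in c for j in c if i < j)]
    return sorted((tuple(sorted(c)) for c in with_edge),
                  key=lambda c: (-len(c), c[0]))


def _oracle_components_dfs(adj):
    n = adj.shape[0]
    seen = np.zeros(n, bool)
    out = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        if len(comp) > 1 or adj[start, start]:
            if any(adj[i, j] for i in comp for j in comp if i < j):
                out.append(tuple(sorted(comp)))
    return sorted(out, key=lambda c: (-len(c), c[0]))


def _random_adj(n, p, rng):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


def test_edgewise_stats_matches_pooled_t(rng):
    mats = rng.standard_normal((10, 5, 5))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    y = np.array([1] * 5 + [0] * 5)
    diff = edgewise_stats(mats, y)
    iu = np.triu_indices(5, 1)
    t_ref, p_ref = pooled_ttest(mats[y == 1][:, iu[0], iu[1]],
                                mats[y == 0][:, iu[0], iu[1]])
    assert np.allclose(diff.t[iu], t_ref)
    assert np.allclose(diff.p[iu], p_ref)
    assert np.allclose(diff.t, diff.t.T) and np.allclose(diff.p, diff.p.T)
    assert np.all(np.diag(diff.p) == 1.0)


def test_binarize_strict_threshold():
    p = np.ones((3, 3))
    p[0, 1] = p[1, 0] = 0.001  # exactly at threshold: excluded
    p[1, 2] = p[2, 1] = 0.0009
    diff = DifferenceNetwork(np.zeros((3, 3)), p, ["a", "b", "c"])
    adj = binarize(diff, 0.001)
    assert not adj[0, 1]
    assert adj[1, 2] and adj[2, 1]
    assert not adj.diagonal().any()
    with pytest.raises(ValueError):
        binarize(diff, 0.0)


def test_components_simple_graph():
    adj = np.zeros((6, 6), bool)
    for i, j in [(0, 1), (1, 2), (4, 5)]:
        adj[i, j] = adj[j, i] = True
    t = np.zeros((6, 6))
    t[0, 1] = t[1, 0] = 2.5
    t[1, 2] = t[2, 1] = -3.0
    t[4, 5] = t[5, 4] = 1.0
    comps = components(adj, t)
    assert [c.nodes for c in comps] == [(0, 1, 2), (4, 5)]
    assert comps[0].size == 3
    signs = {(i, j): s for i, j, s, _ in comps[0].edges}
    assert signs == {(0, 1): 1, (1, 2): -1}


def test_components_rejects_asymmetric():
    adj = np.zeros((3, 3), bool)
    adj[0, 1] = True
    with pytest.raises(ValueError, match="symmetric"):
        components(adj)


def test_components_match_exhaustive_small(rng):
    for n in range(2, 6):
        n_edges = n * (n - 1) // 2
        iu = np.triu_indices(n, 1)
        for bits in range(2 ** n_edges):
            adj = np.zeros((n, n), bool)
            mask = [(bits >> k) & 1 for k in range(n_edges)]
            adj[iu] = np.array(mask, bool)
            adj = adj | adj.T
            got = [c.nodes for c in components(adj)]
            assert got == _oracle_components_exhaustive(adj)


def test_components_match_exhaustive_sampled(rng):
    for n in (6, 7, 8):
        for _ in range(100):
            adj = _random_adj(n, rng.uniform(0.05, 0.6), rng)
            got = [c.nodes for c in components(adj)]
            assert got == _oracle_components_exhaustive(adj)


def test_components_match_dfs_large(rng):
    for _ in range(20):
        adj = _random_adj(116, 0.01, rng)
        got = [c.nodes for c in components(adj)]
        assert got == _oracle_components_dfs(adj)
        iu = np.triu_indices(116, 1)
        sel = adj[iu]
        mx = _max_component_size(iu[0][sel], iu[1][sel], 116)
        assert mx == (max(len(c) for c in got) if got else 0)


def test_empirical_p_arithmetic():
    # 100 of 5000 null maxima strictly exceed the observed size -> p = 0.02
    null = np.r_[np.full(100, 10), np.full(4900, 2)].astype(int)
    s = 5
    p_strict = (null > s).sum() / 5000
    assert p_strict == 0.02
    p_plus = ((null >= s).sum() + 1) / 5001
    assert p_plus == pytest.approx(101 / 5001)


def test_permutation_test_planted(small_cohort):
    res = permutation_test(small_cohort.fc, small_cohort.y, threshold=0.01,
                           n_perm=500, seed=1)
    assert res.n_perm == 500
    assert len(res.null_max_sizes) == 500
    assert all(0.0 <= p <= 1.0 for p in res.component_pvalues)
    # planted edges (2,10),(3,10) should appear in some component
    planted = {2, 3, 10}
    assert any(planted <= set(c.nodes) for c in res.components)


def test_permutation_test_determinism(small_cohort):
    a = permutation_test(small_cohort.fc, small_cohort.y, n_perm=100, seed=7)
    b = permutation_test(small_cohort.fc, small_cohort.y, n_perm=100, seed=7)
    assert np.array_equal(a.null_max_sizes, b.null_max_sizes)
    assert np.array_equal(a.component_pvalues, b.component_pvalues)
    c = permutation_test(small_cohort.fc, small_cohort.y, n_perm=100, seed=8)
    assert not np.array_equal(a.null_max_sizes, c.null_max_sizes)


def test_permutation_null_matches_direct_recomputation(small_cohort):
    """Dual route: the BLAS permutation internals must equal re-running the
    full edgewise_stats -> binarize -> components chain per permutation."""
    fc, y = small_cohort.fc, small_cohort.y
    n_perm, seed, thr = 25, 3, 0.01
    res = permutation_test(fc, y, threshold=thr, n_perm=n_perm, seed=seed)
    rng = np.random.default_rng(seed)
    g0 = (y == 1).astype(float)
    for k in range(n_perm):
        g = rng.permutation(g0)
        diff = edgewise_stats(fc, g.astype(int))
        comps = components(binarize(diff, thr))
        expect = max((c.size for c in comps), default=0)
        assert res.null_max_sizes[k] == expect


def test_threshold_sweep_shared_permutations(small_cohort):
    sweep = threshold_sweep(small_cohort.fc, small_cohort.y,
                            thresholds=[0.001, 0.01, 0.05], n_perm=50, seed=2)
    assert [r.threshold for r in sweep] == [0.001, 0.01, 0.05]
    # same label sequence: per permutation the max size is monotone in the
    # threshold (larger threshold admits a superset of edges)
    m1, m2, m3 = (r.null_max_sizes for r in sweep)
    assert np.all(m1 <= m2) and np.all(m2 <= m3)
    # sweep result at a threshold equals the single-threshold run
    single = permutation_test(small_cohort.fc, small_cohort.y, threshold=0.01,
                              n_perm=50, seed=2)
    assert np.array_equal(single.null_max_sizes, m2)


def test_sweep_validation(small_cohort):
    with pytest.raises(ValueError, match="strictly increasing"):
        threshold_sweep(small_cohort.fc, small_cohort.y,
                        thresholds=[0.01, 0.001], n_perm=10)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(small_cohort.fc, small_cohort.y, n_perm=0)
    with pytest.warns(UserWarning, match="coarse"):
        permutation_test(small_cohort.fc, small_cohort.y, n_perm=10, seed=0)


def test_estimator_interface(small_cohort):
    est = ExtendedNBS(threshold=0.01, n_perm=50, random_state=5)
    est.fit(small_cohort.fc, small_cohort.y)
    assert est.result_.threshold == 0.01
    assert len(est.null_max_sizes_) == 50
    assert est.components_ == est.result_.components
    assert est.difference_network_.t.shape == (12, 12)
    params = est.get_params()
    assert params["n_perm"] == 50 and params["random_state"] == 5


def test_result_serialization(small_cohort):
    res = permutation_test(small_cohort.fc, small_cohort.y, threshold=0.01,
                           n_perm=50, seed=1)
    d = res.to_dict()
    import json

    blob = json.dumps(d)
    assert json.loads(blob)["n_perm"] == 50
    for comp_d, comp in zip(d["components"], res.components):
        assert comp_d["size"] == comp.size
        assert comp_d["nodes"] == list(comp.nodes)


@settings(max_examples=5)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_plus_one_estimator_bounds(seed):
    """Property: plus-one empirical p is always > 0 and >= the strict one."""
    rng = np.random.default_rng(seed)
    mats = rng.standard_normal((12, 8, 8))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    y = np.array([1] * 6 + [0] * 6)
    strict = permutation_test(mats, y, threshold=0.05, n_perm=40, seed=seed)
    plus = permutation_test(mats, y, threshold=0.05, n_perm=40, seed=seed,
                            plus_one=True)
    assert len(strict.components) == len(plus.components)
    for ps, pp in zip(strict.component_pvalues, plus.component_pvalues):
        assert pp > 0.0
        assert pp >= ps - 1e-12
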