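"""Extended network-based statistics for group differences in connectivity.

The procedure: a two-sided pooled-variance t-test per edge across subjects
(positive t = stronger connectivity in patients) gives a symmetric p-value
"difference network"; edges with p strictly below a pre-defined threshold form
a binary difference network; its connected components (maximal connected
subgraphs with at least one edge, sized by the number of member regions) are
the candidate effects.  Significance comes from a permutation null: group
labels are shuffled (group sizes preserved), the full chain is re-run, and the
maximal component size per permutation is stored.  The empirical p-value of an
observed component of size s is

    Emp_pval = #{permutations whose maximal component size > s} / n_perm

with a strict inequality and without adding the observed labeling to the null;
a component is declared significant when Emp_pval < alpha (default 0.05).
``plus_one=True`` switches to the standard conservative estimator
(#{>= s} + 1) / (n_perm + 1); it is off by default to match the formula above,
but note the strict estimator is anticonservative when the null distribution
of the maximal size is concentrated on small values (see docs/methods.md).

Edge signs (increased/decreased in patients) are annotation only: components
are formed ignoring sign and may mix both directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _csgraph_components
from sklearn.base import BaseEstimator

from .group_stats import pooled_ttest

__all__ = [
    "DifferenceNetwork",
    "Component",
    "NBSResult",
    "ExtendedNBS",
    "edgewise_stats",
    "binarize",
    "components",
    "permutation_test",
    "threshold_sweep",
]


@dataclass
class DifferenceNetwork:
    """Symmetric edgewise t and p matrices (diagonal excluded from analysis)."""

    t: np.ndarray
    p: np.ndarray
    region_labels: list[str]


@dataclass
class Component:
    """A connected component of the binary difference network.

    ``edges`` holds (i, j, sign, t) with sign +1 for connectivity increased in
    patients and -1 for decreased; ``size`` is the number of member regions.
    """

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int, int, float], ...]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class NBSResult:
    threshold: float
    components: list[Component]
    component_pvalues: np.ndarray
    null_max_sizes: np.ndarray
    n_perm: int
    seed: int | None
    alpha: float
    plus_one: bool
    region_labels: list[str]

    @property
    def significant(self) -> list[int]:
        """Indices of components with empirical p strictly below alpha."""
        return [i for i, p in enumerate(self.component_pvalues) if p < self.alpha]

    def significant_components(self) -> list[Component]:
        return [self.components[i] for i in self.significant]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "plus_one": self.plus_one,
            "region_labels": list(self.region_labels),
            "components": [
                {
                    "nodes": list(c.nodes),
                    "node_labels": [self.region_labels[i] for i in c.nodes],
                    "edges": [
                        {"i": i, "j": j, "sign": s, "t": t} for i, j, s, t in c.edges
                    ],
                    "size": c.size,
                    "empirical_p": float(p),
                    "significant": bool(p < self.alpha),
                }
                for c, p in zip(self.components, self.component_pvalues)
            ],
            "null_max_sizes": self.null_max_sizes.astype(int).tolist(),
        }


def _edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_regions, k=1)


def _stack_edges(matrices: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    matrices = np.asarray(matrices, float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("matrices must be a subjects x R x R stack")
    iu = _edge_index(matrices.shape[1])
    return matrices[:, iu[0], iu[1]], iu


def edgewise_stats(matrices: np.ndarray, y, region_labels=None) -> DifferenceNetwork:
    """Two-sided pooled t-test per edge (patients minus controls)."""
    X, iu = _stack_edges(matrices)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("number of matrices must match number of labels")
    pat, ctl = X[y == 1], X[y == 0]
    t, p = pooled_ttest(pat, ctl)
    R = matrices.shape[1]
    tm = np.zeros((R, R))
    pm = np.ones((R, R))
    tm[iu], pm[iu] = t, p
    tm += tm.T
    pm[iu[1], iu[0]] = p
    np.fill_diagonal(pm, 1.0)
    if region_labels is None:
        region_labels = [f"R{i + 1:03d}" for i in range(R)]
    return DifferenceNetwork(tm, pm, list(region_labels))


def binarize(diff: DifferenceNetwork, threshold: float) -> np.ndarray:
    """Binary adjacency: edge present iff raw p is strictly below threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    adj = diff.p < threshold
    np.fill_diagonal(adj, False)
    return adj & adj.T


def components(adj: np.ndarray, t_matrix: np.ndarray | None = None) -> list[Component]:
    """Connected components (>= 1 edge) of a binary adjacency matrix.

    Isolated nodes are not components.  Output is sorted by size descending,
    ties broken by smallest member node index.
    """
    adj = np.asarray(adj, bool)
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    rows, cols = np.nonzero(np.triu(adj, k=1))
    if len(rows) == 0:
        return []
    nodes = np.unique(np.concatenate([rows, cols]))
    remap = {int(v): k for k, v in enumerate(nodes)}
    sub = sparse.csr_matrix(
        (np.ones(len(rows)), ([remap[int(r)] for r in rows],
                              [remap[int(c)] for c in cols])),
        shape=(len(nodes), len(nodes)),
    )
    _, labels = _csgraph_components(sub + sub.T, directed=False)
    comps: list[Component] = []
    for lab in np.unique(labels):
        members = tuple(int(v) for v in nodes[labels == lab])
        member_set = set(members)
        edges = []
        for r, c in zip(rows, cols):
            if int(r) in member_set:
                tval = float(t_matrix[r, c]) if t_matrix is not None else 0.0
                sign = 1 if tval > 0 else (-1 if tval < 0 else 0)
                edges.append((int(r), int(c), sign, tval))
        comps.append(Component(nodes=members, edges=tuple(edges)))
    comps.sort(key=lambda c: (-c.size, c.nodes[0]))
    return comps


def _max_component_size(rows: np.ndarray, cols: np.ndarray, n_regions: int) -> int:
    if len(rows) == 0:
        return 0
    nodes, inv = np.unique(np.concatenate([rows, cols]), return_inverse=True)
    half = len(rows)
    sub = sparse.csr_matrix(
        (np.ones(half), (inv[:half], inv[half:])), shape=(len(nodes), len(nodes))
    )
    _, labels = _csgraph_components(sub + sub.T, directed=False)
    return int(np.bincount(labels).max())


def _group_t(X: np.ndarray, Xsq: np.ndarray, total: np.ndarray, total_sq: np.ndarray,
             g: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pooled t for all edges given a 0/1 patient indicator (BLAS formulation)."""
    s1 = g @ X
    q1 = g @ Xsq
    s2 = total - s1
    q2 = total_sq - q1
    v1 = (q1 - s1 * s1 / n1) / (n1 - 1)
    v2 = (q2 - s2 * s2 / n2) / (n2 - 1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(np.clip(sp, 0.0, None) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (s1 / n1 - s2 / n2) / denom
    return np.where(denom == 0, 0.0, t)


class ExtendedNBS(BaseEstimator):
    """Permutation test for connected components of a group-difference network.

    Parameters
    ----------
    threshold : float
        Edgewise raw-p threshold defining the binary difference network.
    n_perm : int
        Number of label permutations (5000 by default).
    alpha : float
        Empirical-p level for declaring a component significant (strict <).
    plus_one : bool
        Use the conservative (#{null >= s} + 1) / (n_perm + 1) estimator
        instead of the default strict #{null > s} / n_perm.
    random_state : int or None
        Seed for the permutation stream.

    Attributes (after ``fit``)
    --------------------------
    difference_network_ : DifferenceNetwork
    components_ : list[Component]
    component_pvalues_ : ndarray
    null_max_sizes_ : ndarray of length ``n_perm``
    result_ : NBSResult
    """

    def __init__(self, threshold: float = 0.001, n_perm: int = 5000,
                 alpha: float = 0.05, plus_one: bool = False,
                 random_state: int | None = None):
        self.threshold = threshold
        self.n_perm = n_perm
        self.alpha = alpha
        self.plus_one = plus_one
        self.random_state = random_state

    def fit(self, X, y, region_labels=None):
        results = _sweep(
            np.asarray(X, float), np.asarray(y), [self.threshold], self.n_perm,
            self.random_state, self.alpha, self.plus_one, region_labels,
        )
        result = results[0]
        self.result_ = result
        self.difference_network_ = result._difference_network
        self.components_ = result.components
        self.component_pvalues_ = result.component_pvalues
        self.null_max_sizes_ = result.null_max_sizes
        return self


def _sweep(matrices, y, thresholds, n_perm, seed, alpha, plus_one,
           region_labels=None, estimator: ExtendedNBS | None = None):
    thresholds = list(thresholds)
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if sorted(thresholds) != thresholds or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20 / alpha:
        warnings.warn(
            f"n_perm={n_perm} gives coarse empirical-p resolution at alpha={alpha}",
            stacklevel=2,
        )
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n2 = int((y == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")

    diff = edgewise_stats(matrices, y, region_labels)
    X, iu = _stack_edges(matrices)
    Xsq = X * X
    total = X.sum(axis=0)
    total_sq = Xsq.sum(axis=0)
    df = n1 + n2 - 2
    t_crit = {thr: float(stats.t.isf(thr / 2.0, df)) for thr in thresholds}

    rng = np.random.default_rng(seed)
    g0 = (y == 1).astype(float)
    null = {thr: np.empty(n_perm, dtype=int) for thr in thresholds}
    for k in range(n_perm):
        g = rng.permutation(g0)
        t_edges = np.abs(_group_t(X, Xsq, total, total_sq, g, n1, n2))
        for thr in thresholds:
            sel = t_edges > t_crit[thr]
            null[thr][k] = _max_component_size(iu[0][sel], iu[1][sel],
                                               matrices.shape[1])

    results = []
    for thr in thresholds:
        adj = binarize(diff, thr)
        comps = components(adj, diff.t)
        sizes = np.array([c.size for c in comps])
        if plus_one:
            pvals = np.array(
                [((null[thr] >= s).sum() + 1) / (n_perm + 1) for s in sizes]
            )
        else:
            pvals = np.array([(null[thr] > s).sum() / n_perm for s in sizes])
        results.append(
            NBSResult(
                threshold=thr,
                components=comps,
                component_pvalues=pvals,
                null_max_sizes=null[thr],
                n_perm=n_perm,
                seed=seed,
                alpha=alpha,
                plus_one=plus_one,
                region_labels=diff.region_labels,
            )
        )
    _sweep_attach_diff(results, diff)
    return results


def _sweep_attach_diff(results, diff):
    for r in results:
        r._difference_network = diff


def permutation_test(matrices, y, threshold: float = 0.001, n_perm: int = 5000,
                     seed: int | None = None, alpha: float = 0.05,
                     plus_one: bool = False, region_labels=None) -> NBSResult:
    """One-threshold extended-NBS run (see :class:`ExtendedNBS`)."""
    results = _sweep(np.asarray(matrices, float), np.asarray(y), [threshold],
                     n_perm, seed, alpha, plus_one, region_labels)
    return results[0]


def threshold_sweep(matrices, y, thresholds=None, n_perm: int = 5000,
                    seed: int | None = None, alpha: float = 0.05,
                    plus_one: bool = False, region_labels=None) -> list[NBSResult]:
    """Run the procedure over a strictly increasing list of p thresholds.

    The default sweep is 0.0001 to 0.0010 in steps of 0.0001.  All thresholds
    share the identical sequence of shuffled labels (same seed), so the nulls
    are directly comparable across thresholds.
    """
    if thresholds is None:
        thresholds = [round(0.0001 * k, 4) for k in range(1, 11)]
    return _sweep(np.asarray(matrices, float), np.asarray(y), list(thresholds),
                  n_perm, seed, alpha, plus_one, region_labels)
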