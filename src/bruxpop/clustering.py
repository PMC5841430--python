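"""Tree building, ordination and cluster selection on genetic distance matrices.

Provides neighbour joining (unrooted, with the standard clamp-and-transfer
rule for negative branch estimates), UPGMA (average-linkage, ultrametric),
classical metric MDS (Torgerson double centering), successive-K-means cluster
number selection in the style of DAPC's ``find.clusters``, and a
partition-style node reliability score: a clade is reliable when its members
are more closely related than random sets of leaves of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .bruvo import DistanceMatrix

__all__ = [
    "ClusterAssignment",
    "nj",
    "upgma",
    "classical_mds",
    "find_clusters",
    "partition_reliability",
    "tree_leaf_partition",
]


def _new_taxa(ids: list[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace(ids)


def nj(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbour joining from a complete distance matrix.

    Uses the Q-criterion; negative branch-length estimates are clamped to
    zero with the deficit transferred to the sister branch, so path lengths
    between leaves are preserved.  On additive input distances the tree
    reproduces them exactly.  The result is unrooted (trifurcating seed node).
    """
    n = D.n
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    if not np.isfinite(D.d).all():
        raise ValueError("incomplete distance matrix")
    taxa = _new_taxa(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for tax in taxa:
        nd = dendropy.Node(taxon=tax)
        nodes.append(nd)
    d = D.d.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negative estimates, transferring the deficit to the sister
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ci, cj = node_of[i], node_of[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        # distances from the new node to the remaining nodes
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        active = [k for k in active if k not in (i, j)] + [new]
        node_of[new] = parent

    # resolve the final three nodes around an unrooted centre
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    centre = tree.seed_node
    for k, lk in ((a, la), (b, lb), (c, lc)):
        centre.add_child(node_of[k])
        node_of[k].edge.length = max(lk, 0.0)
    tree.is_rooted = False
    return tree


def upgma(D: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; returns a rooted ultrametric tree."""
    n = D.n
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    if not np.isfinite(D.d).all():
        raise ValueError("incomplete distance matrix")
    taxa = _new_taxa(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    Z = linkage(D.condensed(), method="average")
    height = {}
    node_of = {}
    for i, tax in enumerate(taxa):
        nd = dendropy.Node(taxon=tax)
        node_of[i] = nd
        height[i] = 0.0
    for step, (a, b, dist, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        parent = dendropy.Node()
        h = dist / 2.0
        for child in (a, b):
            parent.add_child(node_of[child])
            node_of[child].edge.length = max(h - height[child], 0.0)
        idx = n + step
        node_of[idx] = parent
        height[idx] = h
    root = node_of[2 * n - 2]
    for child in list(root.child_nodes()):
        root.remove_child(child)
    # graft onto the dendropy seed node to keep the taxon namespace binding
    seed = tree.seed_node
    for child in (int(Z[-1, 0]), int(Z[-1, 1])):
        seed.add_child(node_of[child])
        node_of[child].edge.length = max(height[2 * n - 2] - height[child], 0.0)
    tree.is_rooted = True
    return tree


def classical_mds(D: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Torgerson/Gower metric scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns the
    top-``k`` coordinates scaled by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean input) are dropped with a warning; if fewer than ``k``
    positive eigenvalues exist, the embedding is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.n
    d2 = D.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-12
    if (vals < -tol).any():
        warnings.warn("non-Euclidean distances: negative eigenvalues dropped")
    npos = int((vals > tol).sum())
    if npos < k:
        warnings.warn(f"only {npos} positive eigenvalues; embedding reduced to {npos}")
        k = max(npos, 1)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    return coords


def mds_variance_coords(D: DistanceMatrix, var_frac: float = 0.95) -> np.ndarray:
    """MDS coordinates keeping components explaining ``var_frac`` of the
    positive-eigenvalue variance (the input space for K-means)."""
    n = D.n
    coords = classical_mds(D, k=max(n - 1, 1))
    var = (coords ** 2).sum(axis=0)
    if var.sum() <= 0:
        return coords[:, :1]
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_frac) + 1)
    return coords[:, :k]


@dataclass
class ClusterAssignment:
    labels: dict[int, int]  # row index -> cluster label in 1..k
    k: int
    wss_curve: dict[int, float]

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[i] for i in range(len(self.labels))])


def _wss_curve(coords: np.ndarray, kmax: int, restarts: int, rng: np.random.Generator):
    wss = {}
    labels = {}
    for k in range(1, kmax + 1):
        if k == 1:
            centre = coords.mean(axis=0)
            wss[1] = float(((coords - centre) ** 2).sum())
            labels[1] = np.zeros(len(coords), dtype=int)
            continue
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            random_state=int(rng.integers(2 ** 31 - 1)),
        ).fit(coords)
        wss[k] = float(km.inertia_)
        labels[k] = km.labels_
    return wss, labels


def find_clusters(
    coords: np.ndarray,
    kmax: int = 8,
    restarts: int = 10,
    seed: int | None = None,
    tau: float = 0.05,
    null_reps: int = 5,
) -> ClusterAssignment:
    """Select the number of clusters by successive K-means.

    The WSS curve is computed for k = 1..kmax (best of ``restarts`` runs).
    A Gaussian-reference guard first checks whether the observed WSS decay
    is distinguishable from K-means on surrogate data drawn from a single
    Gaussian with the sample mean and covariance; if not, k = 1.  Otherwise
    the selected k is the smallest whose relative WSS drop
    (WSS(k) - WSS(k+1)) / WSS(1) falls below ``tau``.
    """
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    rng = np.random.default_rng(seed)
    wss, labels = _wss_curve(coords, kmax, restarts, rng)

    if wss[1] <= 1e-12:  # degenerate: all points identical
        return ClusterAssignment(
            labels={i: 1 for i in range(len(coords))}, k=1, wss_curve=wss
        )

    # Gaussian-reference guard for k = 1
    n, p = coords.shape
    mean = coords.mean(axis=0)
    cov = np.cov(coords, rowvar=False).reshape(p, p) + 1e-12 * np.eye(p)
    log_ratio = np.log(np.array([wss[k] for k in range(2, kmax + 1)]) / wss[1])
    ref = np.empty((null_reps, kmax - 1))
    for r in range(null_reps):
        sim = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        w, _ = _wss_curve(sim, kmax, max(restarts // 2, 2), rng)
        ref[r] = np.log(np.array([w[k] for k in range(2, kmax + 1)]) / w[1])
    gap = ref.mean(axis=0) - log_ratio  # >0 when data beats the Gaussian null
    se = ref.std(axis=0, ddof=1) / np.sqrt(null_reps) + 1e-9
    if not (gap > 2.0 * se + 0.05).any():
        return ClusterAssignment(
            labels={i: 1 for i in range(len(coords))}, k=1, wss_curve=wss
        )

    chosen = kmax
    for k in range(1, kmax):
        if (wss[k] - wss[k + 1]) / wss[1] < tau:
            chosen = k
            break
    lab = labels[chosen]
    return ClusterAssignment(
        labels={i: int(lab[i]) + 1 for i in range(len(coords))},
        k=chosen,
        wss_curve=wss,
    )


def tree_leaf_partition(tree: dendropy.Tree) -> dict[str, list[str]]:
    """Internal node id -> leaf taxon labels under that node."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        out[id(node)] = [lf.taxon.label for lf in node.leaf_iter()]
    return out


def partition_reliability(
    tree: dendropy.Tree,
    D: DistanceMatrix,
    R: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """Annotate internal nodes with a partition-style reliability score.

    For each internal node whose clade holds 2..N-1 leaves, the observed mean
    pairwise distance within the clade is compared with ``R`` random leaf
    subsets of the same size; reliability is the fraction of random subsets
    whose mean pairwise distance is strictly greater.  The score is stored as
    ``node.reliability`` (and as the node label for Newick export); clades
    with reliability > 0.90 are the ones the tree display retains.
    """
    if R < 100:
        raise ValueError("R must be >= 100")
    rng = np.random.default_rng(seed)
    idx = {name: i for i, name in enumerate(D.ids)}
    n = D.n
    d = D.d

    def mean_pairwise(rows: np.ndarray) -> float:
        sub = d[np.ix_(rows, rows)]
        m = len(rows)
        return float(sub.sum()) / (m * (m - 1))

    # null distributions shared across clades of equal size
    sizes = set()
    clades = []
    for node in tree.preorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(leaves) < n:
            clades.append((node, leaves))
            sizes.add(len(leaves))
        else:
            node.reliability = None
    null = {}
    for s in sizes:
        means = np.empty(R)
        for r in range(R):
            rows = rng.choice(n, size=s, replace=False)
            means[r] = mean_pairwise(rows)
        null[s] = means
    for node, leaves in clades:
        rows = np.array([idx[l] for l in leaves])
        obs = mean_pairwise(rows)
        rel = float((null[len(leaves)] > obs).mean())
        node.reliability = rel
        node.label = f"{rel:.3f}"
    return tree
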