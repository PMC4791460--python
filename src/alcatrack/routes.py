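"""Route similarity: nearest-neighbour distances, clustering, AU support.

The similarity of two foraging routes is the nearest-neighbour-analysis
(NNA) distance: the mean, over the points of one path, of the distance
to the nearest point of the other, symmetrised by averaging both
directions.  Trips are then clustered hierarchically on the Euclidean
distances between the rows of the NNA matrix (each trip represented by
its vector of NNA distances to all trips), and node support is
estimated with the approximately-unbiased (AU) multiscale bootstrap:
the feature coordinates are resampled at several sample-size scales,
per-node recovery probabilities are mapped through the normal quantile,
and the signed-distance/curvature model z(r) = v/sqrt(r) + c*sqrt(r)
gives AU = 1 - Phi(v - c), in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

log = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def nna_distance(path_a, path_b, symmetrize: bool = True,
                 min_fixes: int = 10) -> float:
    """Mean nearest-point distance between two planar paths, metres.

    d(A,B) = mean over points of A of the distance to the nearest point
    of B; symmetrised as (d(A,B) + d(B,A)) / 2.  Both paths must have at
    least ``min_fixes`` points (shorter paths carry too little shape).
    """
    a = np.asarray(path_a, dtype=float)
    b = np.asarray(path_b, dtype=float)
    if len(a) < min_fixes or len(b) < min_fixes:
        raise ValueError(f"paths need >= {min_fixes} fixes for the NNA")
    d_ab = float(cKDTree(b).query(a)[0].mean())
    if not symmetrize:
        return d_ab
    d_ba = float(cKDTree(a).query(b)[0].mean())
    return 0.5 * (d_ab + d_ba)


def nna_matrix(paths, labels=None, symmetrize: bool = True,
               min_fixes: int = 10):
    """Symmetric matrix of pairwise NNA distances over all paths.

    Returns ``(labels, D)``; trees built once per path.
    """
    n = len(paths)
    if labels is None:
        labels = [str(i) for i in range(n)]
    arrays = [np.asarray(p, dtype=float) for p in paths]
    for i, a in enumerate(arrays):
        if len(a) < min_fixes:
            raise ValueError(f"path {labels[i]!r} has {len(a)} < {min_fixes} fixes")
    trees = [cKDTree(a) for a in arrays]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_ij = trees[j].query(arrays[i])[0].mean()
            d_ji = trees[i].query(arrays[j])[0].mean()
            D[i, j] = D[j, i] = 0.5 * (d_ij + d_ji) if symmetrize else d_ij
    return list(labels), D


@dataclass
class ClusterTree:
    labels: list
    Z: np.ndarray                 # scipy linkage matrix
    nodes: dict                   # node id -> frozenset of leaf indices
    au: dict | None = None        # node id -> AU percent
    au_flags: dict | None = None  # node id -> "never_recovered" etc.

    def cut(self, k: int) -> np.ndarray:
        return fcluster(self.Z, t=k, criterion="maxclust")


def _linkage_nodes(Z: np.ndarray, n: int) -> dict:
    """Member leaf-sets of every internal node of a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    nodes = {}
    for k, (a, b, *_rest) in enumerate(Z):
        s = members[int(a)] | members[int(b)]
        members[n + k] = s
        nodes[n + k] = s
    return nodes


def cluster_tree(D: np.ndarray, labels=None, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering on Euclidean distances between NNA rows.

    Each trip is represented by its row of the NNA matrix; rows are
    compared with the Euclidean metric and merged with the given linkage
    (average/UPGMA by default).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    Z = scipy_linkage(pdist(D), method=linkage)
    return ClusterTree(labels=list(labels), Z=Z, nodes=_linkage_nodes(Z, n))


def _cluster_sets(Z: np.ndarray, n: int) -> set:
    members = {i: frozenset([i]) for i in range(n)}
    found = set()
    for k, row in enumerate(Z):
        s = members[int(row[0])] | members[int(row[1])]
        members[n + k] = s
        found.add(s)
    return found


def au_support(row_vectors: np.ndarray, n_boot: int = 1000,
               scale_factors=DEFAULT_SCALES, linkage: str = "average",
               seed=0, tree: ClusterTree | None = None):
    """Per-node AU support (percent) by multiscale bootstrap.

    ``row_vectors`` is the (n_objects, n_features) matrix whose rows are
    clustered — here each trip's vector of NNA distances.  For each
    scale r the n_features coordinates are resampled with replacement at
    size round(n*r), objects are reclustered, and each original node's
    recovery frequency recorded; z(r) = Phi^{-1}(1 - BP_r) is regressed
    (weighted by the binomial information) on [1/sqrt(r), sqrt(r)]
    giving the signed distance v and curvature c, and
    AU = 100 * (1 - Phi(v - c)).  Nodes never recovered at any scale get
    AU = 0 with a flag.
    """
    X = np.asarray(row_vectors, dtype=float)
    n_obj, n_feat = X.shape
    scales = np.asarray(scale_factors, dtype=float)
    if scales.size < 2 or not (np.any(scales < 1) and np.any(scales > 1)):
        raise ValueError("need >= 2 scale factors spanning values below and above 1")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = cluster_tree(X, linkage=linkage)
    target_nodes = {nid: s for nid, s in tree.nodes.items() if 1 < len(s) < n_obj}

    counts = {nid: np.zeros(scales.size, dtype=int) for nid in target_nodes}
    for si, r in enumerate(scales):
        m = max(2, int(round(n_feat * r)))
        for _ in range(n_boot):
            idx = rng.integers(0, n_feat, size=m)
            Zb = scipy_linkage(pdist(X[:, idx]), method=linkage)
            found = _cluster_sets(Zb, n_obj)
            for nid, s in target_nodes.items():
                if s in found:
                    counts[nid][si] += 1

    sqrt_r = np.sqrt(scales)
    design = np.column_stack([1.0 / sqrt_r, sqrt_r])
    au, flags = {}, {}
    eps = 0.5 / n_boot
    for nid, cnt in counts.items():
        if cnt.sum() == 0:
            au[nid] = 0.0
            flags[nid] = "never_recovered"
            continue
        if (cnt == n_boot).all():
            # recovery certain at every scale: the curve carries no
            # gradient information and the quantile regression is
            # ill-conditioned; support is at the resolution ceiling
            au[nid] = 100.0
            flags[nid] = "saturated"
            continue
        bp = np.clip(cnt / n_boot, eps, 1 - eps)
        z = norm.ppf(1.0 - bp)
        w = n_boot * norm.pdf(z) ** 2 / (bp * (1 - bp))  # binomial information
        W = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(design * W, z * np.sqrt(w), rcond=None)
        v, c = coef
        au[nid] = float(np.clip(100.0 * (1.0 - norm.cdf(v - c)), 0.0, 100.0))
        flags[nid] = "ok"
    tree.au, tree.au_flags = au, flags
    return au


def group_recovery(tree: ClusterTree, labels, k: int = 2) -> dict:
    """Fraction of each label's members in its plurality cluster at a k-cut."""
    labels = np.asarray(labels)
    assign = tree.cut(k)
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        clusters, cnt = np.unique(assign[mask], return_counts=True)
        out[lab] = float(cnt.max() / mask.sum())
    return out


def to_newick(tree: ClusterTree) -> str:
    """Newick export with AU support (percent) as internal-node comments."""
    n = len(tree.labels)
    Z = tree.Z
    def rec(node):
        if node < n:
            return str(tree.labels[node]).replace(",", "_").replace("(", "_").replace(")", "_")
        row = Z[node - n]
        left, right = rec(int(row[0])), rec(int(row[1]))
        au = "" if not tree.au or node not in tree.au else f"[&&NHX:AU={tree.au[node]:.1f}]"
        return f"({left},{right}){au}:{row[2]:.6g}"
    return rec(2 * n - 2) + ";"
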