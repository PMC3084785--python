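"""Between-sample community comparison.

Composition overlap is summarised by the Sørensen index over 96% clusters,
Cs = 2j/(a+b) * 100; phylogenetic structure by a neighbor-joining tree of
cluster representatives (p-distance input), an abundance-weighted UniFrac
distance matrix over that tree, and a principal-coordinates (PCoA)
projection of the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .cluster import ClusterSet, overlap_count

# --------------------------------------------------------------------------
# Sørensen index
# --------------------------------------------------------------------------


def sorensen(cs: ClusterSet, sample_a: str, sample_b: str) -> float:
    """Sørensen similarity Cs = 2j/(a+b) * 100 over cluster presence.

    Returns NaN when both samples contain no clusters.
    """
    j, a, b = overlap_count(cs, sample_a, sample_b)
    if a + b == 0:
        return float("nan")
    return 100.0 * 2.0 * j / (a + b)


def sorensen_matrix(cs: ClusterSet) -> pd.DataFrame:
    samples = list(cs.abundance.columns)
    mat = pd.DataFrame(100.0, index=samples, columns=samples)
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1:]:
            v = sorensen(cs, s1, s2)
            mat.loc[s1, s2] = mat.loc[s2, s1] = v
    return mat


def overlap_matrix(cs: ClusterSet) -> pd.DataFrame:
    """Matrix of shared-cluster counts j (diagonal: clusters per sample)."""
    samples = list(cs.abundance.columns)
    mat = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for s1 in samples:
        for s2 in samples:
            j, a, _ = overlap_count(cs, s1, s2)
            mat.loc[s1, s2] = j if s1 != s2 else a
    return mat


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


def p_distance_matrix(seqs: list[str], identity_fn=None) -> np.ndarray:
    """p-distances 1 - identity/100 (no substitution-model correction)."""
    from .screen import identity_matrix

    ident = identity_matrix(seqs)
    d = 1.0 - ident / 100.0
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted (trifurcating) tree.

    Ties in the Q criterion are broken by the smallest index pair, so the
    topology is deterministic.  Negative estimated branch lengths are
    clamped to zero with the deficit transferred to the sibling branch (the
    pair distance is preserved).
    """
    D = np.array(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n) or not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be square and finite")
    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, 1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first occurrence = smallest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        du = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]

    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d12 + d13 - d23),
        0.5 * (d12 + d23 - d13),
        0.5 * (d13 + d23 - d12),
    ]
    root = TreeNode()
    for node, ln in zip(nodes, lengths):
        node.length = float(max(ln, 0.0))
        root.append(node)
    return root


def patristic_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length distances in ``labels`` order."""
    dm = tree.tip_tip_distances(endpoints=[str(l) for l in labels])
    return np.asarray(dm.data)


# --------------------------------------------------------------------------
# Weighted UniFrac
# --------------------------------------------------------------------------


def _subtree_masses(tree: TreeNode, weights: dict[str, float]) -> dict[int, float]:
    masses: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        m = weights.get(node.name, 0.0) if node.is_tip() else sum(
            masses[id(c)] for c in node.children
        )
        masses[id(node)] = m
    return masses


def weighted_unifrac(
    tree: TreeNode,
    abundance: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    normalized: bool = False,
) -> float:
    """Abundance-weighted UniFrac between two samples over ``tree``.

    Raw form: sum over branches of length * |A_i/A_T - B_i/B_T| where A_i is
    the read mass of sample a below the branch.  The normalized form divides
    by sum of length * (A_i/A_T + B_i/B_T).  Tree leaves without an
    abundance row (reference sequences) carry zero weight; every abundance
    row must map to a leaf.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [c for c in abundance.index if c not in tip_names]
    if missing:
        raise KeyError(f"abundance rows with no tree leaf: {missing}")
    totals = {}
    for s in (sample_a, sample_b):
        if s not in abundance.columns:
            raise KeyError(f"unknown sample {s!r}")
        tot = float(abundance[s].sum())
        if tot <= 0:
            raise ValueError(f"sample {s!r} has zero total abundance")
        totals[s] = tot
    wa = (abundance[sample_a] / totals[sample_a]).to_dict()
    wb = (abundance[sample_b] / totals[sample_b]).to_dict()
    ma = _subtree_masses(tree, wa)
    mb = _subtree_masses(tree, wb)
    num = 0.0
    den = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        num += length * abs(ma[id(node)] - mb[id(node)])
        den += length * (ma[id(node)] + mb[id(node)])
    if not normalized:
        return num
    return num / den if den else 0.0


def unifrac_matrix(
    tree: TreeNode, abundance: pd.DataFrame, normalized: bool = False
) -> DistanceMatrix:
    samples = list(abundance.columns)
    mat = np.zeros((len(samples), len(samples)))
    for i, s1 in enumerate(samples):
        for j in range(i + 1, len(samples)):
            d = weighted_unifrac(tree, abundance, s1, samples[j], normalized)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=samples)


# --------------------------------------------------------------------------
# Principal coordinates
# --------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """PCoA projection: centered coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix | np.ndarray, n_axes: int = 2,
         ids: list[str] | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling via Gower centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors scaled
    by sqrt(eigenvalue) for positive eigenvalues.  Negative eigenvalues are
    reported but their axes dropped; proportions are relative to the sum of
    positive eigenvalues.  Axis signs are fixed so each axis' largest-
    magnitude loading is positive.
    """
    if isinstance(dm, DistanceMatrix):
        D = np.asarray(dm.data, dtype=float)
        labels = list(dm.ids)
    else:
        D = np.asarray(dm, dtype=float)
        labels = list(ids) if ids is not None else [str(i) for i in range(len(D))]
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0) if n else 1.0
    pos = vals > 1e-12 * scale
    pos_sum = vals[pos].sum()
    n_keep = min(n_axes, int(pos.sum()))
    coords = np.zeros((n, n_keep))
    for k in range(n_keep):
        v = vecs[:, k] * np.sqrt(vals[k])
        if abs(v.min()) > abs(v.max()):
            v = -v
        coords[:, k] = v
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PC{k + 1}" for k in range(n_keep)]
    )
    prop = np.array([v / pos_sum if pos_sum > 0 else 0.0 for v in vals[:n_keep]])
    return PcoaResult(coordinates=frame, eigenvalues=vals, proportion_explained=prop)
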