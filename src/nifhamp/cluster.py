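"""Complete-linkage identity clustering of amino-acid sequences.

Sequences are clustered on the distance 100 - percent identity with
complete linkage, so every output cluster satisfies the diameter property:
all pairwise identities within a cluster are at or above the threshold.
The three analysis levels (100/96/92%) are cuts of one agglomeration, which
makes the partitions nested (every 96% cluster lies inside exactly one 92%
cluster).  Clusters holding fewer than a minimum number of reads (default
10) can be pruned to remove residual sequencing-error artefacts.

The agglomeration is exact (no heuristic identity shortcuts) and
deterministic: among pairs at equal distance the lexicographically smallest
(id_i, id_j) pair is merged first, where a cluster's id is the smallest
member seq_id.  Because merges above the coarsest cut can never change the
partition, the agglomeration runs independently inside each connected
component of the below-cut distance graph, which keeps exact clustering
tractable for tens of thousands of unique sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .qc import ProteinSeq
from .screen import identity_matrix

#: tolerance when cutting at integer identity thresholds
_EPS = 1e-9


@dataclass
class ClusterSet:
    """Partition of sequences at one identity threshold.

    ``clusters`` maps cluster_id -> member seq_ids; ``representatives`` maps
    cluster_id -> seq_id of the most abundant member (ties broken by the
    lexicographically smallest seq_id); ``abundance`` is the cluster x sample
    read-count matrix.
    """

    threshold: float
    clusters: dict[str, list[str]]
    representatives: dict[str, str]
    abundance: pd.DataFrame

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.abundance.index)

    def members(self, cluster_id: str) -> list[str]:
        return self.clusters[cluster_id]


# --------------------------------------------------------------------------
# Exact complete-linkage agglomeration
# --------------------------------------------------------------------------


def _agglomerate_component(D: np.ndarray, cut_levels: list[float]) -> dict[float, np.ndarray]:
    """Complete-linkage merges inside one component, snapshotting the
    partition at each cut (ascending ``cut_levels`` of distance).

    Returns cut -> label array (arbitrary but deterministic integers).
    Ties are broken by the smallest (row, column) pair; rows must already be
    ordered by seq_id so this realises the lexicographic tie rule.
    """
    m = len(D)
    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    root = np.arange(m)              # original index -> current cluster anchor
    active = np.ones(m, dtype=bool)
    pending = sorted(cut_levels)
    out: dict[float, np.ndarray] = {}
    upper = np.triu(np.ones((m, m), dtype=bool), 1)

    while True:
        U = np.where(upper, W, np.inf)
        flat = int(np.argmin(U))
        i, j = divmod(flat, m)
        h = U[i, j]
        while pending and h > pending[0]:
            out[pending.pop(0)] = root.copy()
        if not pending:
            break
        # merge cluster anchored at j into the one anchored at i (i < j)
        merged = np.maximum(W[i], W[j])
        W[i, :] = merged
        W[:, i] = merged
        W[i, i] = np.inf
        W[j, :] = np.inf
        W[:, j] = np.inf
        active[j] = False
        root[root == j] = i
        if active.sum() == 1:
            while pending:
                out[pending.pop(0)] = root.copy()
            break
    return out


def _encode_seqs(seqs: list[str]) -> np.ndarray:
    n, L = len(seqs), len(seqs[0])
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)


def _distance_graph(seqs: list[str], max_cut: float):
    """Sparse below-cut distance edges + connected component labels.

    Equal-length sequences use vectorised Hamming distance; mixed lengths
    fall back to the alignment-based identity (small inputs only).
    """
    n = len(seqs)
    lengths = {len(s) for s in seqs}
    rows, cols = [], []
    if len(lengths) == 1:
        enc = _encode_seqs(seqs)
        L = enc.shape[1]
        block = 256
        for i0 in range(0, n, block):
            sub = enc[i0:i0 + block]
            dist = 100.0 * (sub[:, None, :] != enc[None, :, :]).mean(axis=2)
            ii, jj = np.nonzero(dist <= max_cut)
            rows.extend((ii + i0).tolist())
            cols.extend(jj.tolist())
    else:
        full = 100.0 - identity_matrix(seqs)
        ii, jj = np.nonzero(full <= max_cut)
        rows, cols = ii.tolist(), jj.tolist()
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    return comp


def _pairwise_distances(seqs: list[str]) -> np.ndarray:
    if len({len(s) for s in seqs}) == 1 and seqs:
        enc = _encode_seqs(seqs)
        return 100.0 * (enc[:, None, :] != enc[None, :, :]).mean(axis=2)
    return 100.0 - identity_matrix(seqs)


def _cluster_labels(
    seqs: list[str], thresholds: tuple[float, ...]
) -> dict[float, np.ndarray]:
    """Global complete-linkage labels per threshold (seqs in seq_id order)."""
    n = len(seqs)
    cuts = {t: (100.0 - t) + _EPS for t in thresholds}
    max_cut = max(cuts.values())
    comp = _distance_graph(seqs, max_cut)
    labels = {t: np.zeros(n, dtype=int) for t in thresholds}
    offset = 0
    order = sorted(set(comp), key=lambda c: int(np.flatnonzero(comp == c)[0]))
    for c in order:
        idx = np.flatnonzero(comp == c)
        if len(idx) == 1:
            for t in thresholds:
                labels[t][idx[0]] = offset
            offset += 1
            continue
        D = _pairwise_distances([seqs[k] for k in idx])
        snaps = _agglomerate_component(D, [cuts[t] for t in thresholds])
        for t in thresholds:
            local = snaps[cuts[t]]
            labels[t][idx] = local + offset
        offset += len(idx)
    return labels


def _build_clusterset(
    pseqs: list[ProteinSeq], labels: np.ndarray, threshold: float
) -> ClusterSet:
    by_label: dict[int, list[ProteinSeq]] = {}
    for p, lab in zip(pseqs, labels):
        by_label.setdefault(int(lab), []).append(p)
    samples = sorted({s for p in pseqs for s in p.per_sample_counts})

    entries = []
    for lab, members in by_label.items():
        total = sum(p.total for p in members)
        rep = min(members, key=lambda p: (-p.total, p.seq_id)).seq_id
        entries.append((total, rep, members))
    # deterministic numbering: by decreasing total reads, then representative
    entries.sort(key=lambda e: (-e[0], e[1]))

    clusters, reps, rows = {}, {}, []
    width = max(4, len(str(len(entries))))
    for k, (total, rep, members) in enumerate(entries):
        cid = f"C{int(round(threshold))}_{k + 1:0{width}d}"
        clusters[cid] = sorted(p.seq_id for p in members)
        reps[cid] = rep
        rows.append(
            [sum(p.per_sample_counts.get(s, 0) for p in members) for s in samples]
        )
    abundance = pd.DataFrame(rows, index=list(clusters), columns=samples, dtype=int)
    return ClusterSet(threshold, clusters, reps, abundance)


def hierarchical_cluster(
    pseqs: list[ProteinSeq], thresholds: tuple[float, ...] = (100.0, 96.0, 92.0)
) -> dict[float, ClusterSet]:
    """Cluster once and cut the complete-linkage agglomeration at each
    threshold; partitions at decreasing thresholds are nested coarsenings."""
    for t in thresholds:
        if not 0.0 < t <= 100.0:
            raise ValueError(f"threshold must be in (0, 100], got {t}")
    if not pseqs:
        return {t: _build_clusterset([], np.array([]), t) for t in thresholds}
    ordered = sorted(pseqs, key=lambda p: p.seq_id)
    if len(ordered) == 1:
        return {t: _build_clusterset(ordered, np.array([0]), t) for t in thresholds}
    labels = _cluster_labels([p.aa_seq for p in ordered], tuple(thresholds))
    return {t: _build_clusterset(ordered, labels[t], t) for t in thresholds}


def complete_linkage_cluster(pseqs: list[ProteinSeq], threshold: float) -> ClusterSet:
    """Complete-linkage clustering at a single identity threshold."""
    return hierarchical_cluster(pseqs, (threshold,))[threshold]


def verify_diameter(cs: ClusterSet, pseqs: list[ProteinSeq]) -> bool:
    """Exhaustively check the complete-linkage diameter property."""
    seq_of = {p.seq_id: p.aa_seq for p in pseqs}
    for cid, members in cs.clusters.items():
        seqs = [seq_of[m] for m in members]
        ident = identity_matrix(seqs)
        if ident.min() < cs.threshold - _EPS:
            return False
    return True


def prune_small_clusters(
    cs: ClusterSet, min_size: int = 10
) -> tuple[ClusterSet, float]:
    """Drop clusters with fewer than ``min_size`` total reads.

    Returns the pruned set and the fraction of reads removed.
    """
    totals = cs.abundance.sum(axis=1)
    keep = totals[totals >= min_size].index
    removed_reads = int(totals.sum() - totals.loc[keep].sum())
    frac = removed_reads / totals.sum() if totals.sum() else 0.0
    pruned = ClusterSet(
        threshold=cs.threshold,
        clusters={c: cs.clusters[c] for c in keep},
        representatives={c: cs.representatives[c] for c in keep},
        abundance=cs.abundance.loc[keep].copy(),
    )
    return pruned, float(frac)


def overlap_count(cs: ClusterSet, sample_a: str, sample_b: str) -> tuple[int, int, int]:
    """(j, a, b): shared and per-sample cluster counts (presence = count > 0)."""
    for s in (sample_a, sample_b):
        if s not in cs.abundance.columns:
            raise KeyError(f"unknown sample {s!r}")
    in_a = cs.abundance[sample_a] > 0
    in_b = cs.abundance[sample_b] > 0
    return int((in_a & in_b).sum()), int(in_a.sum()), int(in_b.sum())


def membership_frame(cs: ClusterSet) -> pd.DataFrame:
    rows = [
        {"cluster_id": cid, "seq_id": sid,
         "representative": cs.representatives[cid]}
        for cid, members in cs.clusters.items()
        for sid in members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "seq_id", "representative"])
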