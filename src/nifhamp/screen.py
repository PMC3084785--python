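"""Reagent-contaminant screening by amino-acid identity.

nifH-like sequences related to Alpha- and Betaproteobacteria occur in PCR
reagents, so any sequence at or above a configurable identity threshold
(default 96%) to a contaminant reference set is removed.  Identity is
defined on a full-length global alignment (match/mismatch scoring with
affine gaps) as matches divided by alignment columns, terminal gap columns
excluded — one identity definition shared with the clustering module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .io import read_fasta
from .qc import ProteinSeq


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment of two protein sequences.

    Identity = matching columns / alignment columns, where columns that are
    terminal gaps (overhangs at either end) are excluded from the
    denominator.  Two identical 60-mers give 100.0; a 60-mer against itself
    with one internal extra residue gives 100 * 60/61.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    cols = [(x, y) for x, y in zip(row_a, row_b)]
    start = 0
    while start < len(cols) and "-" in cols[start]:
        start += 1
    end = len(cols)
    while end > start and "-" in cols[end - 1]:
        end -= 1
    core = cols[start:end]
    if not core:
        return 0.0
    matches = sum(x == y for x, y in core)
    return 100.0 * matches / len(core)


def identity_matrix(seqs: list[str]) -> np.ndarray:
    """Symmetric percent-identity matrix over a sequence list.

    When all sequences share one length the ungapped (Hamming) identity is
    used — equivalent to the alignment definition for the indel-free
    sequences that survive the frameshift filters, and fast enough for
    thousands of sequences.  Mixed lengths fall back to
    :func:`pairwise_identity`.
    """
    n = len(seqs)
    out = np.full((n, n), 100.0)
    if n == 0:
        return out
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        L = lengths.pop()
        enc = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
        block = 512
        for i0 in range(0, n, block):
            sub = enc[i0:i0 + block]
            matches = (sub[:, None, :] == enc[None, :, :]).sum(axis=2)
            out[i0:i0 + block] = 100.0 * matches / L
    else:
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pairwise_identity(seqs[i], seqs[j])
    return out


def cross_identity(queries: list[str], refs: list[str]) -> np.ndarray:
    """(n_query x n_ref) percent identities, Hamming fast path as above."""
    nq, nr = len(queries), len(refs)
    out = np.zeros((nq, nr))
    if nq == 0 or nr == 0:
        return out
    lens = {len(s) for s in queries} | {len(s) for s in refs}
    if len(lens) == 1:
        L = lens.pop()
        qe = np.frombuffer("".join(queries).encode(), dtype=np.uint8).reshape(nq, L)
        re_ = np.frombuffer("".join(refs).encode(), dtype=np.uint8).reshape(nr, L)
        for i0 in range(0, nq, 1024):
            sub = qe[i0:i0 + 1024]
            out[i0:i0 + 1024] = (
                100.0 * (sub[:, None, :] == re_[None, :, :]).sum(axis=2) / L
            )
    else:
        for i, q in enumerate(queries):
            for j, r in enumerate(refs):
                out[i, j] = pairwise_identity(q, r)
    return out


@dataclass
class ContaminantDB:
    """Reference amino-acid sequences of putative reagent contaminants."""

    entries: list[tuple[str, str]]
    threshold: float = 96.0

    def __post_init__(self):
        if not 0.0 < self.threshold <= 100.0:
            raise ValueError("threshold must be in (0, 100]")

    @classmethod
    def from_fasta(cls, path, threshold: float = 96.0) -> "ContaminantDB":
        return cls(entries=read_fasta(path), threshold=threshold)


class ScreenError(ValueError):
    pass


def screen(
    pseqs: list[ProteinSeq], db: ContaminantDB
) -> tuple[list[ProteinSeq], list[ProteinSeq], pd.DataFrame]:
    """Split sequences into (retained, removed) against the contaminant db.

    A sequence is removed when its best identity to any db entry is at or
    above ``db.threshold`` (ties at the threshold are removed, matching the
    ">= 96%" convention).  The report gives per-sample read counts and the
    removed fraction.
    """
    if not db.entries:
        raise ScreenError("contaminant screening enabled with an empty database")
    refs = [seq for _, seq in db.entries]
    ident = cross_identity([p.aa_seq for p in pseqs], refs)
    best = ident.max(axis=1) if len(pseqs) else np.array([])
    retained, removed = [], []
    for p, b in zip(pseqs, best):
        (removed if b >= db.threshold else retained).append(p)

    samples = sorted({s for p in pseqs for s in p.per_sample_counts})
    rows = []
    for s in samples:
        n_in = sum(p.per_sample_counts.get(s, 0) for p in pseqs)
        n_rm = sum(p.per_sample_counts.get(s, 0) for p in removed)
        rows.append(
            {
                "sample": s,
                "n_in": n_in,
                "n_removed": n_rm,
                "fraction_removed": n_rm / n_in if n_in else 0.0,
            }
        )
    report = pd.DataFrame(rows, columns=["sample", "n_in", "n_removed",
                                         "fraction_removed"])
    return retained, removed, report
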