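"""Read-level quality control and frame-aware denoising.

The filter cascade mirrors standard practice for protein-coding amplicon
pyrosequencing: trim primers, drop reads <200 nt or containing undetermined
bases, clip to 180 nt, translate in the frame fixed by the forward primer
boundary, drop sequences with in-frame stop codons, and finally drop
sequences that do not align cleanly to a position-specific NifH profile.
Because the target is protein coding, a homopolymer indel (the dominant 454
error mode) shifts the reading frame and is caught either as a premature
stop codon or as an unalignable tail at the profile stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_NEG = -1e30


class ProfileError(ValueError):
    """Invalid profile configuration."""


@dataclass
class Read:
    read_id: str
    sample: str
    nt_seq: str


@dataclass
class ProteinSeq:
    """A unique QC-passed amino-acid sequence with per-sample read counts."""

    seq_id: str
    aa_seq: str
    per_sample_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class AttritionLog:
    """Read counts surviving each QC stage (monotone non-increasing)."""

    input: int = 0
    after_trim: int = 0
    after_length: int = 0
    after_ambiguity: int = 0
    after_clip: int = 0
    after_stop_filter: int = 0
    after_profile_filter: int = 0

    STAGES = (
        "input", "after_trim", "after_length", "after_ambiguity",
        "after_clip", "after_stop_filter", "after_profile_filter",
    )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.STAGES, "reads": [getattr(self, s) for s in self.STAGES]}
        )

    def check_monotone(self) -> None:
        counts = [getattr(self, s) for s in self.STAGES]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"attrition is not monotone: {counts}")


# --------------------------------------------------------------------------
# Primer trimming and base filters
# --------------------------------------------------------------------------


def _mismatches(window: str, primer: str) -> int:
    n = 0
    for base, code in zip(window, primer):
        if base not in IUPAC_NT.get(code, code):
            n += 1
    return n


def trim_primers(
    read: Read,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 1,
) -> Read | None:
    """Strip primer flanks; returns ``None`` if the forward primer is absent.

    The forward primer must match at the 5' end with at most ``max_mismatch``
    mismatches (IUPAC degeneracy honoured) because the reading frame is
    anchored on it.  The reverse primer (given 5'->3' on the minus strand) is
    stripped from the 3' end when present, but its absence is tolerated —
    truncated reads simply keep their shortened tail.
    """
    if len(read.nt_seq) < len(fwd_primer):
        return None
    if _mismatches(read.nt_seq[: len(fwd_primer)], fwd_primer) > max_mismatch:
        return None
    insert = read.nt_seq[len(fwd_primer):]
    rc = _revcomp(rev_primer)
    if len(insert) >= len(rc) and _mismatches(insert[-len(rc):], rc) <= max_mismatch:
        insert = insert[: -len(rc)]
    return Read(read.read_id, read.sample, insert)


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def filter_length_ambiguity(read: Read, min_len: int = 200) -> tuple[bool, str]:
    """(passes, reason); rejects reads shorter than ``min_len`` or with 'N'."""
    if len(read.nt_seq) < min_len:
        return False, "short"
    if "N" in read.nt_seq:
        return False, "ambiguous"
    return True, ""


def clip_and_translate(read: Read, clip_len: int = 180) -> str | None:
    """Clip to ``clip_len`` nt, translate in frame 0, reject in-frame stops.

    Frame 0 starts at the base immediately after the trimmed forward primer.
    Returns the peptide (``clip_len // 3`` residues) or ``None`` when the
    translation contains a stop codon.
    """
    if clip_len % 3 != 0:
        raise ValueError(f"clip_len must be divisible by 3, got {clip_len}")
    if len(read.nt_seq) < clip_len:
        return None
    peptide = str(Seq(read.nt_seq[:clip_len]).translate())
    if "*" in peptide:
        return None
    return peptide


def proteins_to_fasta_records(pseqs: list[ProteinSeq]) -> list[tuple[str, str]]:
    """FASTA records with per-sample counts encoded in the header."""
    return [
        (
            p.seq_id + " "
            + ";".join(f"{s}:{c}" for s, c in sorted(p.per_sample_counts.items())),
            p.aa_seq,
        )
        for p in pseqs
    ]


def proteins_from_fasta_records(records: list[tuple[str, str]]) -> list[ProteinSeq]:
    """Inverse of :func:`proteins_to_fasta_records`; counts default to 1."""
    out = []
    for header, seq in records:
        parts = header.split(None, 1)
        counts: dict[str, int] = {}
        if len(parts) == 2:
            for item in parts[1].split(";"):
                sample, c = item.split(":")
                counts[sample] = int(c)
        out.append(ProteinSeq(parts[0], seq, counts or {"all": 1}))
    return out


def dereplicate(seqs: list[tuple[str, str]]) -> list[ProteinSeq]:
    """Collapse ``(aa_seq, sample)`` pairs into unique :class:`ProteinSeq`.

    Ids are assigned in order of decreasing total count (ties broken by the
    sequence string) so numbering is deterministic.
    """
    counts: dict[str, dict[str, int]] = {}
    for aa, sample in seqs:
        per = counts.setdefault(aa, {})
        per[sample] = per.get(sample, 0) + 1
    ordered = sorted(counts, key=lambda aa: (-sum(counts[aa].values()), aa))
    return [
        ProteinSeq(f"P{i + 1:05d}", aa, dict(sorted(counts[aa].items())))
        for i, aa in enumerate(ordered)
    ]


# --------------------------------------------------------------------------
# Position-specific profile and alignment filter
# --------------------------------------------------------------------------


@dataclass
class Profile:
    """Plain position-specific scoring profile with affine delete gaps.

    ``match_scores`` is a (length x 20) array over :data:`AA_ALPHABET`.
    Inserts (sequence residues consuming no profile position) cost
    ``insert_penalty`` per residue; deletes (skipped profile positions) cost
    ``gap_open`` then ``gap_extend``.  A sequence is "unaligned" when no
    optimal global alignment to the profile is insert-free.
    """

    match_scores: np.ndarray
    gap_open: float = -1.5
    gap_extend: float = -0.3
    insert_penalty: float = -0.3

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ProfileError("match_scores must be (length, 20)")
        if not np.all(np.isfinite(self.match_scores)):
            raise ProfileError("match scores must be finite")
        if self.gap_open > 0 or self.gap_extend > 0 or self.insert_penalty > 0:
            raise ProfileError("gap and insert penalties must be non-positive")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        variable_positions=(),
        match_score: float = 2.0,
        mismatch_score: float = -1.8,
        variable_score: float = 0.2,
        **kwargs,
    ) -> "Profile":
        """Profile for a conserved scaffold: consensus residues score
        ``match_score``, other residues ``mismatch_score``; designated
        variable positions score ``variable_score`` for every residue."""
        scores = np.full((len(consensus), 20), mismatch_score)
        for i, aa in enumerate(consensus):
            scores[i, AA_INDEX[aa]] = match_score
        for pos in variable_positions:
            scores[pos, :] = variable_score
        return cls(scores, **kwargs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#gap_open\t{self.gap_open}\n")
            fh.write(f"#gap_extend\t{self.gap_extend}\n")
            fh.write(f"#insert_penalty\t{self.insert_penalty}\n")
            fh.write("position\t" + "\t".join(AA_ALPHABET) + "\n")
            for i, row in enumerate(self.match_scores):
                fh.write(f"{i + 1}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "Profile":
        params = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, value = line[1:].split("\t")
                    params[key] = float(value)
                elif not line.startswith("position"):
                    rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(
            np.array(rows),
            gap_open=params.get("gap_open", -1.5),
            gap_extend=params.get("gap_extend", -0.3),
            insert_penalty=params.get("insert_penalty", -0.3),
        )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc} in sequence") from exc


def _batch_optimal_scores(seq_idx: np.ndarray, profile: Profile) -> np.ndarray:
    """Optimal global profile-alignment score for a batch of equal-length
    sequences (dynamic programming with M/I/D states)."""
    n, m = seq_idx.shape
    L = profile.length
    go, ge, ip = profile.gap_open, profile.gap_extend, profile.insert_penalty

    M = np.full((m + 1, n), _NEG)
    I = np.full((m + 1, n), _NEG)
    D = np.full((m + 1, n), _NEG)
    M[0] = 0.0
    for j in range(1, m + 1):
        I[j] = ip + np.maximum(M[j - 1], I[j - 1])

    for i in range(1, L + 1):
        Mp, Ip, Dp = M, I, D
        M = np.full((m + 1, n), _NEG)
        I = np.full((m + 1, n), _NEG)
        D = np.empty((m + 1, n))
        D[0] = np.maximum(Dp[0] + ge, np.maximum(Mp[0], Ip[0]) + go)
        for j in range(1, m + 1):
            gain = profile.match_scores[i - 1, seq_idx[:, j - 1]]
            M[j] = gain + np.maximum(Mp[j - 1], np.maximum(Ip[j - 1], Dp[j - 1]))
            D[j] = np.maximum(Dp[j] + ge, np.maximum(Mp[j], Ip[j]) + go)
            I[j] = ip + np.maximum(M[j - 1], np.maximum(I[j - 1], D[j - 1]))
    return np.maximum(M[m], np.maximum(I[m], D[m]))


def _all_match_scores(seq_idx: np.ndarray, profile: Profile) -> np.ndarray:
    """Score of the insert-free (all-match) alignment; only defined when the
    sequence length equals the profile length."""
    L = profile.length
    return profile.match_scores[np.arange(L)[None, :], seq_idx].sum(axis=1)


def _pair_best_insert_free(seq_idx: np.ndarray, profile: Profile) -> float:
    """Best global score using match/delete states only (no inserts)."""
    m = len(seq_idx)
    L = profile.length
    if m > L:
        return _NEG
    go, ge = profile.gap_open, profile.gap_extend
    M = np.full(m + 1, _NEG)
    D = np.full(m + 1, _NEG)
    M[0] = 0.0
    for i in range(1, L + 1):
        Mp, Dp = M.copy(), D.copy()
        D = np.maximum(Dp + ge, Mp + go)
        M = np.full(m + 1, _NEG)
        gain = profile.match_scores[i - 1, seq_idx]
        M[1:] = gain + np.maximum(Mp[:-1], Dp[:-1])
    return float(max(M[m], D[m]))


def align_to_profile(aa_seq: str, profile: Profile) -> tuple[float, bool]:
    """Score one sequence against the profile.

    Returns ``(optimal score, insert_free)`` where ``insert_free`` is True
    when some optimal global alignment places every residue in a match
    state — the retention criterion of :func:`profile_align_filter`.
    """
    idx = _encode(aa_seq)
    opt = float(_batch_optimal_scores(idx[None, :], profile)[0])
    best_free = _pair_best_insert_free(idx, profile)
    return opt, bool(best_free >= opt - 1e-9)


def profile_align_filter(
    pseqs: list[ProteinSeq], profile: Profile
) -> tuple[list[ProteinSeq], list[ProteinSeq], pd.DataFrame]:
    """Partition sequences into (retained, rejected) by profile alignment.

    A sequence is rejected when every optimal global alignment to the profile
    forces at least one residue into an insert (unaligned) state — the
    signature of a frameshifted tail.  Substitution-only sequences keep an
    insert-free optimal alignment and are retained.
    """
    if profile.length < 30:
        raise ProfileError(f"profile has {profile.length} match states (< 30)")
    retained: list[ProteinSeq] = []
    rejected: list[ProteinSeq] = []
    audit_rows = []
    by_len: dict[int, list[ProteinSeq]] = {}
    for p in pseqs:
        by_len.setdefault(len(p.aa_seq), []).append(p)
    for length, group in sorted(by_len.items()):
        idx = np.vstack([_encode(p.aa_seq) for p in group])
        opt = _batch_optimal_scores(idx, profile)
        if length == profile.length:
            free = _all_match_scores(idx, profile)
        else:
            free = np.array([_pair_best_insert_free(row, profile) for row in idx])
        ok = free >= opt - 1e-9
        for p, o, f, keep in zip(group, opt, free, ok):
            (retained if keep else rejected).append(p)
            audit_rows.append(
                {"seq_id": p.seq_id, "score": float(o),
                 "insert_free_score": float(f), "retained": bool(keep)}
            )
    retained.sort(key=lambda p: p.seq_id)
    rejected.sort(key=lambda p: p.seq_id)
    audit = pd.DataFrame(
        audit_rows, columns=["seq_id", "score", "insert_free_score", "retained"]
    ).sort_values("seq_id").reset_index(drop=True)
    return retained, rejected, audit


# --------------------------------------------------------------------------
# Full QC cascade
# --------------------------------------------------------------------------


@dataclass
class QCResult:
    pseqs: list[ProteinSeq]
    attrition: AttritionLog
    rejections: pd.DataFrame  # read_id, sample, stage


def run_qc(
    reads: list[Read],
    profile: Profile,
    fwd_primer: str,
    rev_primer: str,
    min_len: int = 200,
    clip_len: int = 180,
    max_mismatch: int = 1,
) -> QCResult:
    """Run the full QC cascade and return unique proteins plus attrition."""
    log = AttritionLog(input=len(reads))
    rejections = []

    def reject(read: Read, stage: str) -> None:
        rejections.append(
            {"read_id": read.read_id, "sample": read.sample, "stage": stage}
        )

    trimmed = []
    for read in reads:
        t = trim_primers(read, fwd_primer, rev_primer, max_mismatch)
        if t is None:
            reject(read, "trim")
        else:
            trimmed.append(t)
    log.after_trim = len(trimmed)

    kept = []
    for read in trimmed:
        if len(read.nt_seq) < min_len:
            reject(read, "length")
        else:
            kept.append(read)
    log.after_length = len(kept)

    clean = []
    for read in kept:
        if "N" in read.nt_seq:
            reject(read, "ambiguity")
        else:
            clean.append(read)
    log.after_ambiguity = len(clean)

    clipped: list[tuple[Read, str | None]] = []
    for read in clean:
        if len(read.nt_seq) < clip_len:
            reject(read, "clip")
        else:
            clipped.append((read, read.nt_seq[:clip_len]))
    log.after_clip = len(clipped)

    translated = []
    for read, nt in clipped:
        peptide = clip_and_translate(Read(read.read_id, read.sample, nt), clip_len)
        if peptide is None:
            reject(read, "stop")
        else:
            translated.append((peptide, read.sample, read.read_id))
    log.after_stop_filter = len(translated)

    pseqs = dereplicate([(aa, sample) for aa, sample, _ in translated])
    retained, rejected, _ = profile_align_filter(pseqs, profile)
    rejected_aas = {p.aa_seq for p in rejected}
    for aa, sample, read_id in translated:
        if aa in rejected_aas:
            rejections.append(
                {"read_id": read_id, "sample": sample, "stage": "profile"}
            )
    # renumber survivors so ids are dense and deterministic
    final = dereplicate(
        [(aa, s) for aa, s, _ in translated if aa not in rejected_aas]
    )
    log.after_profile_filter = sum(p.total for p in final)
    log.check_monotone()
    rej = pd.DataFrame(rejections, columns=["read_id", "sample", "stage"])
    return QCResult(pseqs=final, attrition=log, rejections=rej)
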