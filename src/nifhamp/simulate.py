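"""Synthetic nifH amplicon communities with known ground truth.

Emulates the structure of a multi-sample functional-gene pyrosequencing
study: each sample is a skewed mixture of 60-residue NifH protein variants,
reads are ~359 bp amplicons (primer + back-translated coding region +
downstream flank + reverse primer), and the error channel injects the
signatures of 454 pyrosequencing — per-base substitutions, homopolymer-run
insertions/deletions (the frameshift source), ambiguous bases, truncated
reads — plus reagent-contaminant spike-ins.

Variants are built on a conserved NifH-like scaffold: a fixed consensus with
20 designated variable positions.  Community variants randomise the variable
positions, so any two independent variants agree at the 40 conserved sites
and differ at essentially all variable sites (~68% identity, well below the
92% clustering level).  Optional "satellite" variants sit at designed
distances from their parent (1 substitution -> same 96% cluster; 3
substitutions -> same 92% cluster, distinct 96% cluster), which makes the
true cluster count at each threshold known by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import write_fasta

# --------------------------------------------------------------------------
# Fixed sequence context
# --------------------------------------------------------------------------

#: Synthetic NifH-like 60-residue consensus (composition modelled on the
#: conserved iron-protein core; not a database sequence).
CONSENSUS = "MRQCAIYGKGGIGKSTTTQNLVAALAEMGKKVMIVGCDPKADSTRLILHSKAQNTIMEMA"

#: Positions free to vary between community variants (0-based).
VARIABLE_POSITIONS = tuple(range(2, 60, 3))  # 20 positions: 2, 5, ..., 59

#: Fixed primer flanks (concrete instances of degenerate nifH primers).
FWD_PRIMER = "TGCGACCCTAAGGCTGA"          # 17 nt
REV_PRIMER = "AGCGCCATCATTTCACC"          # 17 nt, given 5'->3' on the minus strand

#: Length of the back-translated coding region carried by each read.
CODING_NT = 180
#: Downstream flank so the amplicon reaches the study's ~359 bp.
EXTENSION_NT = 145

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, sense codons only, keyed by residue.
_CODONS: dict[str, list[str]] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        _CODONS.setdefault(aa, []).append(codon)
    for aa in _CODONS:
        _CODONS[aa].sort()


_build_codon_table()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length sequences (ungapped)."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


# --------------------------------------------------------------------------
# Configuration and truth containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study design and error-channel parameters for one simulated run.

    Defaults reproduce the simulated study conditions: ten samples of 25
    variants each at 5,000 reads, a strongly skewed (Zipf, shape 1.0)
    abundance distribution, and 454-style error rates (0.2% per-base
    substitutions, 1% per-homopolymer-run indels).
    """

    n_samples: int = 10
    variants_per_sample: int = 25
    shared_variant_fraction: float = 0.6
    reads_per_sample: int = 5000
    abundance_shape: float = 1.0
    sub_rate: float = 0.002
    homopolymer_indel_rate: float = 0.01
    ambig_rate: float = 0.0002
    short_read_fraction: float = 0.02
    contaminant_fraction: float = 0.05
    rng_seed: int = 0
    # design extensions
    n_contaminants: int = 8
    contaminants_error_free: bool = False
    outlier_samples: int = 0
    sat96_per_variant: int = 0
    sat92_per_variant: int = 0

    def validate(self) -> None:
        rates = {
            "shared_variant_fraction": self.shared_variant_fraction,
            "sub_rate": self.sub_rate,
            "homopolymer_indel_rate": self.homopolymer_indel_rate,
            "ambig_rate": self.ambig_rate,
            "short_read_fraction": self.short_read_fraction,
            "contaminant_fraction": self.contaminant_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.variants_per_sample < 1:
            raise ValueError("variants_per_sample must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.outlier_samples > self.n_samples:
            raise ValueError("outlier_samples cannot exceed n_samples")
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")
        if self.sat96_per_variant + 2 + 3 > len(VARIABLE_POSITIONS) and (
            self.sat92_per_variant or self.sat96_per_variant
        ):
            raise ValueError("too many satellites for the variable-position budget")


@dataclass
class SimTruth:
    """Ground truth for one simulated run (community design + per-read labels)."""

    variants: dict[str, str]                      # id -> 60-aa sequence
    contaminants: dict[str, str]                  # id -> 60-aa sequence
    extensions: dict[str, str]                    # origin id -> 145-nt flank
    parent: dict[str, str]                        # satellite id -> backbone id
    sample_variants: dict[str, list[str]]         # sample -> variant ids
    sample_abundances: dict[str, np.ndarray]      # sample -> relative abundances
    true_cluster_count: dict[int, int]            # threshold -> count
    true_sorensen: pd.DataFrame                   # pairwise Cs (%) at 96%

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_variants)

    def true_protein_variants(self, sample: str) -> dict[str, tuple[str, float]]:
        ids = self.sample_variants[sample]
        ab = self.sample_abundances[sample]
        return {v: (self.variants[v], float(p)) for v, p in zip(ids, ab)}


class DesignError(RuntimeError):
    """Requested identity design is not realisable."""


# --------------------------------------------------------------------------
# Variant pool design
# --------------------------------------------------------------------------


def _random_variant(rng: np.random.Generator) -> str:
    seq = list(CONSENSUS)
    for pos in VARIABLE_POSITIONS:
        seq[pos] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(seq)


def _substitute(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _draw_distinct(rng, existing: list[str], max_identity: float = 85.0,
                   attempts: int = 500) -> str:
    for _ in range(attempts):
        cand = _random_variant(rng)
        if all(hamming_identity(cand, other) < max_identity for other in existing):
            return cand
    raise DesignError(
        f"could not draw a variant below {max_identity}% identity to the "
        f"existing pool of {len(existing)} after {attempts} attempts"
    )


def generate_variant_pool(config: SimConfig) -> SimTruth:
    """Design the per-sample variant communities and the contaminant pool.

    Backbone variants are mutually <85% identical (verified by brute-force
    pairwise comparison before returning); satellites sit at designed
    distances from their parents, so the true cluster count at 100/96/92% is
    known by construction.  Non-outlier samples draw
    ``round(shared_variant_fraction * variants_per_sample)`` backbones from a
    common shared pool; outlier samples carry only private variants.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    pool_rng, _ = (np.random.default_rng(s) for s in ss.spawn(2))

    v = config.variants_per_sample
    n_shared = int(round(config.shared_variant_fraction * v))
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    outliers = set(samples[config.n_samples - config.outlier_samples:])

    all_seqs: list[str] = []
    variants: dict[str, str] = {}

    def new_backbone(tag: str) -> str:
        seq = _draw_distinct(pool_rng, all_seqs)
        all_seqs.append(seq)
        variants[tag] = seq
        return tag

    shared_ids = [new_backbone(f"V_shared_{k:03d}") for k in range(n_shared)]
    sample_backbones: dict[str, list[str]] = {}
    for s in samples:
        n_private = v if s in outliers else v - n_shared
        priv = [new_backbone(f"V_{s}_{k:03d}") for k in range(n_private)]
        sample_backbones[s] = ([] if s in outliers else list(shared_ids)) + priv

    # Satellites at designed distances from their backbone.
    parent: dict[str, str] = {}
    backbones = [b for b in variants]
    for b in backbones:
        base = variants[b]
        for k in range(config.sat96_per_variant):
            sid = f"{b}_s96_{k}"
            variants[sid] = _substitute(base, [VARIABLE_POSITIONS[k]], pool_rng)
            parent[sid] = b
        n96 = config.sat96_per_variant
        for k in range(config.sat92_per_variant):
            positions = [VARIABLE_POSITIONS[n96], VARIABLE_POSITIONS[n96 + 1],
                         VARIABLE_POSITIONS[n96 + 2 + k]]
            sid = f"{b}_s92_{k}"
            variants[sid] = _substitute(base, positions, pool_rng)
            parent[sid] = b

    contaminants: dict[str, str] = {}
    for k in range(config.n_contaminants):
        seq = _draw_distinct(pool_rng, all_seqs)
        all_seqs.append(seq)
        contaminants[f"CONTAM_{k:02d}"] = seq

    _verify_design(variants, contaminants, parent, config)

    # Per-sample variant lists (backbones + their satellites) and abundances.
    sample_variants: dict[str, list[str]] = {}
    sample_abundances: dict[str, np.ndarray] = {}
    sats_of: dict[str, list[str]] = {}
    for sid, b in parent.items():
        sats_of.setdefault(b, []).append(sid)
    for s in samples:
        ids = []
        for b in sample_backbones[s]:
            ids.append(b)
            ids.extend(sorted(sats_of.get(b, [])))
        ranks = pool_rng.permutation(len(ids)) + 1
        weights = ranks.astype(float) ** (-config.abundance_shape)
        sample_variants[s] = ids
        sample_abundances[s] = weights / weights.sum()

    # Flanking nucleotide context, fixed per origin.
    extensions = {
        oid: _random_nt(EXTENSION_NT, pool_rng)
        for oid in list(variants) + list(contaminants)
    }

    n_backbones = len(backbones)
    true_cluster_count = {
        100: len(variants),
        96: n_backbones * (1 + (1 if config.sat92_per_variant else 0)),
        92: n_backbones,
    }

    true_sorensen = _true_sorensen(samples, sample_backbones, parent, config)

    return SimTruth(
        variants=variants,
        contaminants=contaminants,
        extensions=extensions,
        parent=parent,
        sample_variants=sample_variants,
        sample_abundances=sample_abundances,
        true_cluster_count=true_cluster_count,
        true_sorensen=true_sorensen,
    )


def _verify_design(variants, contaminants, parent, config) -> None:
    """Brute-force pairwise identity verification of the designed pool."""
    ids = sorted(variants)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = hamming_identity(variants[a], variants[b])
            fam_a = parent.get(a, a)
            fam_b = parent.get(b, b)
            if fam_a != fam_b:
                if ident >= 88.0:
                    raise DesignError(f"{a} vs {b}: cross-family identity {ident:.1f}")
            else:
                if ident < 92.0:
                    raise DesignError(f"{a} vs {b}: family identity {ident:.1f} < 92")
    for c, cseq in contaminants.items():
        for a, aseq in variants.items():
            if hamming_identity(cseq, aseq) >= 88.0:
                raise DesignError(f"contaminant {c} too close to variant {a}")


def _true_sorensen(samples, sample_backbones, parent, config) -> pd.DataFrame:
    """Pairwise Sørensen (%) between samples from designed 96% clusters."""
    extra = 1 if config.sat92_per_variant else 0
    support = {
        s: {(b, k) for b in sample_backbones[s] for k in range(1 + extra)}
        for s in samples
    }
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, s1 in enumerate(samples):
        for s2 in samples[i:]:
            a, b = len(support[s1]), len(support[s2])
            j = len(support[s1] & support[s2])
            cs = 100.0 * 2 * j / (a + b) if (a + b) else np.nan
            mat.loc[s1, s2] = mat.loc[s2, s1] = cs
    return mat


# --------------------------------------------------------------------------
# Read emission
# --------------------------------------------------------------------------


def back_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform random synonymous codon choice."""
    picks = rng.random(len(aa_seq))
    codons = []
    for aa, r in zip(aa_seq, picks):
        options = _CODONS[aa]
        codons.append(options[int(r * len(options))])
    return "".join(codons)


_RUN_RE = re.compile(r"(.)\1+")


def homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, end) of maximal single-base runs of length >= 2."""
    return [m.span() for m in _RUN_RE.finditer(seq)]


def inject_single_homopolymer_indel(
    insert: str, rng: np.random.Generator, region: tuple[int, int] | None = None
) -> tuple[str, int, str]:
    """Apply exactly one +-1 bp indel at a random homopolymer run.

    ``region`` restricts eligible runs to those starting inside it (e.g. the
    coding window).  Returns (mutated insert, run start, 'ins'|'del').
    """
    runs = homopolymer_runs(insert)
    if region is not None:
        lo, hi = region
        runs = [r for r in runs if lo <= r[0] < hi]
    if not runs:
        raise ValueError("no homopolymer run of length >= 2 in the region")
    start, end = runs[rng.integers(len(runs))]
    kind = "ins" if rng.random() < 0.5 else "del"
    if kind == "ins":
        mutated = insert[:start] + insert[start] + insert[start:]
    else:
        mutated = insert[:start] + insert[start + 1:]
    return mutated, start, kind


def _apply_channel(insert: str, config: SimConfig, rng: np.random.Generator):
    """Inject substitutions, homopolymer indels and ambiguous bases."""
    events: list[tuple[int, str]] = []
    seq = list(insert)
    if config.sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < config.sub_rate)
        for pos in hits:
            alt = "ACGT".replace(seq[pos], "")
            seq[pos] = alt[rng.integers(3)]
            events.append((int(pos), "sub"))
    s = "".join(seq)
    if config.homopolymer_indel_rate > 0:
        runs = homopolymer_runs(s)
        edits = []
        for start, end in runs:
            if rng.random() < config.homopolymer_indel_rate:
                kind = "ins" if rng.random() < 0.5 else "del"
                edits.append((start, kind))
        for start, kind in sorted(edits, reverse=True):
            if kind == "ins":
                s = s[:start] + s[start] + s[start:]
            else:
                s = s[:start] + s[start + 1:]
            events.append((start, kind))
    if config.ambig_rate > 0:
        arr = list(s)
        hits = np.flatnonzero(rng.random(len(arr)) < config.ambig_rate)
        for pos in hits:
            arr[pos] = "N"
            events.append((int(pos), "ambig"))
        s = "".join(arr)
    return s, sorted(events)


def emit_reads(
    config: SimConfig, truth: SimTruth
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Emit per-sample nucleotide reads and the per-read truth sidecar.

    Deterministic for a fixed ``config`` (including ``rng_seed``): the read
    stream uses its own child of the config seed, independent of pool design.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    _, read_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    reads: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for sample in truth.samples:
        ids = truth.sample_variants[sample]
        ab = truth.sample_abundances[sample]
        n = config.reads_per_sample
        n_contam = int(read_rng.binomial(n, config.contaminant_fraction))
        contam_ids = sorted(truth.contaminants)
        origins = []
        if n_contam and contam_ids:
            picks = read_rng.integers(0, len(contam_ids), size=n_contam)
            origins += [(contam_ids[i], True) for i in picks]
        counts = read_rng.multinomial(n - len(origins), ab)
        for vid, c in zip(ids, counts):
            origins += [(vid, False)] * int(c)
        order = read_rng.permutation(len(origins))

        sample_reads = []
        for ridx, oi in enumerate(order):
            origin, is_contam = origins[oi]
            aa = truth.contaminants[origin] if is_contam else truth.variants[origin]
            coding = back_translate(aa, read_rng)
            insert = coding + truth.extensions[origin]
            pristine = is_contam and config.contaminants_error_free
            if pristine:
                events: list[tuple[int, str]] = []
            else:
                insert, events = _apply_channel(insert, config, read_rng)
            read = FWD_PRIMER + insert + revcomp(REV_PRIMER)
            if not pristine and read_rng.random() < config.short_read_fraction:
                keep = int(read_rng.integers(60, len(FWD_PRIMER) + 200))
                read = read[:keep]
                events = [e for e in events if e[0] < keep - len(FWD_PRIMER)]
                events.append((keep - len(FWD_PRIMER), "trunc"))
            read_id = f"{sample}_R{ridx:06d}"
            sample_reads.append((read_id, read))
            rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "origin_variant_id": origin,
                    "is_contaminant": is_contam,
                    "error_events": ";".join(f"{p}:{t}" for p, t in events),
                }
            )
        reads[sample] = sample_reads
    sidecar = pd.DataFrame(
        rows, columns=["read_id", "sample", "origin_variant_id",
                       "is_contaminant", "error_events"]
    )
    return reads, sidecar


def write_simulation(
    config: SimConfig, truth: SimTruth, reads, sidecar, outdir
) -> None:
    """Write per-sample FASTA, the truth sidecar, the contaminant db and a profile."""
    import os

    from .qc import Profile

    os.makedirs(outdir, exist_ok=True)
    for sample in sorted(reads):
        write_fasta(
            os.path.join(outdir, f"{sample}.fasta"),
            [(f"{rid} sample={sample}", seq) for rid, seq in reads[sample]],
        )
    sidecar.to_csv(os.path.join(outdir, "truth_sidecar.tsv"), sep="\t", index=False)
    write_fasta(
        os.path.join(outdir, "contaminants.fasta"),
        sorted(truth.contaminants.items()),
    )
    write_fasta(
        os.path.join(outdir, "true_variants.fasta"), sorted(truth.variants.items())
    )
    Profile.from_consensus(CONSENSUS, VARIABLE_POSITIONS).to_tsv(
        os.path.join(outdir, "profile.tsv")
    )
    truth.true_sorensen.to_csv(os.path.join(outdir, "true_sorensen.tsv"), sep="\t")


def noiseless(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with every error process switched off."""
    return replace(
        config,
        sub_rate=0.0,
        homopolymer_indel_rate=0.0,
        ambig_rate=0.0,
        short_read_fraction=0.0,
        contaminant_fraction=0.0,
    )
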