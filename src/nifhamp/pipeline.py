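"""End-to-end orchestration: QC -> contaminant screen -> clustering ->
diversity -> between-sample comparison.

Every stochastic stage (depth subsampling, the pooled "mixed" sample) draws
from a child of one pipeline seed, so a rerun with the same configuration
is byte-identical.  Comparison outputs (Sørensen, overlap, NJ tree,
UniFrac, PCoA) are computed on min-size-pruned clusters; per-sample
diversity is computed on depth-normalised, unpruned counts.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cluster import (
    ClusterSet,
    hierarchical_cluster,
    membership_frame,
    prune_small_clusters,
)
from .compare import (
    nj_tree,
    overlap_matrix,
    p_distance_matrix,
    pcoa,
    sorensen_matrix,
    unifrac_matrix,
)
from .diversity import (
    CountVector,
    diversity_row,
    mixed_sample,
    rarefaction_curve,
    subsample,
)
from .qc import Profile, ProteinSeq, Read, run_qc
from .screen import ContaminantDB, screen
from .simulate import FWD_PRIMER, REV_PRIMER

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    reads_dir: str
    profile: str
    outdir: str
    contaminant_db: str | None = None
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    min_len: int = 200
    clip_len: int = 180
    contaminant_threshold: float = 96.0
    cluster_levels: tuple[float, ...] = (100.0, 96.0, 92.0)
    min_cluster_size: int = 10
    subsample_depth: int = 2883
    seed: int = 0

    def validate(self) -> None:
        if self.min_len < self.clip_len:
            raise ValueError("min_len must be at least clip_len")
        if self.clip_len % 3:
            raise ValueError("clip_len must be divisible by 3")
        if not 0 < self.contaminant_threshold <= 100:
            raise ValueError("contaminant_threshold must be in (0, 100]")
        if any(not 0 < t <= 100 for t in self.cluster_levels):
            raise ValueError("cluster levels must be in (0, 100]")
        if self.min_cluster_size < 1 or self.subsample_depth < 1:
            raise ValueError("min_cluster_size and subsample_depth must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cluster_levels" in data:
            data["cluster_levels"] = tuple(float(x) for x in data["cluster_levels"])
        return cls(**data)


@dataclass
class PipelineResult:
    pseqs: list[ProteinSeq]
    attrition: pd.DataFrame
    screen_report: pd.DataFrame
    clustersets: dict[float, ClusterSet]
    pruned: dict[float, ClusterSet]
    prune_fraction: dict[float, float]
    diversity: pd.DataFrame
    rarefaction: pd.DataFrame
    excluded_samples: list[str]
    sorensen: pd.DataFrame | None
    overlap: pd.DataFrame | None
    tree_newick: str | None
    unifrac: pd.DataFrame | None
    unifrac_normalized: pd.DataFrame | None
    pcoa_coords: pd.DataFrame | None
    manifest: dict


def load_reads(reads_dir: str) -> list[Read]:
    """Read per-sample FASTA files; the sample is the file stem."""
    reads: list[Read] = []
    paths = sorted(glob.glob(os.path.join(reads_dir, "*.fasta")))
    skip = {"contaminants.fasta", "true_variants.fasta"}
    for path in paths:
        name = os.path.basename(path)
        if name in skip:
            continue
        sample = os.path.splitext(name)[0]
        for header, seq in nio.read_fasta(path):
            reads.append(Read(header.split()[0], sample, seq))
    return reads


def _protein_count_vectors(pseqs: list[ProteinSeq]) -> dict[str, CountVector]:
    samples = sorted({s for p in pseqs for s in p.per_sample_counts})
    return {
        s: CountVector(
            {p.seq_id: p.per_sample_counts.get(s, 0) for p in pseqs}
        )
        for s in samples
    }


def _to_cluster_counts(cv: CountVector, cs: ClusterSet) -> CountVector:
    cluster_of = {
        sid: cid for cid, members in cs.clusters.items() for sid in members
    }
    out: dict[str, int] = {}
    for sid, c in cv.counts.items():
        cid = cluster_of.get(sid)
        if cid is not None:
            out[cid] = out.get(cid, 0) + c
    return CountVector(out)


def analyze(
    reads: list[Read],
    profile: Profile,
    db: ContaminantDB | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every analysis stage in memory and assemble the manifest."""
    config.validate()
    manifest: dict = {"version": PACKAGE_VERSION, "seed": config.seed}

    qc = run_qc(
        reads, profile, config.fwd_primer, config.rev_primer,
        config.min_len, config.clip_len,
    )
    manifest["attrition"] = {
        s: int(getattr(qc.attrition, s)) for s in qc.attrition.STAGES
    }

    if db is not None:
        retained, removed, screen_report = screen(qc.pseqs, db)
    else:
        retained = qc.pseqs
        samples = sorted({s for p in retained for s in p.per_sample_counts})
        screen_report = pd.DataFrame(
            {
                "sample": samples,
                "n_in": [
                    sum(p.per_sample_counts.get(s, 0) for p in retained)
                    for s in samples
                ],
                "n_removed": 0,
                "fraction_removed": 0.0,
            }
        )
    manifest["screen"] = {
        row["sample"]: round(float(row["fraction_removed"]), 6)
        for _, row in screen_report.iterrows()
    }

    clustersets = hierarchical_cluster(retained, config.cluster_levels)
    pruned, prune_fraction = {}, {}
    for t, cs in clustersets.items():
        pruned[t], prune_fraction[t] = prune_small_clusters(
            cs, config.min_cluster_size
        )
    manifest["clusters"] = {
        str(int(t)): {
            "n_clusters": len(cs.clusters),
            "n_pruned": len(pruned[t].clusters),
            "pruned_read_fraction": round(prune_fraction[t], 6),
        }
        for t, cs in clustersets.items()
    }

    # Depth normalisation at the unique-protein level, shared by thresholds.
    ss = np.random.SeedSequence(config.seed)
    sub_rng, mix_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    protein_cvs = _protein_count_vectors(retained)
    subsampled: dict[str, CountVector] = {}
    excluded: list[str] = []
    for s in sorted(protein_cvs):
        drawn = subsample(protein_cvs[s], config.subsample_depth, sub_rng)
        if drawn is None:
            excluded.append(s)
        else:
            subsampled[s] = drawn
    mixed = (
        mixed_sample(
            [subsampled[s] for s in sorted(subsampled)],
            config.subsample_depth,
            mix_rng,
        )
        if len(subsampled) >= 2
        else None
    )
    manifest["excluded_samples"] = excluded

    div_rows, rare_rows = [], []
    for t in config.cluster_levels:
        cs = clustersets[t]
        items = [(s, subsampled[s]) for s in sorted(subsampled)]
        if mixed is not None:
            items.append(("mixed", mixed))
        for name, cv in items:
            ccv = _to_cluster_counts(cv, cs)
            row = {"sample": name, "threshold": int(t), **diversity_row(ccv)}
            div_rows.append(row)
            curve = rarefaction_curve(ccv, n_points=20)
            curve.insert(0, "threshold", int(t))
            curve.insert(0, "sample", name)
            rare_rows.append(curve)
    diversity = pd.DataFrame(div_rows)
    rarefaction = (
        pd.concat(rare_rows, ignore_index=True) if rare_rows else pd.DataFrame()
    )

    # Between-sample comparison on pruned clusters.
    t96 = 96.0 if 96.0 in pruned else config.cluster_levels[min(1, len(config.cluster_levels) - 1)]
    t92 = 92.0 if 92.0 in pruned else config.cluster_levels[-1]
    cs96, cs92 = pruned[t96], pruned[t92]
    sor = sorensen_matrix(cs96) if len(cs96.abundance.columns) else None
    ovl = overlap_matrix(cs96) if len(cs96.abundance.columns) else None

    tree_newick = None
    unifrac_df = unifrac_norm_df = coords = None
    seq_of = {p.seq_id: p.aa_seq for p in retained}
    cids = cs92.cluster_ids
    abundance92 = cs92.abundance.loc[:, cs92.abundance.sum(axis=0) > 0]
    if len(cids) >= 3 and abundance92.shape[1] >= 2:
        rep_seqs = [seq_of[cs92.representatives[c]] for c in cids]
        tree = nj_tree(cids, p_distance_matrix(rep_seqs))
        tree = tree.root_at_midpoint()
        tree_newick = str(tree).strip()
        dm = unifrac_matrix(tree, abundance92, normalized=False)
        unifrac_df = dm.to_data_frame()
        unifrac_norm_df = unifrac_matrix(
            tree, abundance92, normalized=True
        ).to_data_frame()
        res = pcoa(dm, n_axes=2)
        coords = res.coordinates
        manifest["pcoa_proportion_explained"] = [
            round(float(x), 6) for x in res.proportion_explained
        ]
    manifest["n_samples_compared"] = int(abundance92.shape[1])
    return PipelineResult(
        pseqs=retained,
        attrition=qc.attrition.as_frame(),
        screen_report=screen_report,
        clustersets=clustersets,
        pruned=pruned,
        prune_fraction=prune_fraction,
        diversity=diversity,
        rarefaction=rarefaction,
        excluded_samples=excluded,
        sorensen=sor,
        overlap=ovl,
        tree_newick=tree_newick,
        unifrac=unifrac_df,
        unifrac_normalized=unifrac_norm_df,
        pcoa_coords=coords,
        manifest=manifest,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_result(result: PipelineResult, outdir: str) -> dict:
    """Write all stage outputs and the manifest; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    nio.write_tsv(os.path.join(outdir, "attrition.tsv"), result.attrition,
                  index=False)
    nio.write_fasta(
        os.path.join(outdir, "unique_proteins.fasta"),
        [(p.seq_id, p.aa_seq) for p in result.pseqs],
    )
    nio.write_tsv(os.path.join(outdir, "screen_report.tsv"),
                  result.screen_report, index=False)
    seq_of = {p.seq_id: p.aa_seq for p in result.pseqs}
    for t, cs in result.clustersets.items():
        tag = str(int(t))
        nio.write_tsv(
            os.path.join(outdir, f"membership_{tag}.tsv"),
            membership_frame(cs), index=False,
        )
        nio.write_tsv(os.path.join(outdir, f"abundance_{tag}.tsv"), cs.abundance)
        pr = result.pruned[t]
        nio.write_tsv(os.path.join(outdir, f"abundance_{tag}_pruned.tsv"),
                      pr.abundance)
        nio.write_fasta(
            os.path.join(outdir, f"representatives_{tag}_pruned.fasta"),
            [(f"{c} {pr.representatives[c]}", seq_of[pr.representatives[c]])
             for c in pr.cluster_ids],
        )
    nio.write_tsv(os.path.join(outdir, "diversity.tsv"), result.diversity,
                  index=False)
    nio.write_tsv(os.path.join(outdir, "rarefaction.tsv"), result.rarefaction,
                  index=False)
    if result.sorensen is not None:
        nio.write_tsv(os.path.join(outdir, "sorensen_96.tsv"), result.sorensen)
        nio.write_tsv(os.path.join(outdir, "overlap_96.tsv"), result.overlap)
    if result.tree_newick is not None:
        with open(os.path.join(outdir, "tree_92.nwk"), "w") as fh:
            fh.write(result.tree_newick + "\n")
        nio.write_tsv(os.path.join(outdir, "unifrac_92.tsv"), result.unifrac)
        nio.write_tsv(os.path.join(outdir, "unifrac_92_normalized.tsv"),
                      result.unifrac_normalized)
        nio.write_tsv(os.path.join(outdir, "pcoa_92.tsv"), result.pcoa_coords)

    manifest = dict(result.manifest)
    manifest["outputs"] = {
        name: _sha256(os.path.join(outdir, name))
        for name in sorted(os.listdir(outdir))
        if name != "manifest.json" and os.path.isfile(os.path.join(outdir, name))
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs, run every stage, write outputs; returns the manifest."""
    config.validate()
    reads = load_reads(config.reads_dir)
    profile = Profile.from_tsv(config.profile)
    db = (
        ContaminantDB.from_fasta(
            config.contaminant_db, config.contaminant_threshold
        )
        if config.contaminant_db
        else None
    )
    result = analyze(reads, profile, db, config)
    return write_result(result, config.outdir)
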