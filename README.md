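# nifhamp

Frame-aware denoising, clustering and diversity analysis of **nifH amplicon
pyrosequencing reads**, with a ground-truth read simulator.

The *nifH* gene, encoding the iron-protein subunit of nitrogenase, is the
standard marker for surveying nitrogen-fixing microorganisms (diazotrophs).
Amplicon surveys of *nifH* from 454-style pyrosequencing face two specific
problems: homopolymer insertion/deletion errors that shift the reading frame
of a protein-coding gene, and *nifH*-like sequences present in PCR reagents
that masquerade as environmental diazotrophs.  `nifhamp` implements the full
analysis chain for such surveys, for microbial ecologists who want a
deterministic, testable alternative to ad-hoc script pipelines:

1. **Quality control and frame-aware denoising** — primer trimming, removal
   of reads <200 bp or containing undetermined bases, clipping to 180 bp,
   translation in the primer-anchored frame, rejection of in-frame stop
   codons, and rejection of sequences that cannot be aligned insert-free to
   a position-specific NifH profile.  A frameshift either creates a stop
   codon within the 60 analysed codons or an unalignable tail, so indel
   errors are removed rather than counted as novel diversity.
2. **Contaminant screening** — sequences with ≥96% amino-acid identity to a
   reference set of putative reagent contaminants are removed.
3. **Complete-linkage clustering** of the unique 60-residue protein
   sequences at 100/96/92% identity (nested cuts of one agglomeration);
   clusters with <10 reads can be pruned.
4. **Diversity** — subsampling to a common depth (default 2,883 reads),
   observed richness S_obs, the Chao1 estimator
   S_Chao1 = S_obs + F1(F1−1)/(2(F2+1)), the Shannon index
   H = −Σ pᵢ ln pᵢ, analytic (hypergeometric) rarefaction
   E[S_n] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], and a pooled "mixed" sample.
5. **Between-sample comparison** — the Sørensen index C_s = 2j/(a+b)·100
   over 96% clusters, a Saitou–Nei neighbor-joining tree of 92%-cluster
   representatives on p-distances, abundance-weighted UniFrac
   d(A,B) = Σ_branches bᵢ·|Aᵢ/A_T − Bᵢ/B_T| over that tree, and principal
   coordinates analysis of the distance matrix.
6. **Synthetic data** — a simulator that generates multi-sample communities
   of 60-residue NifH variants with skewed abundances, back-translates them
   into ~359 bp amplicons, and injects 454-style errors (substitutions,
   homopolymer-run indels, ambiguous bases, truncated reads) plus reagent
   contaminant spike-ins, recording per-read ground truth.

## Worked example

Simulate a ten-sample survey (25 variants per sample, 5,000 reads each) and
run the full pipeline:

```sh
nifhamp simulate --outdir sim --seed 3
# wrote 50000 reads to sim

nifhamp qc --in sim --profile sim/profile.tsv --out proteins.fasta
#               stage  reads
#               input  50000
#          after_trim  50000
#        after_length  49002
#     after_ambiguity  45957
#          after_clip  45957
#   after_stop_filter  35219
#after_profile_filter  32870

nifhamp screen --in proteins.fasta --db sim/contaminants.fasta \
    --out clean.fasta --report screen.tsv
# retained 6134 unique sequences, removed 363

nifhamp cluster --in clean.fasta --outdir clusters
# 100.0%: 6134 clusters (116 after pruning, 23.69% of reads removed)
# 96.0%: 1008 clusters (118 after pruning, 3.86% of reads removed)
# 92.0%: 213 clusters (115 after pruning, 0.54% of reads removed)

nifhamp diversity --abundance clusters/abundance_92.tsv --depth 2000 \
    --seed 1 --out diversity.tsv
nifhamp compare --abundance clusters/abundance_92_pruned.tsv \
    --representatives clusters/representatives_92_pruned.fasta --outdir cmp
```

Reading the numbers: of 50,000 raw reads, ~29% are lost to frameshift
filtering (stop codons plus profile-unalignable tails) — the expected
signature of per-homopolymer-run indel errors at the simulated rate.  The
32,870 surviving reads collapse to 6,134 unique proteins; substitution
errors inflate the 100% level, but complete-linkage clustering absorbs them:
213 clusters at 92% identity, and after removing clusters with <10 reads
(0.54% of the data) 115 clusters remain — the ten communities were designed
with 130 distinct variants.  `cmp/` then holds the Sørensen and weighted
UniFrac matrices, the NJ tree (Newick) and the PCoA coordinates.

Or run everything in one step (`nifhamp run-all --reads sim ...`), which
also writes a `manifest.json` with per-stage counts and output checksums;
reruns with the same configuration and seed are byte-identical.

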