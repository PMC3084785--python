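# Methods

This note documents the models, algorithms and numerical choices behind
`nifhamp`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## The analysis model

The pipeline treats a *nifH* amplicon survey as a protein-level problem.
Reads are nucleotide fragments of a protein-coding marker amplified with a
known forward primer, so the reading frame is fixed by the primer boundary
(frame 0 from the first base after the trimmed forward primer; no six-frame
search).  All analysis past translation operates on 60-residue amino-acid
sequences: clipping at 180 nt standardises length, translation collapses
synonymous variation, and two error classes become separable:

* **Indels** (dominant in homopolymer runs for 454-style chemistry) shift
  the frame and are caught either by an in-frame stop codon among the 60
  codons or by an unalignable tail at the profile stage.
* **Substitutions** survive QC but are absorbed by identity clustering:
  they sit within a few residues of their template, far from the distances
  separating genuine variants.

Assumptions: the forward primer is present and nearly exact (its loss is a
trimming rejection, since frame depends on it); the reverse primer is
optional; the first 180 nt of the insert carry enough signal for
classification; chimeras and PCR abundance bias are out of scope.

## QC cascade

Stage order and defaults: trim (1 mismatch tolerated, IUPAC degeneracy
honoured) → length ≥ 200 nt → no `N` → clip at 180 nt → translate →
reject stops → dereplicate → profile filter.  The 180 nt clip is applied
to the trimmed insert (the alternative — clipping before trimming — would
make the frame depend on primer length).  The per-stage attrition log is
monotone by construction and checked at run time.

### Profile filter

`hmmalign`-style "unaligned characters" are re-expressed with a plain
position-specific profile: a (length × 20) score matrix plus affine delete
penalties (open −1.5, extend −0.3) and a per-residue insert penalty
(−0.3).  A sequence is **rejected when no optimal global alignment to the
profile is insert-free**.  For sequences of the profile's length this has a
clean characterisation: the insert-free alignment is unique (all-match), so
the sequence is kept iff the all-match score equals the DP optimum; ties
favour retention.  The DP is batched across sequences (states M/I/D,
vectorised over the sequence axis), so filtering tens of thousands of
unique sequences costs seconds.

The default profile is built from the simulator's conserved scaffold:
consensus residues score +2.0, other residues −1.8 at the 40 conserved
positions; the 20 variable positions score +0.2 for every residue.  With
these values a frameshifted tail of ≥3 residues scores better in
insert+delete states than as forced matches (and is rejected), while up to
a few isolated substitutions at conserved positions remain cheaper as
mismatching matches (and are retained).  Frameshifts within the last two
codons are a known blind spot — too short to produce either a stop or an
alignable-insert signal; on simulated single-indel reads the stop and
profile filters jointly reject ≈96%.

## Identity, screening, clustering

One identity definition is used repo-wide: global alignment (match +1,
mismatch −1, gap open −3, gap extend −1), identity = matching columns /
alignment columns excluding terminal gaps.  For equal-length sequences the
distance matrices used at scale (clustering, screening) take the ungapped
Hamming form; this is equivalent for the indel-free sequences that survive
the frameshift filters (a gapped alignment of two equal-length QC survivors
would require compensating indels that the profile filter excludes), and
the public `pairwise_identity` always performs the full alignment.

Screening removes a sequence when its best identity to any contaminant
reference is ≥ the threshold (default 96%; ties removed).  Identity is
computed on the full-length global alignment rather than local HSPs — the
sequences are uniformly 60 aa, so the global form is deterministic and
toolkit-free with the same threshold semantics.

Clustering is **exact complete linkage** on distance 100 − identity:
every output cluster's worst within-cluster pair respects the threshold
(verified exhaustively in tests).  Among equally distant pairs the
lexicographically smallest (id_i, id_j) pair merges first; ids are assigned
in order of decreasing abundance, so ties resolve toward the abundant
centre of an error cloud.  This matters in practice: distances between
60-mers are multiples of 100/60, ties are pervasive, and an arbitrary tie
order can split an abundant variant's substitution cloud into spurious
≥10-read clusters.  The three analysis levels are cuts of one
agglomeration, so partitions are nested.  Because merges above the coarsest
cut cannot change any partition at or below it, the agglomeration runs
independently inside each connected component of the below-cut distance
graph, keeping the exact algorithm O(m³) only in component size (hundreds),
not dataset size (tens of thousands).

Pruning removes clusters with <10 total reads.  The pipeline applies it at
every clustering level before between-sample comparisons (Sørensen,
overlap, tree, UniFrac, PCoA), treating it as the final denoising step;
per-sample alpha diversity is reported on unpruned, depth-normalised
counts, where singletons are part of the signal that Chao1 uses.

## Diversity

Subsampling to a common depth (default 2,883) is a multivariate
hypergeometric draw (without replacement); samples below the depth are
excluded, not errors.  The "mixed" sample draws the same depth from the
pool of all per-sample subsamples.  Chao1 defaults to the bias-corrected
form S_obs + F1(F1−1)/(2(F2+1)) (defined when F2 = 0); the classic
S_obs + F1²/(2F2) is available by flag, falling back to the bias-corrected
term when F2 = 0.  Shannon uses the natural log.  Rarefaction is analytic
(log-gamma evaluation of the hypergeometric expectation), not resampled.

## Comparison

Sørensen uses presence (count > 0) of clusters at the 96% level:
C_s = 2j/(a+b)·100, NA only when both samples are empty.  The NJ tree is
Saitou–Nei over p-distances (1 − identity/100, no substitution-model
correction) of pruned 92%-cluster representatives; Q-criterion ties break
on the smallest index pair; a negative estimated branch length is clamped
to zero with the deficit moved to its sibling so the pair distance is
preserved.  The tree is midpoint-rooted for branch-descent bookkeeping.
Weighted UniFrac is the raw branch sum Σ bᵢ·|Aᵢ/A_T − Bᵢ/B_T| by default
(a metric; used for PCoA); the normalised form divides by
Σ bᵢ·(Aᵢ/A_T + Bᵢ/B_T).  Tree leaves without abundance rows (reference
sequences) carry zero weight.  PCoA is classical scaling: Gower-centred
−½ J D² J, symmetric eigendecomposition, coordinates = eigenvector·√λ for
positive eigenvalues; negative eigenvalues are reported and their axes
dropped; proportions are taken over the positive spectrum; axis signs are
fixed so each axis' largest loading is positive.

## Synthetic data: what it emulates, what it does not

Communities are built on a fixed NifH-like 60-residue scaffold with 20
designated variable positions.  Backbone variants randomise the variable
positions (pairwise identity ≈68%, verified <85% by brute force before
emission), so the true cluster count at every threshold is known by
construction; optional satellites sit at 1 substitution (same 96% cluster)
or 3 substitutions (same 92%, new 96% cluster) from their parent.
Non-outlier samples share a common fraction of backbones
(`shared_variant_fraction`, default 0.6 of 25 variants), fixing the true
Sørensen matrix; outlier samples carry only private variants.  Abundances
follow a discretised power law (Zipf shape 1.0 by default — the most
abundant of 25 variants holds ≈26% of a sample, the rarest ≈1%), ranks
shuffled per sample.

Reads are `forward primer + back-translated coding region (180 nt, uniform
synonymous codon choice) + fixed per-variant 145 nt flank + reverse
primer` ≈ 359 bp.  The error channel applies, in order: per-base
substitutions (default 0.2%), one ±1 bp indel per homopolymer run of ≥2
with probability 1% per run, per-base `N` conversion (0.02%), and
truncation below the length cutoff for 2% of reads; contaminant spike-ins
(default 5% of reads) draw from a separate pool of scaffold-compatible
sequences that double as the screening database.  Every event is recorded
in a per-read sidecar.  The per-base rates are exposed in `SimConfig`; the
defaults are plausible placeholders for 454 chemistry, not fitted values.

Not emulated: flowgram-level error structure, quality scores, chimeras,
PCR abundance bias, length variation of real amplicons, and real *nifH*
phylogenetic structure (variants are star-like around one scaffold rather
than falling into canonical Clusters I/III/IV).  Passing tests therefore
demonstrate the correctness and calibration of the algorithms under this
generative model, not field performance on real reagent contamination or
real phylogenies.

## Problem sizes and determinism

The test suite and acceptance script run the full design at its stated
scale — ten samples × 5,000 reads (≈50,000 reads, ≈6,000–12,000 unique
proteins), depth 2,883 — which completes in well under a minute; unit
tests use hundreds of reads.  Brute-force oracles (exhaustive partition
search, exact hypergeometric richness variance, additive-matrix NJ
round-trips) are limited to ≤10 taxa/sequences where enumeration is exact.
A single pipeline seed is split per stage (subsampling, mixed sample) via
`numpy` seed sequences; reruns with identical configuration are
byte-identical, and the manifest records per-stage counts and output
checksums.

## Known limitations

* Frameshifts in the final ~2 codons pass QC; recurrent late indels of an
  abundant variant can leave small artefact clusters (usually pruned).
* The equal-length Hamming fast path and the gapped alignment can disagree
  for pathological pairs with compensating indels; such sequences are
  excluded upstream by the profile filter, but the screening of externally
  supplied protein sets with indel variation should use the alignment path
  (automatic for mixed lengths).
* Complete-linkage partitions are not unique under ties; determinism comes
  from the documented tie rule, and other valid tie orders can yield
  different (equally diameter-valid) partitions.
* Chao1 confidence intervals, coverage estimators, Hill numbers, bootstrap
  support values and graphical rendering are out of scope.
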