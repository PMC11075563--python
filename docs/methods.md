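# Methods

## Scope and data model

`woodpop` implements the downstream analyses of a small-sample resequencing
study: diploid genotypes at biallelic SNPs (a samples × variants dosage
matrix with chromosome, position and depth metadata), a mitogenome multiple
alignment, and a whole-genome alignment coordinate table against a reference
karyotype. All stages are exercised against a built-in coalescent simulator
whose parameters define the study conditions the tests assume.

## Coalescent simulator

Each locus is an independent Hudson genealogy with no intra-locus
recombination: with k lineages the waiting time to the next coalescence is
exponential with rate k(k−1)/2 (constant size), time measured in units of 2N
generations. Under exponential growth at rate α the backwards coalescence
rate is inflated by e^{αt}; waiting times are drawn by inverting the
cumulative hazard in closed form. The two-deme demography coalesces each
deme independently up to the split depth, then merges the surviving
lineages; migration is not modeled — a clean split is the minimal structure
needed to test PCA/clustering recovery.

Mutations fall on branches as a Poisson process of rate θ/2 per unit branch
length, infinite-sites: every mutation is a new column. Consequences used
throughout the tests: E[T₂] = 1, E[S] = θ·a_{k−1} for k haplotypes
(a_k the k-th harmonic number), and E[per-locus pairwise difference] = θ.
The simulator is cross-checked in the test suite against msprime (matched
parameterization: population size 1/2, mutation rate θ/2 on a unit-length
continuous genome) with a chi-square comparison of pooled folded spectra at
α = 0.01; msprime is only ever an oracle, never the implementation.

Per-locus streams are seeded as `(seed, locus_index)`, so output is
bit-reproducible and loci are individually addressable.

Default study conditions mirror the target regime: 11–12 diploids, θ = 2
per 10 kb locus, ~10 % of loci labelled Z. The flatness and estimator
recovery checks use 2,000 loci — enough that every Monte-Carlo standard
error is small relative to a 5 % band while the whole suite runs in well
under a minute.

### Depth model

Per-variant depth is negative binomial (mean 22.7×, dispersion 8) with a
Pareto-tailed outlier mixture (2 % of variants, scale 6×, shape 1.5). The
mixture guarantees a wide gap between the median and the 90th percentile,
emulating the repeat-driven right tail of real resequencing depth
distributions; without it a percentile ceiling would be indistinguishable
from a constant cutoff. Depth is written as `INFO/DP`.

### Synthetic rearrangement and mitogenome fixtures

The coordinate-table generator tiles each truth segment with contiguous
high-identity blocks (normal around 94 %, clipped to [75, 99.9]) and adds
spurious blocks that are short (< 500 bp) and low-identity (< 70 %), i.e.
below the "distant" filter thresholds by construction, so recovery of the
truth map is exact when the filters work. Minus-strand segments are emitted
with reversed query coordinates, as alignment coordinate tables do.

Mitogenome alignments evolve on a constant-size coalescent under infinite
sites; designated ranges are overwritten with monomorphic homopolymer runs
in every sequence so that masking them is observable only through alignment
length, mimicking the monomeric/repeat regions excluded before diversity
estimation.

## Depth filter

The retention rule keeps a variant iff DP lies in the closed interval
[min_dp, ceiling]. The interval is closed at both ends: when a published
description mixes strict prose ("exceeds 10×") with closed bracket notation
("[10; 346]"), the bracket describing the actual retained set wins. The
ceiling is the nearest-rank (inverse-ECDF) empirical quantile — the smallest
observed value with at least a fraction q of the sample at or below it —
computed once on the pre-filter distribution (one pass, not iterated).
Nearest-rank is exact and reproducible on integer depths, where
interpolating definitions give non-observed values. DP comes from `INFO/DP`
when present, else the sum of `FORMAT/DP`; the source used is recorded in
the filter report.

## Diversity statistics

S counts sites with both alleles present among the non-missing genotypes of
the selected samples. Missing data reduces the local allele-copy count m
(pairwise-complete) rather than dropping the site. For nuclear data the
sequence count n in Watterson's estimator is 2 × diploids; for
mitochondrial data it is the number of individuals. Effective lengths for
per-site normalization default to contig lengths from the VCF header; a
callable-sites override is accepted, since "sequence length" is otherwise
assembly-dependent.

Note that a heterozygous site in an otherwise identical set of diploids is
segregating among the 2n allele copies; "identical clones give zero
diversity" holds for homozygous clones.

## Folded SFS and transform

η_i counts sites at minor-allele copy i ∈ [1, n]; ties at exactly 50 %
frequency belong to class n. Sites with any missing genotype in the subset
are excluded (no hypergeometric projection — out of scope). The flattening
transform weights classes by i(2n−i)/(2n) for i < n and by n for i = n,
then renormalizes. This is the unique reading of the published (typo-bearing)
formula under which the constant-size expectation
η_i ∝ 1/i + 1/(2n−i) = 2n/(i(2n−i)) becomes flat at 1/n — verified
analytically in the tests, and the flat-at-1/11 behaviour for 11 diploids is
checked by simulation with batch-means standard errors (20 batches of 100
loci). The default replication sample size is 11 diploids because the flat
reference 1/11 implies 11 folded classes; the count is a parameter.

## Mitogenome statistics

Mask ranges are 1-based inclusive alignment columns, removed with union
semantics. Columns containing a gap or IUPAC ambiguity (including
heteroplasmy codes such as R) in any sequence are excluded from S and π
(complete deletion, the convention of the standard desktop tool for such
tables); p-distance uses pairwise-complete columns, so with a clean
alignment π equals the mean p-distance exactly. Hd uses the sample-size
corrected form n(1 − Σp²)/(n − 1).

## Synteny assignment

Filters are strict (identity > 70 %, length > 500 bp for a diverged
reference; > 80 % and > 10 kb for a close relative, where repeat-driven
noise dominates); the link floor is inclusive (≥ 500). A "unique link" is a
deduplicated filtered block keyed by its exact reference and query
intervals. Overlap is summed on the reference side (renaming is
reference-anchored). Ties in overlap break by larger link count, then
lexicographically smaller reference label, for determinism. Query
chromosomes sharing a reference assignment — the norm when the query
karyotype is more fragmented — are suffixed a, b, … by descending overlap.
Query segments are ordered by the median of their reference-side block
midpoints within natural-sorted reference chromosomes.

## Structure

PCA centers each site at its mean dosage 2p̂ and scales by the binomial
standard deviation √(2p̂(1−p̂)); monomorphic sites and sites with > 20 %
missingness are dropped, and missing genotypes are mean-imputed for the
decomposition only. Scores are U·Σ from the SVD of the scaled matrix; when
fewer informative sites than requested components exist, trailing components
are zero. The dissimilarity is 1 − mean IBS over pairwise-complete sites,
with per-site IBS = 1 − |g_a − g_b|/2; a pair with no shared genotyped sites
is an error naming the pair. Clustering is agglomerative with average
linkage (UPGMA) — the default of the workflow the design follows — and
groups are read off by cutting at a fixed height; the dendrogram is exported
as an ultrametric newick with merge heights as node depths.

## Numerical and degenerate-input choices

- Genotype dosages are int8 with −1 as the missing code.
- Transform normalization is exact to 1e−12 (assertion in tests).
- An empty VCF body yields a 0-variant matrix, not an error; a filter on it
  reports NaN ceiling.
- θ = 0 simulations produce structurally valid, variant-free outputs.
- VCF positions are uniform integers on the locus window, deduplicated by
  resampling and sorted, so positions are strictly increasing per
  chromosome.

## Limitations

- The simulator omits recombination within loci, selection, sequencing
  error, and genotype-likelihood uncertainty: passing recovery tests shows
  the estimators are correct under the neutral model, not that real-data
  filtering artefacts are handled.
- Z loci are simulated as diploid in all samples; female hemizygosity is not
  modeled (a documented simplification — the handling in the motivating
  analysis is unstated).
- SFS projection for missing data, ancestral polarization, Tajima's D, Fst
  and sliding windows are out of scope.
- The synteny stage consumes alignment coordinates; it does not run the
  aligner, and exports link tables rather than rendering circos figures.
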