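# Methods

This note documents the models, estimators and numerical choices behind
`vitnet`, and what the synthetic data generator does and does not emulate.

## Data model

Inputs are (a) per-locus multiple sequence alignments of diploid Sanger
consensus sequences, heterozygous positions coded with the two-fold IUPAC
codes K/M/R/S/W/Y and missing data as N or '-'; (b) a biallelic SNP matrix
coded 0/1/2 on the alternate-allele count with per-SNP metadata
(discovery panel ∈ {vinifera, american, muscadinia}; genome ∈ {nuclear,
chloroplast}); (c) an accession table with clade labels from the closed
vocabulary {EA, EU, NA1, NA2, CAL, OUT, UNKNOWN} and known-hybrid flags;
(d) trait tables (continuous leaf measures, ordinal OIV descriptors); and
(e) newick trees.  Coordinates are 0-based half-open internally; 1-based
only in human-readable reports.

## Diversity statistics (popgen_stats)

Site classification scans the diploid consensus columns and counts only
unambiguous bases, treating IUPAC heterozygote codes as missing — this
mirrors how alignment-viewer software reports variable sites and therefore
*understates* polymorphism relative to the phased haplotypes; the phased
segregating-site counts are the ones used for θ estimation.

All haplotype statistics use **pairwise deletion** of missing data: each
haplotype pair is compared over the sites where both carry a called state,
and per-pair differences are divided by that comparable-site count.  The
mean pairwise difference entering Tajima's D is rescaled to a count by the
mean comparable length, keeping π and D on a consistent basis.  An
alternative (complete deletion) changes θ/π by at most the missing fraction;
the choice is recorded in the output metadata.  Haplotype identity for
tallies is exact string match after excluding columns missing in any
haplotype — deterministic, at the cost of slightly merging haplotypes in
very gappy data.

Fay & Wu's H is the unnormalized θπ − θH with
θH = Σ 2i²Sᵢ/(n(n−1)) over derived-allele counts; the ancestral state is
the majority base across the outgroup haplotypes, and sites with a tied or
missing outgroup, or more than two states, are excluded.  Monomorphic loci
yield an explicitly undefined D (never silently 0).

## Phasing (phasing)

Phase is inferred per locus by an Excoffier–Slatkin EM on haplotype
frequencies: each individual's probability mass is distributed over the
haplotype pairs compatible with its genotype (missing sites summed over
completions), with 10 restarts, ≤500 iterations, log-likelihood tolerance
1e-8, a fixed seed, and lexicographic tie-breaking — fully deterministic.
Individuals with more than `max_het_sites` (default 16) ambiguous sites are
excluded from frequency estimation and phased by a surrogate rule: the most
frequent population haplotype compatible with their genotype is paired with
the implied complement, scored by the product of the two frequencies.

Because the amplicons are short and effectively non-recombining, EM
frequencies alone are weakly informative when both of an individual's
haplotypes are rare.  A **four-gamete refinement** therefore post-processes
every double-heterozygous site pair: phase-obvious individuals (at most one
of the two sites heterozygous) reveal the gametes present in the sample;
under the no-recombination (perfect-phylogeny) assumption at most three of
the four gametes exist, and the observed gamete table dictates the cis/trans
configuration.  Ties or absent evidence keep the EM phase.  The refinement
never alters the implied genotypes, and on coalescent simulations at the
package's test conditions (40 diploids, locus θ = 10, no recombination) it
reduces the switch-error rate from ~10% (plain EM) to ~3.5%.  The
inter-haplotype difference count d̄ used for hybrid detection is invariant
to phase (it equals the heterozygous-site count), so hybrid detection does
not depend on this refinement.

## Median-joining networks (hapnet)

Networks start from the minimum spanning network (all minimal alternative
links; tolerance ε, default 0) over the distinct haplotypes.  Candidate
median vectors are the per-site majority consensus of node triplets
(well-defined because sites are at most biallelic after upstream
filtering).  A median is accepted only if adding it **strictly reduces the
minimum spanning cost of the whole node set** — a global criterion, chosen
over the local triplet-cost rule after the latter proved able to add medians
that lengthen the network.  On networks of ≤14 nodes a bounded two-median
lookahead also runs, since a pair of Steiner points can pay off where
neither does alone; on larger networks the single-candidate greedy applies.
Inferred nodes of final degree ≤2 are pruned (their incident edges merge by
re-deriving the spanning links), observed nodes never are.  Everything is
deterministic: candidates are ranked by (cost gain, lexicographic sequence).
Node-for-node identity with any particular published drawing is not claimed;
the testable surface is total network cost (checked against exhaustive
Steiner enumeration on small inputs) and clade-adjacency structure.

## Distance trees and ascertainment (distance_trees)

Sequence distances are raw p-distances on the diploid consensus with
allele-sharing treatment: per site, 1 − (shared alleles)/2, so a
heterozygote against a homozygote sharing one allele contributes 0.5.  Array
distances are 1 − IBS (mean |gᵢ−gⱼ|/2 over shared SNPs).  No evolutionary
model correction is applied — the analyses read topology, support and
relative branch length, not absolute rates.  Trees are Saitou–Nei NJ
(scikit-bio); negative branch estimates are clamped to zero and logged.
Bootstrap (default B = 100) resamples alignment columns or SNPs with
replacement; support is the percentage of replicates containing each
internal bipartition, computed from canonicalized tip-name bipartitions so
results are invariant to taxon order.  For branch-length summaries the tree
is rooted on the edge above the outgroup MRCA and each clade's mean
root-to-tip length is reported as a ratio to the ingroup-wide mean; in the
subsampling experiment the discovery-panel clade's ratio falls monotonically
as panel SNPs are removed.

## Hybrid inference (hybrid_inference)

d̄ is the mean over sequenced loci of the Hamming distance between an
accession's two haplotypes.  Outliers are flagged by the standard boxplot
fence (value > Q3 + 1.5·IQR, linear-interpolation quartiles) within the
accession's clade group; groups under 4 members are tested against the
pooled distribution.  Parental clades: per locus, each haplotype maps to the
clade of its nearest labeled haplotype (ties across clades → UNKNOWN), with
the accession itself, known hybrids and all flagged accessions excluded
from the labeled pools; a clade qualifies as parental when it appears in at
least 25% of informative loci — the threshold exists so a single
homoplasious locus cannot fabricate a second parent.  An accession is
*called* a hybrid only when it is both a d̄ outlier and resolves two
distinct parental clades; this two-stage rule is what keeps false-positive
calls near zero even though boxplot fences on small groups flag mild
outliers regularly.

Chlorotypes are multilocus genotypes over the chloroplast-flagged SNPs that
are biallelic across the sample; heterozygous plastid calls are treated as
missing (array artifacts on a haploid genome).  Collapse is single-linkage
at ≤ t mismatches (default 1) over shared non-missing loci, implemented
with a union-find chain (the mismatch measure with missing data is not a
metric, so generic linkage code is not appropriate).  The maternal parent of
a hybrid is the parental clade whose pure members share its collapsed
chlorotype group; if both share it the result is UNKNOWN (reported with the
sharing clades), if neither, UNKNOWN plus the nearest-chlorotype clade —
the ambiguous narrative cases are reported, not adjudicated.

## Morphometrics and phylogenetic signal (morpho_signal)

Trait preparation takes the median per accession per parameter, then
averages left/right paired parameters, and derives circularity per leaf
before the median.  PCA is an eigendecomposition of the correlation matrix
by default (unit-variance scaling — the natural choice for mixed-unit
morphometric tables; covariance PCA is available by flag); OIV ordinal codes
are treated as numeric.  Abouheif's proximity between two tips is the
inverse product of the number of direct descendants of each internal node on
the path; C_mean is the Moran-type form z'Wz/z'z with the row-normalized
proximity and a one-sided upper permutation p with the +1 correction
(999 permutations, seeded).  pPCA diagonalizes (1/n)·X'W_sym·X with X
centered/scaled and W_sym the symmetrized row-normalized proximity; with
W = I this reduces exactly to correlation PCA, which is the identity used to
test it.  Positive eigenvalues are labeled global, negative local.
Top-loading selection keeps traits below the 10th or above the 90th loading
quantile (all traits when fewer than 10).

## Synthetic data (synthetic_data)

The generator emulates the study's structure: 5 ingroup clades + outgroup,
2 species per clade, 2 accessions per species (3 for the outgroup), 12 loci
of 600 bp, and three planted F1 hybrids (EU×NA1, EA×EU, NA1×NA2) whose
chloroplast comes from the configured maternal clade and whose clade label
groups them with that clade, as unrecognized hybrids would be.  Sequence
divergence is nested Jukes–Cantor-style Poisson mutation: the configured
rates are *total expected pairwise* divergences — 0.02/site between clades,
0.008 within clades, 0.004 within species (≈2.4 differences per locus) —
realized per level as half-rates on each lineage; a 5% per-locus accession
dropout reproduces varying per-locus sample sizes.  The SNP array has 800
panel-ascertained SNPs (segregating only within the EU discovery clade, 80%
at the species level and 20% private to one haplotype) and 200 panel-free
SNPs spread over clade/species/haplotype levels, with 2% missing calls.
The chloroplast is a 23-position non-recombining haplotype: three diagnostic
positions per clade (pairwise distance ≥6 between clades) plus one
clade-private position toggled by each clade's second species, so
chlorotypes collapse exactly into clades at one mismatch.  Traits follow
hierarchical Brownian motion (clade shift sd 2.0, species shift sd 0.7,
accession noise sd 0.5) for 8 signal traits next to 4 pure-noise traits,
with per-leaf replicates (6 leaves, sd 0.3) and paired left/right angle
columns for the preparation stage.

What the generator does **not** emulate: recombination within loci
(appropriate for short Sanger amplicons), a full coalescent genealogy
(within-species variation is star-shaped, so linkage patterns inside species
are simpler than reality), backcrosses or later-generation hybrids,
selection, and shared ancestral polymorphism between clades in the array
(ascertained SNPs are strictly clade-private).  Passing tests therefore
demonstrate the machinery's correctness and its behavior under clean
F1-between-divergent-clades conditions — not performance on introgressed or
recently diverged material.

## Problem sizes and determinism

The default synthetic dataset is a scaled-down panel (26 accessions,
12×600 bp, ~1000 array SNPs), chosen so that replicate end-to-end analyses
(50 seeds in the recovery tests, plus bootstrap trees at B = 100) remain
desk-scale while keeping every qualitative regime of the full study: clade
separation ≫ within-clade diversity, hybrid d̄ ≈ 4–6× the pure range, EU
root-to-tip ratio > 3 on the full ascertained array falling toward 1 at the
smallest panel subset.  Every stochastic component (simulation, EM restarts,
bootstrap, permutations, subsampling) consumes an explicit seed, and
identical configurations are byte-identical on disk.

## Known limitations

- The outlier fence on 4–5-member clade groups is noisy; detection relies on
  the parental-clade confirmation step rather than the fence alone.
- Fay & Wu's H is reported unnormalized; magnitudes are comparable across
  loci of similar length only.
- Within-clade hybrids (parents from the same clade) are out of scope by
  design: their d̄ does not separate from the clade background.
- The pPCA variant is the symmetrized, uniformly-weighted one; this is
  flagged in the result metadata since other row-weighting conventions
  exist.
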