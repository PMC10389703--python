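# vitnet

Multi-locus diversity, haplotype networks, hybrid detection and
phylogenetic-signal analysis for grape (*Vitis*) germplasm panels.

## The problem

The grape genus *Vitis* comprises five well-supported clades — East Asian
(EA), European (EU, *V. vinifera*), two North American (NA1, NA2) and the
isolated *V. californica* (CAL) — plus the *Muscadinia* outgroup (OUT).
Species in the genus are interfertile, so germplasm collections contain
natural and artificial interspecific hybrids that blur phylogenies built
from pooled data.  `vitnet` implements an integrated workflow for panels of
Sanger-sequenced nuclear amplicons, SNP-array genotypes and morphometric
traits:

1. **Per-locus diversity** on phased haplotypes: segregating sites *S*,
   haplotype counts, Watterson's θ<sub>W</sub> = *S*/(a₁·*L*), nucleotide
   diversity π, gene diversity *H*<sub>e</sub> = *n*/(*n*−1)·(1−Σp²),
   Tajima's *D* and Fay & Wu's *H* = θ<sub>π</sub> − θ<sub>H</sub>
   (outgroup-oriented), with MEGA-style site classification
   (variable / parsimony-informative / singleton) on the diploid consensus.
2. **Haplotype phasing** of IUPAC-coded diploid consensus sequences by an
   Excoffier–Slatkin EM on haplotype frequencies, followed by a four-gamete
   refinement suited to non-recombining amplicons.
3. **Median-joining haplotype networks** (minimum spanning network plus
   cost-reducing median vectors) with clade-colored nodes.
4. **Hybrid detection**: an F1 between clades carries one haplotype from
   each parent at every locus, so its mean inter-haplotype difference d̄ is
   a Tukey-fence outlier within its clade's boxplot; parental clades are
   assigned per locus by nearest-clade haplotype matching, and the cross
   direction (female parent) comes from the maternally inherited chloroplast
   haplotype (chlorotype), after single-linkage collapse of chlorotypes at
   one mismatch.
5. **Distance phylogenies**: p-distance / allele-sharing (1 − IBS) matrices,
   Saitou–Nei neighbor joining, column-resampling bootstrap supports, and an
   SNP-subsampling experiment quantifying how a discovery-panel-ascertained
   array inflates the panel clade's branch lengths.
6. **Morphometrics & phylogenetic signal**: leaf-measure preparation
   (median per accession, left/right averaging, circularity
   Circ = 4π·area/perimeter²), scaled PCA, Abouheif's C<sub>mean</sub>
   permutation test, phylogenetic PCA (positive eigenvalues = global,
   clade-level structure), and top-loading trait selection by the 10%/90%
   loading quantiles.
7. **Synthetic data**: a generator producing the full data bundle (loci,
   array, chlorotypes, traits, tree) with ground truth, so every stage is
   testable without external downloads.

## Worked example

```python
from vitnet.synthetic_data import SimConfig, simulate
from vitnet.pipeline import phase_all_loci
from vitnet.hybrid_inference import hybrid_report

ds = simulate(SimConfig(seed=1))          # 26 accessions, 12 loci, 3 planted F1s
hs = phase_all_loci(ds.loci, seed=1)
reports = hybrid_report(hs, ds.accessions, gm=ds.genotypes)
for r in reports:
    if r.outlier:
        print(f"{r.accession}: dbar={r.dbar:.1f} group={r.clade_group} "
              f"parents={r.parental_clades} maternal={r.maternal_clade}")
```

prints

```
CAL_sp2_a1: dbar=2.8 group=CAL parents=('CAL', 'CAL') maternal=CAL
HYB1: dbar=11.5 group=NA1 parents=('EU', 'NA1') maternal=NA1
HYB2: dbar=11.8 group=EA parents=('EA', 'EU') maternal=EA
HYB3: dbar=11.8 group=NA2 parents=('NA1', 'NA2') maternal=NA2
```

The three planted F1 hybrids stand out with d̄ ≈ 11–12 inter-haplotype
differences per locus (pure accessions range 1.7–2.9), their parental clade
pairs are recovered from the phased haplotypes, and the maternal clade
matches the chloroplast haplotype each hybrid inherited.  `CAL_sp2_a1` is a
mild within-clade boxplot outlier, but both of its haplotypes map to its own
clade, so it is not called a hybrid — the two-stage rule (outlier *and*
distinct parental clades) is what keeps precision high.

## Command line

```bash
vitnet simulate out/ --seed 1        # synthetic dataset + manifest.json + truth
vitnet run bundle/ --manifest out/manifest.json --seed 1
vitnet diversity out/manifest.json   # Table-1-style per-locus diversity TSV
vitnet hybrids out/manifest.json     # d̄ outliers, parents, maternal clades
vitnet tree out/manifest.json        # bootstrap NJ trees (all / hybrid-free)
vitnet phase out/manifest.json       # per-locus phased haplotype FASTA
```

`vitnet run` executes every stage in dependency order (diversity → phasing →
hybrids → networks → trees → ascertainment → morphometrics), re-runs the
trees without known plus newly detected hybrids, and writes a JSON/TSV
report bundle stamped with seeds and parameters.

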