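"""Synthetic datasets with the statistical structure of a *Vitis*-style
germplasm panel, with ground truth for every downstream stage.

The generator emulates: five ingroup clades plus an outgroup; per-locus
Sanger-style diploid consensus sequences (IUPAC heterozygote codes) whose
divergence is nested — between clades > between species within a clade >
between haplotypes within a species; F1 hybrids carrying one haplotype from
each parental clade and the maternal clade's chloroplast haplotype; an SNP
array whose majority panel was ascertained inside one clade (polymorphic
only there) plus a panel-free minority; clade-diagnostic chloroplast SNPs;
and traits evolving as hierarchical Brownian motion on the species tree
(clade shift + species shift + accession noise) next to pure-noise traits.

Divergence parameters are *total expected pairwise* differences per site at
the corresponding level, so `between_clade_divergence` is directly the
expected p-distance between accessions of different clades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    AccessionTable,
    GenotypeMatrix,
    IUPAC_HET,
    LocusAlignment,
    TraitTable,
    write_accessions,
    write_fasta_alignment,
    write_genotypes,
    write_newick,
    write_traits,
)

INGROUP_CLADES = ("EA", "EU", "NA1", "NA2", "CAL")
_BASES = "ACGT"
_HET_CODE = {frozenset(v): k for k, v in IUPAC_HET.items()}


@dataclass
class HybridSpec:
    parent1: str
    parent2: str
    maternal: str  # must equal parent1 or parent2

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise ValueError("hybrid parents must be distinct clades")
        if self.maternal not in (self.parent1, self.parent2):
            raise ValueError("maternal clade must be one of the parents")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_clades: int = 5
    species_per_clade: int = 2
    accessions_per_species: int = 2
    outgroup_accessions: int = 3
    n_loci: int = 12
    locus_length: int = 600
    between_clade_divergence: float = 0.02
    within_clade_divergence: float = 0.008
    within_species_theta: float = 0.004
    outgroup_divergence: float = 0.05
    locus_dropout: float = 0.05
    hybrids: list[HybridSpec] = field(
        default_factory=lambda: [
            HybridSpec("EU", "NA1", "NA1"),
            HybridSpec("EA", "EU", "EA"),
            HybridSpec("NA1", "NA2", "NA2"),
        ]
    )
    panel_clade: str = "EU"
    n_panel_snps: int = 800
    n_other_snps: int = 200
    n_cp_snps: int = 23
    array_missing_rate: float = 0.02
    n_signal_traits: int = 8
    n_noise_traits: int = 4
    clade_bm_sd: float = 2.0
    species_bm_sd: float = 0.7
    accession_noise_sd: float = 0.5
    leaves_per_accession: int = 6
    leaf_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_clades < 1 or self.n_clades > len(INGROUP_CLADES):
            raise ValueError("n_clades must be between 1 and 5")
        clades = set(INGROUP_CLADES[: self.n_clades])
        for h in self.hybrids:
            if not {h.parent1, h.parent2} <= clades:
                raise ValueError(
                    f"hybrid parents {h.parent1}/{h.parent2} outside the "
                    f"configured clades {sorted(clades)}"
                )
        if self.hybrids and self.n_clades < 2:
            raise ValueError("hybrids require at least 2 clades")
        for rate in (
            self.between_clade_divergence,
            self.within_clade_divergence,
            self.within_species_theta,
            self.outgroup_divergence,
        ):
            if rate < 0:
                raise ValueError("divergence rates must be nonnegative")

    @property
    def clades(self) -> list[str]:
        return list(INGROUP_CLADES[: self.n_clades])


@dataclass
class SimTruth:
    clade_of: dict[str, str]
    species_of: dict[str, str]
    hybrids: list[dict]
    true_haplotypes: dict[str, dict[str, tuple[str, str]]]
    chlorotype_of_clade: dict[str, str]
    tree_newick: str

    def to_json(self) -> str:
        d = asdict(self)
        d["true_haplotypes"] = {
            locus: {a: list(pair) for a, pair in accs.items()}
            for locus, accs in self.true_haplotypes.items()
        }
        return json.dumps(d, indent=1)


@dataclass
class SyntheticDataset:
    config: SimConfig
    loci: dict[str, LocusAlignment]
    genotypes: GenotypeMatrix
    accessions: AccessionTable
    leaf_traits: TraitTable
    oiv_traits: TraitTable
    per_leaf_raw: pd.DataFrame
    tree: TreeNode
    truth: SimTruth

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"loci": {}, "roles": {}}
        for locus, aln in self.loci.items():
            p = outdir / f"{locus}.fasta"
            write_fasta_alignment(aln, p)
            manifest["loci"][locus] = p.name
        write_genotypes(
            self.genotypes, outdir / "genotypes.tsv", outdir / "snp_meta.tsv"
        )
        write_accessions(self.accessions, outdir / "accessions.tsv")
        write_traits(self.leaf_traits, outdir / "leaf_traits.tsv")
        write_traits(self.oiv_traits, outdir / "oiv_traits.tsv")
        self.per_leaf_raw.to_csv(outdir / "per_leaf_raw.tsv", sep="\t",
                                 index=False)
        write_newick(self.tree, outdir / "species_tree.nwk")
        (outdir / "truth.json").write_text(self.truth.to_json())
        manifest["roles"] = {
            "genotypes": "genotypes.tsv",
            "snp_meta": "snp_meta.tsv",
            "accessions": "accessions.tsv",
            "leaf_traits": "leaf_traits.tsv",
            "oiv_traits": "oiv_traits.tsv",
            "per_leaf_raw": "per_leaf_raw.tsv",
            "tree": "species_tree.nwk",
            "truth": "truth.json",
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return outdir / "manifest.json"


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-style point mutations: Poisson(rate * L) events at
    uniform sites, each to a uniformly chosen different base."""
    out = seq.copy()
    n_mut = rng.poisson(rate * len(seq))
    if n_mut:
        sites = rng.integers(0, len(seq), size=n_mut)
        shifts = rng.integers(1, 4, size=n_mut)
        out[sites] = (out[sites] + shifts) % 4
    return out


def _consensus(h1: np.ndarray, h2: np.ndarray) -> str:
    out = []
    for a, b in zip(h1, h2):
        if a == b:
            out.append(_BASES[a])
        else:
            out.append(_HET_CODE[frozenset((_BASES[a], _BASES[b]))])
    return "".join(out)


def simulate(config: SimConfig) -> SyntheticDataset:
    """Generate one dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    clades = config.clades

    # --- accession roster ---------------------------------------------------
    species_of: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    species_by_clade: dict[str, list[str]] = {}
    pure_accessions: list[str] = []
    for clade in clades + ["OUT"]:
        n_sp = 1 if clade == "OUT" else config.species_per_clade
        n_acc = (
            config.outgroup_accessions
            if clade == "OUT"
            else config.accessions_per_species
        )
        species_by_clade[clade] = []
        for s in range(n_sp):
            sp = f"{clade}_sp{s + 1}"
            species_by_clade[clade].append(sp)
            for a in range(n_acc):
                acc = f"{sp}_a{a + 1}"
                species_of[acc] = sp
                clade_of[acc] = clade
                pure_accessions.append(acc)
    hybrid_specs = []
    hybrid_accessions = []
    for i, h in enumerate(config.hybrids):
        acc = f"HYB{i + 1}"
        hybrid_accessions.append(acc)
        clade_of[acc] = h.maternal  # grouped with its maternal clade
        species_of[acc] = "unknown"
        # maternal species: first species of the maternal clade
        sp1 = rng.choice(species_by_clade[h.parent1])
        sp2 = rng.choice(species_by_clade[h.parent2])
        maternal_sp = sp1 if h.maternal == h.parent1 else sp2
        hybrid_specs.append(
            {
                "accession": acc,
                "parent1": h.parent1,
                "parent2": h.parent2,
                "parent1_species": str(sp1),
                "parent2_species": str(sp2),
                "maternal": h.maternal,
                "maternal_species": str(maternal_sp),
            }
        )
    all_accessions = pure_accessions + hybrid_accessions

    # per-level branch rates (expected pairwise divergence is the sum of the
    # two lineages' rates at the deepest level separating them)
    d_hap = config.within_species_theta / 2.0
    d_sp = max(config.within_clade_divergence - config.within_species_theta,
               0.0) / 2.0
    d_cl = max(config.between_clade_divergence
               - config.within_clade_divergence, 0.0) / 2.0
    d_out = max(config.outgroup_divergence
                - config.within_clade_divergence, 0.0) / 2.0

    # --- sequence loci -------------------------------------------------------
    loci: dict[str, LocusAlignment] = {}
    true_haps: dict[str, dict[str, tuple[str, str]]] = {}
    for li in range(config.n_loci):
        locus = f"locus{li + 1:02d}"
        L = config.locus_length
        root = rng.integers(0, 4, size=L).astype(np.int8)
        clade_anc = {
            c: _mutate(root, d_out if c == "OUT" else d_cl, rng)
            for c in clades + ["OUT"]
        }
        species_anc = {
            sp: _mutate(clade_anc[c], d_sp, rng)
            for c in clades + ["OUT"]
            for sp in species_by_clade[c]
        }

        def draw_hap(sp: str) -> np.ndarray:
            return _mutate(species_anc[sp], d_hap, rng)

        pair_of: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for acc in pure_accessions:
            pair_of[acc] = (draw_hap(species_of[acc]),
                            draw_hap(species_of[acc]))
        for spec in hybrid_specs:
            pair_of[spec["accession"]] = (
                draw_hap(spec["parent1_species"]),
                draw_hap(spec["parent2_species"]),
            )
        # locus dropout: some accessions were not sequenced at this locus
        present = [
            a
            for a in all_accessions
            if rng.random() >= config.locus_dropout
        ]
        if len(present) < 4:
            present = all_accessions
        seqs = [_consensus(*pair_of[a]) for a in present]
        loci[locus] = LocusAlignment(locus, list(present), seqs)
        true_haps[locus] = {
            a: (
                "".join(_BASES[x] for x in pair_of[a][0]),
                "".join(_BASES[x] for x in pair_of[a][1]),
            )
            for a in present
        }

    # --- nuclear array SNPs ---------------------------------------------------
    # Each SNP is one mutation on a branch of the nested hierarchy; the set of
    # haplotype "slots" below that branch carries the derived allele.
    # slots: (accession, 0|1); hybrids expose their parental species per slot.
    slot_species: dict[tuple[str, int], str] = {}
    slot_clade: dict[tuple[str, int], str] = {}
    for acc in pure_accessions:
        for k in (0, 1):
            slot_species[(acc, k)] = species_of[acc]
            slot_clade[(acc, k)] = clade_of[acc]
    for spec in hybrid_specs:
        acc = spec["accession"]
        slot_species[(acc, 0)] = spec["parent1_species"]
        slot_clade[(acc, 0)] = spec["parent1"]
        slot_species[(acc, 1)] = spec["parent2_species"]
        slot_clade[(acc, 1)] = spec["parent2"]
    all_slots = sorted(slot_species)

    def snp_column(level: str, target: str | tuple) -> np.ndarray:
        col = np.zeros(len(all_accessions))
        for i, acc in enumerate(all_accessions):
            g = 0
            for k in (0, 1):
                if level == "clade" and slot_clade[(acc, k)] == target:
                    g += 1
                elif level == "species" and slot_species[(acc, k)] == target:
                    g += 1
                elif level == "hap" and (acc, k) == target:
                    g += 1
            col[i] = g
        return col

    snp_cols, snp_ids, snp_panels = [], [], []
    panel_species = species_by_clade[config.panel_clade]
    panel_slots = [s for s in all_slots
                   if slot_species[s] in panel_species
                   and s[0] in pure_accessions]
    for i in range(config.n_panel_snps):
        # ascertained: the mutation segregates within the discovery clade
        if rng.random() < 0.8 and len(panel_species) > 1:
            target_sp = panel_species[rng.integers(0, len(panel_species))]
            col = snp_column("species", target_sp)
        else:
            target = panel_slots[rng.integers(0, len(panel_slots))]
            col = snp_column("hap", target)
        snp_cols.append(col)
        snp_ids.append(f"snp_panel_{i + 1:05d}")
        snp_panels.append("vinifera")
    non_panel_clades = [c for c in clades + ["OUT"]]
    for i in range(config.n_other_snps):
        u = rng.random()
        if u < 0.5:
            target_c = non_panel_clades[rng.integers(0, len(non_panel_clades))]
            col = snp_column("clade", target_c)
        elif u < 0.8:
            all_species = [sp for c in non_panel_clades
                           for sp in species_by_clade[c]]
            col = snp_column("species",
                             all_species[rng.integers(0, len(all_species))])
        else:
            col = snp_column("hap", all_slots[rng.integers(0, len(all_slots))])
        snp_cols.append(col)
        snp_ids.append(f"snp_other_{i + 1:05d}")
        snp_panels.append("american")

    # --- chloroplast SNPs -----------------------------------------------------
    # clade-diagnostic blocks of 3 positions; the second and later species of
    # each clade toggle one extra clade-private position, so collapsing at one
    # mismatch merges chlorotypes exactly into clades.
    n_cp = max(config.n_cp_snps, 3 * (len(clades) + 1))
    cp_of_species: dict[str, np.ndarray] = {}
    all_clades = clades + ["OUT"]
    for ci, c in enumerate(all_clades):
        base = np.zeros(n_cp, dtype=int)
        base[3 * ci: 3 * ci + 3] = 1
        for si, sp in enumerate(species_by_clade[c]):
            v = base.copy()
            extra = 3 * len(all_clades) + ci
            if si > 0 and extra < n_cp:
                v[extra] = 1
            cp_of_species[sp] = v
    cp_calls = np.zeros((len(all_accessions), n_cp))
    for i, acc in enumerate(all_accessions):
        if acc in dict((s["accession"], s) for s in hybrid_specs):
            spec = next(s for s in hybrid_specs if s["accession"] == acc)
            v = cp_of_species[spec["maternal_species"]]
        else:
            v = cp_of_species[species_of[acc]]
        cp_calls[i] = 2.0 * v  # haploid genome reported as homozygous calls
    cp_ids = [f"cp_{i + 1:02d}" for i in range(n_cp)]

    calls = np.column_stack(snp_cols + [cp_calls[:, j] for j in range(n_cp)])
    # array missing data on nuclear SNPs only
    n_nuc = len(snp_ids)
    miss = rng.random(size=(len(all_accessions), n_nuc)) < config.array_missing_rate
    calls[:, :n_nuc][miss] = np.nan
    meta = pd.DataFrame(
        {
            "discovery_panel": snp_panels + ["american"] * n_cp,
            "genome": ["nuclear"] * n_nuc + ["chloroplast"] * n_cp,
        },
        index=pd.Index(snp_ids + cp_ids, name="snp_id"),
    )
    genotypes = GenotypeMatrix(list(all_accessions), snp_ids + cp_ids,
                               calls, meta)

    # --- accession table ------------------------------------------------------
    acc_df = pd.DataFrame(
        {
            "species_label": [species_of[a] for a in all_accessions],
            "clade_label": [clade_of[a] for a in all_accessions],
            "known_hybrid": [False] * len(all_accessions),
        },
        index=pd.Index(all_accessions, name="accession"),
    )
    accessions = AccessionTable(acc_df)

    # --- species tree (pure accessions as tips) -------------------------------
    def tip(name: str, bl: float) -> str:
        return f"{name}:{bl:.6f}"

    clade_subtrees = []
    for c in all_clades:
        sp_subtrees = []
        for sp in species_by_clade[c]:
            accs = [a for a in pure_accessions if species_of[a] == sp]
            inner = ",".join(tip(a, d_hap) for a in accs)
            sp_subtrees.append(f"({inner}):{d_sp:.6f}")
        depth = d_out if c == "OUT" else d_cl
        clade_subtrees.append(f"({','.join(sp_subtrees)}):{depth:.6f}")
    newick = f"({','.join(clade_subtrees)});"
    tree = TreeNode.read([newick], format="newick",
                         convert_underscores=False)

    # --- traits ---------------------------------------------------------------
    trait_names = [f"trait{i + 1:02d}" for i in range(config.n_signal_traits)]
    noise_names = [f"noise{i + 1:02d}" for i in range(config.n_noise_traits)]
    values = {}
    for t in trait_names:
        clade_shift = {c: rng.normal(0, config.clade_bm_sd)
                       for c in all_clades}
        sp_shift = {sp: rng.normal(0, config.species_bm_sd)
                    for c in all_clades for sp in species_by_clade[c]}
        values[t] = [
            clade_shift[clade_of[a]]
            + sp_shift[species_of[a]]
            + rng.normal(0, config.accession_noise_sd)
            for a in pure_accessions
        ]
    for t in noise_names:
        values[t] = list(rng.normal(0, 1, size=len(pure_accessions)))
    leaf_df = pd.DataFrame(values,
                           index=pd.Index(pure_accessions, name="accession"))
    leaf_traits = TraitTable(
        leaf_df,
        {t: "length" for t in trait_names} | {t: "ratio" for t in noise_names},
    )
    # OIV-style ordinal recoding of the same generative signal
    oiv_df = pd.DataFrame(index=leaf_df.index)
    for t in leaf_df.columns:
        z = (leaf_df[t] - leaf_df[t].mean()) / max(leaf_df[t].std(ddof=0), 1e-9)
        oiv_df["OIV_" + t] = np.clip(np.round(5 + 2 * z), 1, 9).astype(int)
    oiv_traits = TraitTable(
        oiv_df, {c: "morphology" for c in oiv_df.columns}
    )

    # per-leaf raw measurements for the preparation stage: two paired angle
    # halves, one length, and area/perimeter for circularity
    rows = []
    for a in pure_accessions:
        base_len = 50.0 + 5.0 * leaf_df.loc[a, trait_names[0]]
        for leaf in range(config.leaves_per_accession):
            r = max(base_len + rng.normal(0, config.leaf_noise_sd), 1.0)
            elong = 1.0 + abs(rng.normal(0.2, 0.05))
            area = np.pi * r * r / elong
            perimeter = 2 * np.pi * r * (0.98 + 0.04 * rng.random())
            rows.append(
                {
                    "accession": a,
                    "leaf": leaf + 1,
                    "vein_length": r,
                    "angle_left": 45 + rng.normal(0, 2),
                    "angle_right": 45 + rng.normal(0, 2),
                    "area": area,
                    "perimeter": perimeter,
                }
            )
    per_leaf_raw = pd.DataFrame(rows)

    truth = SimTruth(
        clade_of=clade_of,
        species_of=species_of,
        hybrids=hybrid_specs,
        true_haplotypes=true_haps,
        chlorotype_of_clade={
            c: "".join(str(x) for x in cp_of_species[species_by_clade[c][0]])
            for c in all_clades
        },
        tree_newick=newick,
    )
    return SyntheticDataset(
        config, loci, genotypes, accessions, leaf_traits, oiv_traits,
        per_leaf_raw, tree, truth,
    )
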