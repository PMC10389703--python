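"""Readers, writers and core tables for the multi-locus *Vitis* pipeline.

The pipeline consumes per-locus FASTA alignments of diploid Sanger consensus
sequences (heterozygous positions encoded with two-fold IUPAC codes), a
biallelic SNP genotype matrix with per-SNP metadata, an accession table with
clade labels, trait tables, and newick trees.  Everything here is plain
plumbing: parsing, validation, concatenation and round-trip-stable TSV/newick
/GML output.  Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: two-fold IUPAC heterozygote codes and the unordered allele pair they encode
IUPAC_HET: dict[str, tuple[str, str]] = {
    "K": ("G", "T"),
    "M": ("A", "C"),
    "R": ("A", "G"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "Y": ("C", "T"),
}
BASES = frozenset("ACGT")
MISSING_CHARS = frozenset("N-?")
ALLOWED_CHARS = BASES | set(IUPAC_HET) | MISSING_CHARS

#: closed vocabulary of clade labels
CLADES = ("EA", "EU", "NA1", "NA2", "CAL", "OUT", "UNKNOWN")


def expand_site(char: str) -> tuple[str, str] | None:
    """Unordered diploid allele pair encoded by one consensus character.

    Returns ``None`` for missing data (N, '-', '?').
    """
    if char in BASES:
        return (char, char)
    if char in IUPAC_HET:
        return IUPAC_HET[char]
    if char in MISSING_CHARS:
        return None
    raise ValueError(f"illegal alignment character {char!r}")


@dataclass
class LocusAlignment:
    """Aligned IUPAC consensus sequences for one locus across accessions."""

    locus_name: str
    accession_ids: list[str]
    sequences: list[str]
    #: for concatenated alignments: locus -> (start, end), 0-based half-open
    locus_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.accession_ids) != len(self.sequences):
            raise ValueError("accession_ids and sequences length mismatch")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError(f"{self.locus_name}: duplicate accession ids")
        if self.sequences:
            L = len(self.sequences[0])
            for acc, seq in zip(self.accession_ids, self.sequences):
                if len(seq) != L:
                    raise ValueError(
                        f"{self.locus_name}: ragged alignment, record {acc!r} "
                        f"has length {len(seq)} != {L}"
                    )
                bad = set(seq) - ALLOWED_CHARS
                if bad:
                    raise ValueError(
                        f"{self.locus_name}: record {acc!r} contains illegal "
                        f"character(s) {sorted(bad)}"
                    )
        if not self.locus_boundaries:
            self.locus_boundaries = {self.locus_name: (0, self.length_bp)}

    @property
    def length_bp(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def sequence_of(self, accession_id: str) -> str:
        return self.sequences[self.accession_ids.index(accession_id)]

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.sequences]

    def drop_gap_columns(self) -> "LocusAlignment":
        """Remove every column containing at least one '-' (indel editing)."""
        keep = [
            j
            for j in range(self.length_bp)
            if all(s[j] != "-" for s in self.sequences)
        ]
        seqs = ["".join(s[j] for j in keep) for s in self.sequences]
        return LocusAlignment(self.locus_name, list(self.accession_ids), seqs)


def read_fasta_alignment(
    path: str | Path, locus_name: str, drop_gaps: bool = False
) -> LocusAlignment:
    """Load one locus alignment from FASTA, uppercasing and validating."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    aln = LocusAlignment(
        locus_name,
        [r.id for r in records],
        [str(r.seq).upper() for r in records],
    )
    return aln.drop_gap_columns() if drop_gaps else aln


def write_fasta_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in zip(aln.accession_ids, aln.sequences):
            fh.write(f">{acc}\n{seq}\n")


def concatenate(
    alignments: list[LocusAlignment], id_policy: str = "union_fill_N"
) -> LocusAlignment:
    """Concatenate per-locus alignments into one supermatrix.

    ``id_policy='intersection'`` keeps only accessions present at every locus;
    ``'union_fill_N'`` keeps all accessions and pads absent ones with N.  Per
    locus boundaries are recorded as 0-based half-open intervals.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    if id_policy == "intersection":
        ids = [a for a in alignments[0].accession_ids
               if all(a in aln.accession_ids for aln in alignments[1:])]
        if not ids:
            raise ValueError("empty accession intersection across loci")
    elif id_policy == "union_fill_N":
        ids = []
        for aln in alignments:
            for a in aln.accession_ids:
                if a not in ids:
                    ids.append(a)
    else:
        raise ValueError(f"unknown id_policy {id_policy!r}")

    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    parts: dict[str, list[str]] = {a: [] for a in ids}
    for aln in alignments:
        L = aln.length_bp
        boundaries[aln.locus_name] = (pos, pos + L)
        pos += L
        lookup = dict(zip(aln.accession_ids, aln.sequences))
        for a in ids:
            parts[a].append(lookup.get(a, "N" * L))
    return LocusAlignment(
        "+".join(a.locus_name for a in alignments),
        ids,
        ["".join(parts[a]) for a in ids],
        locus_boundaries=boundaries,
    )


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes (alternate-allele counts 0/1/2, NaN = missing)."""

    accession_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # float array, shape (n_accessions, n_snps)
    snp_meta: pd.DataFrame  # indexed by snp_id; discovery_panel, genome, ...

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accession_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match id lists")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        missing_meta = set(self.snp_ids) - set(self.snp_meta.index)
        if missing_meta:
            raise ValueError(f"SNPs without metadata: {sorted(missing_meta)[:5]}")

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.calls).mean())

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            list(self.accession_ids), list(snp_ids),
            self.calls[:, idx], self.snp_meta.loc[snp_ids],
        )

    def subset_accessions(self, accession_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.accession_ids.index(a) for a in accession_ids]
        return GenotypeMatrix(
            list(accession_ids), list(self.snp_ids),
            self.calls[idx, :], self.snp_meta,
        )

    def chloroplast_snp_ids(self) -> list[str]:
        return [s for s in self.snp_ids
                if self.snp_meta.loc[s, "genome"] == "chloroplast"]

    def nuclear_snp_ids(self) -> list[str]:
        return [s for s in self.snp_ids
                if self.snp_meta.loc[s, "genome"] == "nuclear"]


def read_genotypes(path: str | Path, meta_path: str | Path) -> GenotypeMatrix:
    """Read an accessions x SNPs TSV (values 0/1/2/NA) plus SNP metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return GenotypeMatrix(
        [str(a) for a in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        meta.loc[[str(s) for s in df.columns]],
    )


def write_genotypes(
    gm: GenotypeMatrix, path: str | Path, meta_path: str | Path
) -> None:
    df = pd.DataFrame(gm.calls, index=gm.accession_ids, columns=gm.snp_ids)
    # keep integers readable; NaN renders as empty -> read back as missing
    df.to_csv(path, sep="\t", float_format="%.0f", index_label="accession")
    gm.snp_meta.to_csv(meta_path, sep="\t", index_label="snp_id")


@dataclass
class AccessionTable:
    """Accession metadata: species, clade (closed vocabulary), hybrid flag."""

    df: pd.DataFrame  # indexed by accession_id

    REQUIRED = ("species_label", "clade_label", "known_hybrid")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"accession table missing column {col!r}")
        if self.df.index.duplicated().any():
            raise ValueError("duplicate accession ids")
        bad = set(self.df["clade_label"]) - set(CLADES)
        if bad:
            raise ValueError(f"unknown clade labels {sorted(bad)}")

    @property
    def accession_ids(self) -> list[str]:
        return [str(a) for a in self.df.index]

    def clade_of(self, accession_id: str) -> str:
        return str(self.df.loc[accession_id, "clade_label"])

    def is_known_hybrid(self, accession_id: str) -> bool:
        return bool(self.df.loc[accession_id, "known_hybrid"])

    def members(self, clade: str, include_hybrids: bool = False) -> list[str]:
        sel = self.df["clade_label"] == clade
        if not include_hybrids:
            sel &= ~self.df["known_hybrid"].astype(bool)
        return [str(a) for a in self.df.index[sel]]


def read_accessions(path: str | Path) -> AccessionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["known_hybrid"] = df["known_hybrid"].astype(bool)
    return AccessionTable(df)


def write_accessions(table: AccessionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="accession")


@dataclass
class TraitTable:
    """Numeric trait values per accession (continuous measures or OIV codes)."""

    values: pd.DataFrame  # accessions x traits
    trait_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated trait names")

    @property
    def accession_ids(self) -> list[str]:
        return [str(a) for a in self.values.index]

    @property
    def trait_names(self) -> list[str]:
        return [str(t) for t in self.values.columns]

    def align_to(self, accession_ids: list[str]) -> "TraitTable":
        """Restrict/reorder rows, dropping (with a warning) unknown accessions."""
        known = [a for a in accession_ids if a in self.values.index]
        extra = set(self.values.index) - set(accession_ids)
        if extra:
            logger.warning(
                "dropping %d trait rows absent from accession metadata: %s",
                len(extra), sorted(extra)[:5],
            )
        return TraitTable(self.values.loc[known], dict(self.trait_types))


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    types = {}
    if df.index.name == "trait_type" or "trait_type" in df.index:
        # optional first row carrying per-trait type labels
        types = {c: str(df.loc["trait_type", c]) for c in df.columns}
        df = df.drop(index="trait_type").astype(float)
    return TraitTable(df.astype(float), types)


def write_traits(tt: TraitTable, path: str | Path) -> None:
    df = tt.values.copy()
    if tt.trait_types:
        header = pd.DataFrame(
            [ [tt.trait_types.get(c, "") for c in df.columns] ],
            index=pd.Index(["trait_type"], name=df.index.name),
            columns=df.columns,
        )
        df = pd.concat([header, df])
    df.to_csv(path, sep="\t", index_label="accession")


def read_newick(path: str | Path) -> TreeNode:
    # keep underscores verbatim: accession ids use them as separators
    return TreeNode.read(str(path), format="newick",
                         convert_underscores=False)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_network_gml(net, path: str | Path) -> None:
    """Export a haplotype network (`hapnet.HaploNetwork`) as GML."""
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(
            node.node_id,
            sequence=node.sequence,
            multiplicity=node.multiplicity,
            inferred=int(node.inferred),
            clades=";".join(sorted(node.clades)),
        )
    for u, v, w in net.edges:
        g.add_edge(u, v, weight=int(w))
    nx.write_gml(g, str(path))
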