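"""Interspecific hybrid detection and cross-direction inference.

An F1 between two clades carries one haplotype from each parent at every
nuclear locus, so its mean inter-haplotype difference (dbar) is an outlier
within its clade group (Tukey fence on the clade's boxplot).  Parental clades
are then read off the phased haplotypes by nearest-clade assignment against
labeled non-hybrid pools, and the cross direction comes from the maternally
inherited chloroplast haplotype (chlorotype): the parental clade whose pure
members share the hybrid's (collapsed) chlorotype group is the female parent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .hapnet import nearest_clade
from .io_formats import AccessionTable, GenotypeMatrix
from .phasing import HaplotypeSet, interhap_differences

logger = logging.getLogger(__name__)


# --- dbar statistic and outlier rule ---------------------------------------


def dbar_statistic(
    haplotype_sets: dict[str, HaplotypeSet]
) -> dict[str, float]:
    """Mean over loci of inter-haplotype Hamming differences per accession.

    Loci where an accession was not sequenced simply do not contribute.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for hs in haplotype_sets.values():
        for acc, d in interhap_differences(hs).items():
            sums[acc] = sums.get(acc, 0.0) + d
            counts[acc] = counts.get(acc, 0) + 1
    return {acc: sums[acc] / counts[acc] for acc in sums}


def flag_outliers(
    values: dict[str, float],
    grouping: dict[str, str],
    min_group_size: int = 4,
    k: float = 1.5,
) -> dict[str, bool]:
    """Tukey boxplot rule per group: value > Q3 + k*IQR flags an outlier.

    Groups smaller than ``min_group_size`` are tested against the pooled
    distribution instead (logged).  Quartiles use linear interpolation.
    """
    groups: dict[str, list[str]] = {}
    for acc in values:
        groups.setdefault(grouping.get(acc, "UNKNOWN"), []).append(acc)
    pooled = np.array(list(values.values()), dtype=float)
    flags: dict[str, bool] = {}
    for gname, members in groups.items():
        vals = np.array([values[a] for a in members], dtype=float)
        if len(members) < min_group_size:
            logger.info(
                "group %s has %d members; using pooled distribution",
                gname, len(members),
            )
            ref = pooled
        else:
            ref = vals
        q1, q3 = np.quantile(ref, [0.25, 0.75])
        fence = q3 + k * (q3 - q1)
        for a in members:
            flags[a] = bool(values[a] > fence)
    return flags


# --- parental clade assignment ---------------------------------------------


def labeled_haplotype_pool(
    hs: HaplotypeSet,
    accessions: AccessionTable,
    exclude: set[str],
) -> list[tuple[str, str]]:
    """(haplotype, clade) pairs from non-hybrid labeled accessions."""
    pool = []
    for acc in hs.accession_ids:
        if acc in exclude:
            continue
        if acc not in accessions.accession_ids:
            continue
        if accessions.is_known_hybrid(acc):
            continue
        clade = accessions.clade_of(acc)
        if clade == "UNKNOWN":
            continue
        for h in hs.pairs[acc]:
            pool.append((h, clade))
    return pool


def assign_parents(
    accession: str,
    haplotype_sets: dict[str, HaplotypeSet],
    accessions: AccessionTable,
    extra_exclude: set[str] | None = None,
    min_locus_support: float = 0.25,
) -> tuple[tuple[str, str], dict[str, tuple[str, str]]]:
    """Parental clade pair for one accession from per-locus nearest clades.

    Per locus each of the two haplotypes is mapped to the clade of its
    nearest labeled haplotype (the accession itself, known hybrids and any
    ``extra_exclude`` members are removed from the pool).  A clade qualifies
    as parental when it appears in at least ``min_locus_support`` of the
    informative loci; the two most frequent qualifying clades form the pair
    (a single qualifying clade is returned doubled; none -> UNKNOWN pair).
    """
    exclude = {accession} | (extra_exclude or set())
    per_locus: dict[str, tuple[str, str]] = {}
    clade_locus_count: Counter = Counter()
    n_informative = 0
    for locus, hs in haplotype_sets.items():
        if accession not in hs.pairs:
            continue
        pool = labeled_haplotype_pool(hs, accessions, exclude)
        if not pool:
            continue
        h1, h2 = hs.pairs[accession]
        c1, _ = nearest_clade(h1, pool)
        c2, _ = nearest_clade(h2, pool)
        per_locus[locus] = (c1, c2)
        n_informative += 1
        for c in set((c1, c2)) - {"UNKNOWN"}:
            clade_locus_count[c] += 1
    if n_informative == 0:
        return ("UNKNOWN", "UNKNOWN"), per_locus
    qualified = [
        c
        for c, cnt in clade_locus_count.most_common()
        if cnt >= min_locus_support * n_informative
    ]
    if not qualified:
        pair = ("UNKNOWN", "UNKNOWN")
    elif len(qualified) == 1:
        pair = (qualified[0], qualified[0])
    else:
        pair = tuple(sorted(qualified[:2]))
    return pair, per_locus


# --- array heterozygosity ---------------------------------------------------


def array_heterozygosity(gm: GenotypeMatrix) -> dict[str, float]:
    """Fraction of non-missing SNP calls that are heterozygous, per accession."""
    out = {}
    for i, acc in enumerate(gm.accession_ids):
        row = gm.calls[i]
        obs = ~np.isnan(row)
        out[acc] = float((row[obs] == 1).mean()) if obs.any() else float("nan")
    return out


# --- chlorotypes ------------------------------------------------------------


@dataclass
class ChlorotypeAssignment:
    accession: str
    chlorotype_id: int
    snp_string: str  # over informative chloroplast loci; '.' = missing
    collapsed_group_id: int | None = None


def define_chlorotypes(
    gm: GenotypeMatrix,
) -> tuple[list[ChlorotypeAssignment], list[str]]:
    """Multilocus chloroplast genotypes.

    Heterozygous calls are treated as missing (a plastid locus cannot be
    heterozygous; such calls are array artifacts).  Only loci biallelic
    across the sample are kept.  Accessions with identical strings share a
    chlorotype; accessions missing at every informative locus are left
    unassigned (logged).  Returns (assignments, informative_snp_ids).
    """
    cp_ids = gm.chloroplast_snp_ids()
    if not cp_ids:
        raise ValueError("no chloroplast-flagged SNPs")
    sub = gm.subset_snps(cp_ids)
    calls = sub.calls.copy()
    calls[calls == 1] = np.nan  # het -> missing on a haploid genome
    informative = []
    for j, s in enumerate(cp_ids):
        states = set(calls[~np.isnan(calls[:, j]), j])
        if len(states) == 2:
            informative.append(j)
    inf_ids = [cp_ids[j] for j in informative]
    strings: dict[str, str] = {}
    for i, acc in enumerate(gm.accession_ids):
        chars = []
        for j in informative:
            v = calls[i, j]
            chars.append("." if np.isnan(v) else ("0" if v == 0 else "1"))
        s = "".join(chars)
        if s and set(s) == {"."}:
            logger.info("%s: missing at all informative cpDNA loci", acc)
            continue
        strings[acc] = s
    # identical strings share an id; ids ordered by first occurrence
    seen: dict[str, int] = {}
    assignments = []
    for acc, s in strings.items():
        if s not in seen:
            seen[s] = len(seen)
        assignments.append(ChlorotypeAssignment(acc, seen[s], s))
    return assignments, inf_ids


def _mismatches(a: str, b: str) -> int | None:
    """Mismatch count over loci non-missing in both; None when none shared."""
    shared = [(x, y) for x, y in zip(a, b) if x != "." and y != "."]
    if not shared:
        return None
    return sum(1 for x, y in shared if x != y)


def collapse_chlorotypes(
    assignments: list[ChlorotypeAssignment], threshold: int = 1
) -> list[ChlorotypeAssignment]:
    """Single-linkage collapse of chlorotypes at <= ``threshold`` mismatches.

    Group id = smallest chlorotype id in the group (stable, deterministic).
    Annotates and returns the assignments.
    """
    chloro: dict[int, str] = {}
    for a in assignments:
        chloro.setdefault(a.chlorotype_id, a.snp_string)
    ids = sorted(chloro)
    parent = {i: i for i in ids}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in ids:
        for j in ids:
            if j <= i:
                continue
            d = _mismatches(chloro[i], chloro[j])
            if d is not None and d <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    group_of = {i: find(i) for i in ids}
    for a in assignments:
        a.collapsed_group_id = group_of[a.chlorotype_id]
    return assignments


def infer_maternal(
    accession: str,
    parental_clades: tuple[str, str],
    assignments: list[ChlorotypeAssignment],
    accessions: AccessionTable,
) -> tuple[str, dict]:
    """Maternal clade of a hybrid from collapsed chlorotype sharing.

    The maternal clade is the parental clade whose pure (non-hybrid) members
    share the hybrid's collapsed chlorotype group.  Both parents sharing ->
    UNKNOWN; neither -> UNKNOWN plus the nearest clade by chlorotype distance
    in the evidence dict.
    """
    by_acc = {a.accession: a for a in assignments}
    if accession not in by_acc:
        return "UNKNOWN", {"reason": "no chlorotype"}
    mine = by_acc[accession]
    sharing: set[str] = set()
    for a in assignments:
        if a.accession == accession:
            continue
        if a.collapsed_group_id != mine.collapsed_group_id:
            continue
        if a.accession not in accessions.accession_ids:
            continue
        if accessions.is_known_hybrid(a.accession):
            continue
        sharing.add(accessions.clade_of(a.accession))
    candidates = set(parental_clades) - {"UNKNOWN"}
    shared_parents = sharing & candidates
    evidence = {"clades_sharing_group": sorted(sharing)}
    if len(shared_parents) == 1:
        return shared_parents.pop(), evidence
    if len(shared_parents) > 1:
        evidence["reason"] = "both parental clades share the chlorotype group"
        return "UNKNOWN", evidence
    # neither parent shares: report nearest clade by chlorotype distance
    best = None
    for a in assignments:
        if a.accession == accession or a.accession not in accessions.accession_ids:
            continue
        if accessions.is_known_hybrid(a.accession):
            continue
        d = _mismatches(mine.snp_string, a.snp_string)
        if d is None:
            continue
        clade = accessions.clade_of(a.accession)
        if best is None or d < best[0]:
            best = (d, clade)
    if best is not None:
        evidence["nearest_chlorotype_clade"] = best[1]
        evidence["nearest_chlorotype_distance"] = best[0]
    evidence["reason"] = "no parental clade shares the chlorotype group"
    return "UNKNOWN", evidence


# --- report -----------------------------------------------------------------


@dataclass
class HybridReport:
    accession: str
    dbar: float
    clade_group: str
    outlier: bool
    parental_clades: tuple[str, str] = ("UNKNOWN", "UNKNOWN")
    maternal_clade: str = "UNKNOWN"
    evidence: dict = field(default_factory=dict)
    array_het: float | None = None

    @property
    def is_hybrid_call(self) -> bool:
        """Detected interspecific hybrid: dbar outlier whose two parental
        clades resolved to distinct labels."""
        p1, p2 = self.parental_clades
        return self.outlier and p1 != p2 and "UNKNOWN" not in (p1, p2)


def hybrid_report(
    haplotype_sets: dict[str, HaplotypeSet],
    accessions: AccessionTable,
    gm: GenotypeMatrix | None = None,
    chlorotype_collapse_threshold: int = 1,
) -> list[HybridReport]:
    """Full hybrid-detection pass: dbar outliers per clade group, parental
    clades for flagged or known hybrids, and maternal clade from cpDNA."""
    dbar = dbar_statistic(haplotype_sets)
    grouping = {
        acc: (accessions.clade_of(acc) if acc in accessions.accession_ids
              else "UNKNOWN")
        for acc in dbar
    }
    flags = flag_outliers(dbar, grouping)
    het = array_heterozygosity(gm) if gm is not None else {}
    assignments: list[ChlorotypeAssignment] = []
    if gm is not None and gm.chloroplast_snp_ids():
        assignments, _ = define_chlorotypes(gm)
        collapse_chlorotypes(assignments, chlorotype_collapse_threshold)

    flagged = {a for a, f in flags.items() if f}
    known = {a for a in accessions.accession_ids
             if accessions.is_known_hybrid(a)}
    reports = []
    for acc in sorted(dbar):
        rep = HybridReport(
            accession=acc,
            dbar=dbar[acc],
            clade_group=grouping[acc],
            outlier=flags[acc],
            array_het=het.get(acc),
        )
        if acc in flagged | known:
            pair, per_locus = assign_parents(
                acc, haplotype_sets, accessions, extra_exclude=flagged
            )
            rep.parental_clades = pair
            rep.evidence["per_locus_clades"] = per_locus
            if assignments and pair != ("UNKNOWN", "UNKNOWN"):
                maternal, ev = infer_maternal(acc, pair, assignments, accessions)
                rep.maternal_clade = maternal
                rep.evidence["chlorotype"] = ev
        reports.append(rep)
    return reports
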