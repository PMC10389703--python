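"""Distance matrices, neighbor-joining trees with bootstrap support, and the
SNP-panel subsampling experiment used to probe ascertainment bias.

Sequence distances are raw p-distances on diploid consensus sequences with
allele-sharing treatment of heterozygotes (a het vs a homozygote sharing one
allele contributes 0.5).  Array distances are allele-sharing distances
(1 - IBS) on 0/1/2 genotypes.  Trees are Saitou-Nei NJ (scikit-bio); support
values are the percentage of bootstrap replicates (columns/SNPs resampled
with replacement) containing each internal bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj

from .io_formats import (
    AccessionTable,
    GenotypeMatrix,
    IUPAC_HET,
    BASES,
    LocusAlignment,
)

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and nonnegative")
        self.matrix = m

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.matrix, ids=self.ids)


@dataclass
class SupportTree:
    """Unrooted NJ tree with branch lengths and bootstrap supports (0-100)."""

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    def tip_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


# --- pairwise distances ----------------------------------------------------


def _encode_diploid(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per site, the two alleles (as small ints) and an observed mask."""
    code = {b: i for i, b in enumerate("ACGT")}
    a1 = np.zeros(len(seq), dtype=np.int8)
    a2 = np.zeros(len(seq), dtype=np.int8)
    obs = np.zeros(len(seq), dtype=bool)
    for j, c in enumerate(seq):
        if c in BASES:
            a1[j] = a2[j] = code[c]
            obs[j] = True
        elif c in IUPAC_HET:
            x, y = IUPAC_HET[c]
            a1[j], a2[j] = code[x], code[y]
            obs[j] = True
    return a1, a2, obs


def site_difference_table(
    aln: LocusAlignment,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per (pair, site) allele-sharing difference scores and comparability.

    Returns ``(scores, comparable, pair_index)`` with scores in {0, .5, 1}:
    the fraction of non-shared alleles between the two unordered diploid
    genotypes at the site.  This is the bootstrap workhorse: resampling
    columns of these tables re-derives any replicate's distance matrix.
    """
    enc = [_encode_diploid(s) for s in aln.sequences]
    n = len(enc)
    L = aln.length_bp
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    scores = np.zeros((len(pairs), L), dtype=np.float32)
    comp = np.zeros((len(pairs), L), dtype=bool)
    for p, (i, j) in enumerate(pairs):
        a1, a2, oi = enc[i]
        b1, b2, oj = enc[j]
        both = oi & oj
        comp[p] = both
        # shared allele count between multisets {a1,a2} and {b1,b2}
        eq11 = a1 == b1
        eq12 = a1 == b2
        eq21 = a2 == b1
        eq22 = a2 == b2
        shared = np.zeros(L, dtype=np.float32)
        # direct matching of the two unordered pairs
        shared += np.where(eq11 & eq22, 2.0, 0.0)
        alt = eq12 & eq21
        shared = np.maximum(shared, np.where(alt, 2.0, 0.0))
        one = eq11 | eq12 | eq21 | eq22
        shared = np.maximum(shared, np.where(one, 1.0, 0.0))
        scores[p] = np.where(both, 1.0 - shared / 2.0, 0.0)
    return scores, comp, pairs


def seq_distance(aln: LocusAlignment) -> DistanceMatrix:
    """p-distance over comparable sites, heterozygotes as half-differences."""
    if aln.n_accessions < 3:
        raise ValueError("need at least 3 accessions")
    scores, comp, pairs = site_difference_table(aln)
    n = aln.n_accessions
    m = np.zeros((n, n))
    n_comp = comp.sum(axis=1)
    for p, (i, j) in enumerate(pairs):
        if n_comp[p] == 0:
            raise ValueError(
                f"no comparable sites between {aln.accession_ids[i]} and "
                f"{aln.accession_ids[j]}"
            )
        m[i, j] = m[j, i] = scores[p].sum() / n_comp[p]
    return DistanceMatrix(list(aln.accession_ids), m)


def snp_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance 1 - IBS: mean |g_i - g_j| / 2 over shared SNPs."""
    calls = gm.calls
    n = len(gm.accession_ids)
    m = np.zeros((n, n))
    obs = ~np.isnan(calls)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise ValueError(
                    f"no shared SNPs between {gm.accession_ids[i]} and "
                    f"{gm.accession_ids[j]}"
                )
            m[i, j] = m[j, i] = float(
                np.abs(calls[i, both] - calls[j, both]).mean() / 2.0
            )
    return DistanceMatrix(list(gm.accession_ids), m)


# --- trees -----------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    tree = nj(dm.to_skbio())
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return SupportTree(tree)


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller tip-name side."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_tree(
    resample_fn,
    n_items: int,
    B: int = 100,
    seed: int = 1,
) -> SupportTree:
    """Generic column-resampling bootstrap.

    ``resample_fn(idx)`` must return a :class:`DistanceMatrix` for the given
    resampled column index array (``idx=None`` -> original data).
    """
    base = nj_tree(resample_fn(None))
    if len(base.tip_names()) < 4:
        return base
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        idx = rng.integers(0, n_items, size=n_items)
        rep = nj_tree(resample_fn(idx))
        for bp in tree_bipartitions(rep.tree):
            counts[bp] = counts.get(bp, 0) + 1
    supports = {
        bp: 100.0 * counts.get(bp, 0) / B
        for bp in tree_bipartitions(base.tree)
    }
    base.supports = supports
    return base


def bootstrap_seq_tree(
    aln: LocusAlignment, B: int = 100, seed: int = 1
) -> SupportTree:
    """Site-resampling bootstrap NJ tree from a (concatenated) alignment."""
    scores, comp, pairs = site_difference_table(aln)
    n = aln.n_accessions
    ids = list(aln.accession_ids)

    def resample(idx):
        s = scores if idx is None else scores[:, idx]
        c = comp if idx is None else comp[:, idx]
        m = np.zeros((n, n))
        denom = c.sum(axis=1)
        num = (s * c).sum(axis=1)
        for p, (i, j) in enumerate(pairs):
            if denom[p] == 0:
                raise ValueError("bootstrap replicate with empty comparison")
            m[i, j] = m[j, i] = num[p] / denom[p]
        return DistanceMatrix(ids, m)

    return bootstrap_tree(resample, aln.length_bp, B=B, seed=seed)


def bootstrap_snp_tree(
    gm: GenotypeMatrix, B: int = 100, seed: int = 1
) -> SupportTree:
    """SNP-resampling bootstrap NJ tree from an array genotype matrix."""
    calls = gm.calls
    n = len(gm.accession_ids)
    obs = ~np.isnan(calls)
    filled = np.nan_to_num(calls, nan=0.0)
    ids = list(gm.accession_ids)

    def resample(idx):
        c = filled if idx is None else filled[:, idx]
        o = obs if idx is None else obs[:, idx]
        m = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(c[i] - c[i + 1:]) / 2.0
            both = o[i] & o[i + 1:]
            denom = both.sum(axis=1)
            if np.any(denom == 0):
                raise ValueError("pair sharing zero SNPs in replicate")
            vals = (diff * both).sum(axis=1) / denom
            m[i, i + 1:] = vals
            m[i + 1:, i] = vals
        return DistanceMatrix(ids, m)

    return bootstrap_tree(resample, len(gm.snp_ids), B=B, seed=seed)


# --- ascertainment experiment ----------------------------------------------


def subsample_by_panel(
    gm: GenotypeMatrix, panel_class: str, target_count: int, seed: int = 1
) -> GenotypeMatrix:
    """Keep a uniform random ``target_count`` subset of the SNPs discovered
    in ``panel_class``; all other SNPs are retained unchanged."""
    in_class = [
        s for s in gm.snp_ids
        if gm.snp_meta.loc[s, "discovery_panel"] == panel_class
    ]
    if target_count > len(in_class):
        raise ValueError(
            f"target {target_count} exceeds {len(in_class)} "
            f"available {panel_class} SNPs"
        )
    rng = np.random.default_rng(seed)
    kept = set(
        np.array(in_class)[
            rng.choice(len(in_class), size=target_count, replace=False)
        ]
    )
    snp_ids = [s for s in gm.snp_ids if s not in set(in_class) - kept]
    return gm.subset_snps(snp_ids)


def clade_branch_summary(
    stree: SupportTree, accessions: AccessionTable, outgroup_clade: str = "OUT"
) -> dict[str, dict[str, float]]:
    """Mean root-to-tip path length per clade, outgroup-rooted.

    The tree is rooted on the edge above the outgroup MRCA; ratios are taken
    against the overall ingroup mean.
    """
    tree = stree.tree
    tips = {t.name for t in tree.tips()}
    out_tips = [a for a in accessions.members(outgroup_clade, True) if a in tips]
    if not out_tips:
        raise ValueError("no outgroup accessions in tree")
    if len(out_tips) == 1:
        og_node = tree.find(out_tips[0])
    else:
        og_node = tree.lowest_common_ancestor(out_tips)
    rooted = tree.root_at(og_node, above=True, reset=True)

    depths: dict[str, float] = {}
    for tip in rooted.tips():
        depths[tip.name] = tip.accumulate_to_ancestor(rooted)
    ingroup = [
        a for a in depths
        if a in accessions.accession_ids
        and accessions.clade_of(a) != outgroup_clade
    ]
    overall = float(np.mean([depths[a] for a in ingroup]))
    out: dict[str, dict[str, float]] = {}
    for clade in sorted({accessions.clade_of(a) for a in ingroup}):
        vals = [depths[a] for a in ingroup if accessions.clade_of(a) == clade]
        mean = float(np.mean(vals))
        out[clade] = {
            "mean_root_to_tip": mean,
            "ratio_vs_overall": mean / overall if overall > 0 else float("nan"),
            "n": len(vals),
        }
    return out
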