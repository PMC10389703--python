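"""Per-locus diversity statistics on phased haplotypes.

Implements the classical summaries reported per sequenced locus: segregating
sites S, haplotype counts, Watterson's theta (per site), nucleotide diversity
pi (per site, pairwise deletion of missing data), haplotype diversity He,
Tajima's D and Fay & Wu's H, plus MEGA-style site classification on the
diploid consensus alignment (where IUPAC heterozygote codes are treated as
missing, so the diploid counts understate the phased polymorphism).

Missing-data policy: haplotype comparisons use pairwise deletion — each pair
of haplotypes is compared over the sites where both carry an unambiguous
base; per-pair differences are normalized by that comparable-site count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BASES, LocusAlignment, MISSING_CHARS


@dataclass
class SiteClassCounts:
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_sites_scanned: int

    def __post_init__(self) -> None:
        assert self.n_variable == self.n_parsimony_informative + self.n_singleton


def classify_sites(aln: LocusAlignment) -> SiteClassCounts:
    """Count variable / parsimony-informative / singleton columns.

    Only unambiguous bases (A,C,G,T) are considered; two-fold IUPAC codes,
    N and '-' are treated as missing at the column.  A column is variable if
    at least two distinct bases occur; parsimony-informative if at least two
    bases each occur in at least two sequences; a singleton otherwise.
    """
    if aln.length_bp == 0:
        raise ValueError("zero-length alignment")
    n_var = n_pi = 0
    for j in range(aln.length_bp):
        counts = Counter(c for c in aln.column(j) if c in BASES)
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
    return SiteClassCounts(n_var, n_pi, n_var - n_pi, aln.length_bp)


# ---------------------------------------------------------------------------
# haplotype-level statistics.  Haplotypes are plain strings; characters in
# MISSING_CHARS are missing, anything else is an observed state.


def _state_matrix(haplotypes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode haplotypes as (codes, observed-mask) integer arrays."""
    arr = np.array([list(h) for h in haplotypes])
    observed = ~np.isin(arr, list(MISSING_CHARS))
    return arr, observed


def segregating_sites(haplotypes: list[str]) -> int:
    """Number of columns with >= 2 observed states among the haplotypes."""
    if not haplotypes:
        return 0
    arr, obs = _state_matrix(haplotypes)
    S = 0
    for j in range(arr.shape[1]):
        if len(set(arr[obs[:, j], j])) >= 2:
            S += 1
    return S


def haplotype_tally(haplotypes: list[str]) -> Counter:
    """Group identical haplotypes.

    Identity is exact string match after removing every column that is
    missing in any haplotype (deterministic "distinct sequences" rule).
    """
    arr, obs = _state_matrix(haplotypes)
    keep = obs.all(axis=0)
    keys = ["".join(row[keep]) for row in arr]
    return Counter(keys)


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a1 * L), a1 = sum_{1}^{n-1} 1/i."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L < 1:
        raise ValueError("need at least 1 site")
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * L)


def _pairwise_diffs(haplotypes: list[str]) -> tuple[float, float]:
    """(mean per-site difference over pairs, mean comparable-site count).

    Pairs with zero comparable sites are skipped.
    """
    arr, obs = _state_matrix(haplotypes)
    n = len(haplotypes)
    per_site, comparable = [], []
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                continue
            d = int((arr[i, both] != arr[j, both]).sum())
            per_site.append(d / m)
            comparable.append(m)
    if not per_site:
        raise ValueError("no comparable haplotype pairs")
    return float(np.mean(per_site)), float(np.mean(comparable))


def nucleotide_diversity(haplotypes: list[str]) -> float:
    """pi: mean per-site pairwise difference with pairwise deletion."""
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 haplotypes")
    return _pairwise_diffs(haplotypes)[0]


def haplotype_diversity(counts: Counter | list[int], n: int | None = None) -> float:
    """Unbiased gene diversity He = n/(n-1) * (1 - sum p_k^2)."""
    values = list(counts.values()) if isinstance(counts, Counter) else list(counts)
    total = sum(values)
    if n is None:
        n = total
    if n < 2:
        raise ValueError("need n >= 2")
    p2 = sum((c / total) ** 2 for c in values)
    return n / (n - 1) * (1.0 - p2)


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(haplotypes: list[str]) -> float | None:
    """Tajima's (1989) D; ``None`` when the locus is monomorphic.

    The mean pairwise difference is computed per site with pairwise deletion
    and rescaled to a count by the mean comparable-site length, keeping the
    missing-data treatment consistent with pi.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    S = segregating_sites(haplotypes)
    if S == 0:
        return None
    k_per_site, L_comp = _pairwise_diffs(haplotypes)
    big_pi = k_per_site * L_comp
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (big_pi - S / c["a1"]) / math.sqrt(var)


def fay_wu_h(haplotypes: list[str], outgroup_haplotypes: list[str]) -> float | None:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H.

    The ancestral state at each site is the majority base across the outgroup
    haplotypes; sites where the outgroup is polymorphic (tied majority) or
    entirely missing are excluded.  theta_H = sum_i 2 i^2 S_i / (n (n-1))
    over derived-allele counts i among the ingroup; theta_pi is the matching
    sum with weight i (n - i).  Returns ``None`` when no site is orientable.
    """
    if not outgroup_haplotypes:
        raise ValueError("outgroup required to orient alleles")
    arr, obs = _state_matrix(haplotypes)
    oarr, oobs = _state_matrix(outgroup_haplotypes)
    L = arr.shape[1]
    theta_pi = theta_h = 0.0
    any_orientable = False
    for j in range(L):
        out_states = Counter(oarr[oobs[:, j], j])
        if not out_states:
            continue
        ranked = out_states.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # tie -> not orientable
        ancestral = ranked[0][0]
        col = arr[obs[:, j], j]
        n_j = len(col)
        if n_j < 2:
            continue
        derived = Counter(c for c in col if c != ancestral)
        if len(set(col)) > 2:
            continue  # more than two states: not a biallelic site
        any_orientable = True
        for _, i in derived.items():
            if 0 < i <= n_j:
                theta_pi += 2.0 * i * (n_j - i) / (n_j * (n_j - 1))
                theta_h += 2.0 * i * i / (n_j * (n_j - 1))
    if not any_orientable:
        return None
    return theta_pi - theta_h


@dataclass
class DiversityRow:
    locus: str
    n_sequences: int
    size_bp: int
    n_snps: int
    n_haplotypes: int
    theta_w: float
    pi: float
    he: float
    tajima_d: float | None
    fay_wu_h: float | None


def diversity_table(
    haplotypes_by_locus: dict[str, list[str]],
    outgroup_by_locus: dict[str, list[str]] | None = None,
    locus_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One diversity row per locus plus a 'mean' summary row.

    ``haplotypes_by_locus`` maps locus name to the phased ingroup+outgroup
    haplotypes present there (2 per sequenced individual).  ``locus_lengths``
    overrides the per-site denominator (defaults to haplotype string length,
    i.e. SNP-only strings give per-SNP rates; pass the alignment length to
    obtain per-bp rates as reported for sequenced amplicons).
    """
    rows = []
    for locus, haps in haplotypes_by_locus.items():
        n = len(haps)
        L = (locus_lengths or {}).get(locus, len(haps[0]) if haps else 0)
        S = segregating_sites(haps)
        tally = haplotype_tally(haps)
        he = haplotype_diversity(tally, n) if n >= 2 else 0.0
        og = (outgroup_by_locus or {}).get(locus)
        rows.append(
            DiversityRow(
                locus=locus,
                n_sequences=n,
                size_bp=L,
                n_snps=S,
                n_haplotypes=len(tally),
                theta_w=watterson_theta(S, n, L) if n >= 2 else 0.0,
                pi=nucleotide_diversity(haps) * len(haps[0]) / L if n >= 2 else 0.0,
                he=he,
                tajima_d=tajimas_d(haps) if n >= 2 else None,
                fay_wu_h=fay_wu_h(haps, og) if og else None,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")
    mean_row = df.mean(numeric_only=True)
    df.loc["mean"] = mean_row
    return df
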