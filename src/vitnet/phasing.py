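"""Haplotype phasing of diploid IUPAC consensus sequences by EM.

Each accession's Sanger consensus encodes its two locus haplotypes site by
site: a plain base is homozygous, a two-fold IUPAC code is heterozygous, and
N/'-' is missing.  Phase is inferred with an Excoffier–Slatkin-style EM on
population haplotype frequencies: the E-step distributes each individual's
probability mass over the haplotype pairs compatible with its genotype
(missing sites are summed over their completions), the M-step re-estimates
frequencies, and each individual is finally assigned its maximum-posterior
pair.  There is no recombination model — appropriate for short amplicons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import IUPAC_HET, BASES, LocusAlignment

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for missing; otherwise 0/1/2 alt-allele count


@dataclass
class SnpGenotypes:
    """Biallelic SNP genotypes extracted from one locus alignment."""

    locus: str
    accession_ids: list[str]
    #: shape (n_accessions, n_snps); 0/1/2 alt count, -1 missing
    genotypes: np.ndarray
    snp_positions: list[int]  # column indices into the source alignment
    ref_alt: list[tuple[str, str]]  # per SNP, (ref base, alt base)


def extract_snp_genotypes(aln: LocusAlignment) -> SnpGenotypes:
    """Retain columns with two unambiguous states; code genotypes 0/1/2.

    The reference allele is the first of the two bases in lexicographic
    order.  A heterozygous IUPAC code matching the site's two bases codes 1;
    any other character (including three-state-implying codes) is missing at
    that site for that accession.  Columns implying >2 unambiguous states are
    dropped (non-biallelic, cannot be phased downstream).
    """
    positions, ref_alt, columns = [], [], []
    for j in range(aln.length_bp):
        col = aln.column(j)
        states = set()
        for c in col:
            if c in BASES:
                states.add(c)
            elif c in IUPAC_HET:
                states.update(IUPAC_HET[c])
        if len(states) != 2:
            continue
        ref, alt = sorted(states)
        het_code = next(
            k for k, v in IUPAC_HET.items() if set(v) == {ref, alt}
        )
        geno = []
        for c in col:
            if c == ref:
                geno.append(0)
            elif c == alt:
                geno.append(2)
            elif c == het_code:
                geno.append(1)
            else:
                geno.append(MISSING)
        positions.append(j)
        ref_alt.append((ref, alt))
        columns.append(geno)
    g = (
        np.array(columns, dtype=np.int8).T
        if columns
        else np.zeros((aln.n_accessions, 0), dtype=np.int8)
    )
    return SnpGenotypes(aln.locus_name, list(aln.accession_ids), g,
                        positions, ref_alt)


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotype pairs per accession over a locus's SNP columns."""

    locus: str
    accession_ids: list[str]
    #: per accession, pair of equal-length 0/1/'?' strings
    pairs: dict[str, tuple[str, str]]
    snp_positions: list[int]
    phase_confidence: dict[str, float] = field(default_factory=dict)

    def haplotypes_of(self, accession_id: str) -> tuple[str, str]:
        return self.pairs[accession_id]

    def all_haplotypes(self) -> list[str]:
        return [h for a in self.accession_ids for h in self.pairs[a]]


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs consistent with one genotype vector.

    Heterozygous sites double the pair count (first het site pinned to break
    the mirror symmetry); missing sites contribute all completions.
    """
    site_options: list[list[tuple[int, int]]] = []
    first_het_seen = False
    for g in genotype:
        if g == 0:
            site_options.append([(0, 0)])
        elif g == 2:
            site_options.append([(1, 1)])
        elif g == 1:
            if not first_het_seen:
                site_options.append([(0, 1)])
                first_het_seen = True
            else:
                site_options.append([(0, 1), (1, 0)])
        else:  # missing
            site_options.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = []
    for combo in itertools.product(*site_options):
        h1 = tuple(a for a, _ in combo)
        h2 = tuple(b for _, b in combo)
        pairs.append((h1, h2))
    return pairs


def _phase_greedy(genotype: np.ndarray) -> tuple[tuple, tuple]:
    """Last-resort consistent phase (alt allele alternates between the two
    haplotypes) when no population haplotype is compatible."""
    h1, h2 = [], []
    toggle = 0
    for g in genotype:
        if g == 0:
            h1.append(0); h2.append(0)
        elif g == 2:
            h1.append(1); h2.append(1)
        elif g == 1:
            h1.append(toggle); h2.append(1 - toggle)
        else:
            h1.append(0); h2.append(0)  # missing imputed to ref
    return tuple(h1), tuple(h2)


def _phase_by_pool(
    genotype: np.ndarray,
    pool: list[tuple[tuple, float]],
) -> tuple[tuple, tuple] | None:
    """Surrogate phasing for very heterozygous individuals: pick the most
    frequent population haplotype compatible with the genotype and pair it
    with the implied complement.  The score of a candidate is its frequency
    times the complement's (with a small floor for unseen complements)."""
    freq = {h: f for h, f in pool}
    best = None
    for h, f in pool:
        comp = []
        ok = True
        for a, g in zip(h, genotype):
            if g == MISSING:
                comp.append(a)
            elif g == 0 or g == 2:
                if a != g // 2:
                    ok = False
                    break
                comp.append(a)
            else:  # het
                comp.append(1 - a)
        if not ok:
            continue
        comp = tuple(comp)
        score = f * max(freq.get(comp, 0.0), 1e-6)
        if best is None or score > best[0]:
            best = (score, h, comp)
    if best is None:
        return None
    return best[1], best[2]


def phase_em(
    sg: SnpGenotypes,
    max_het_sites: int = 16,
    seed: int = 1,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    refine: bool = True,
) -> HaplotypeSet:
    """EM haplotype-frequency phasing; deterministic given ``seed``.

    Individuals with more than ``max_het_sites`` ambiguous sites (het +
    2x missing) are phased by the frequency-guided surrogate fallback with
    confidence 0 and do not inform the frequency estimates.  ``refine``
    applies the four-gamete phase refinement afterwards (recommended for
    non-recombining amplicons).
    """
    n, L = sg.genotypes.shape
    rng = np.random.default_rng(seed)

    em_idx, fallback_idx = [], []
    for i in range(n):
        g = sg.genotypes[i]
        ambiguity = int((g == 1).sum()) + 2 * int((g == MISSING).sum())
        (em_idx if ambiguity <= max_het_sites else fallback_idx).append(i)

    # enumerate compatible pairs for EM individuals
    pair_lists = {i: _compatible_pairs(sg.genotypes[i]) for i in em_idx}
    hap_index: dict[tuple, int] = {}
    for plist in pair_lists.values():
        for h1, h2 in plist:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    H = max(len(hap_index), 1)

    # flat arrays over all (individual, pair) rows for vectorized EM
    rows_i, rows_a, rows_b = [], [], []
    for i in em_idx:
        for h1, h2 in pair_lists[i]:
            rows_i.append(i)
            rows_a.append(hap_index[h1])
            rows_b.append(hap_index[h2])
    rows_i = np.array(rows_i, dtype=np.int64)
    rows_a = np.array(rows_a, dtype=np.int64)
    rows_b = np.array(rows_b, dtype=np.int64)
    het_factor = np.where(rows_a == rows_b, 1.0, 2.0)

    def run_em(freq0: np.ndarray) -> tuple[float, np.ndarray]:
        freq = freq0.copy()
        prev_ll = -np.inf
        for _ in range(max_iter):
            w = het_factor * freq[rows_a] * freq[rows_b]
            denom = np.zeros(n)
            np.add.at(denom, rows_i, w)
            d = denom[rows_i]
            ll = float(np.sum(np.log(denom[np.array(em_idx)] + 1e-300)))
            resp = np.where(d > 0, w / np.maximum(d, 1e-300), 0.0)
            new_freq = np.zeros(H)
            np.add.at(new_freq, rows_a, resp)
            np.add.at(new_freq, rows_b, resp)
            total = new_freq.sum()
            if total > 0:
                new_freq /= total
            freq = new_freq
            if abs(ll - prev_ll) < tol:
                break
            prev_ll = ll
        return prev_ll, freq

    best_ll, best_freq = -np.inf, np.full(H, 1.0 / H)
    if len(rows_i):
        for r in range(n_restarts):
            if r == 0:
                freq0 = np.full(H, 1.0 / H)
            else:
                freq0 = rng.dirichlet(np.ones(H))
            ll, freq = run_em(freq0)
            if ll > best_ll + 1e-12:
                best_ll, best_freq = ll, freq

    inv_index = {v: k for k, v in hap_index.items()}
    pairs_out: dict[str, tuple[str, str]] = {}
    confidence: dict[str, float] = {}

    def to_str(h: tuple) -> str:
        return "".join(str(x) for x in h)

    for i in em_idx:
        plist = pair_lists[i]
        w = np.array(
            [
                (1.0 if a == b else 2.0) * best_freq[hap_index[a]] * best_freq[hap_index[b]]
                for a, b in plist
            ]
        )
        if w.sum() <= 0:
            w = np.ones(len(plist))
        w = w / w.sum()
        # ties broken by lexicographic order of the (sorted) haplotype pair
        order = sorted(
            range(len(plist)),
            key=lambda k: (-w[k], tuple(sorted((plist[k][0], plist[k][1])))),
        )
        k = order[0]
        h1, h2 = sorted(plist[k])
        acc = sg.accession_ids[i]
        pairs_out[acc] = (to_str(h1), to_str(h2))
        confidence[acc] = float(w[k])

    pool = sorted(
        ((inv_index[k], float(f)) for k, f in enumerate(best_freq) if f > 1e-9),
        key=lambda t: -t[1],
    )
    for i in fallback_idx:
        acc = sg.accession_ids[i]
        surrogate = _phase_by_pool(sg.genotypes[i], pool)
        if surrogate is None:
            surrogate = _phase_greedy(sg.genotypes[i])
        h1, h2 = sorted(surrogate)
        pairs_out[acc] = (to_str(h1), to_str(h2))
        confidence[acc] = 0.0
        logger.info("%s: %s phased by surrogate (> %d ambiguous sites)",
                    sg.locus, acc, max_het_sites)

    # restore missing sites as '?' so they stay visible downstream
    final_pairs: dict[str, tuple[str, str]] = {}
    for i, acc in enumerate(sg.accession_ids):
        h1, h2 = pairs_out[acc]
        g = sg.genotypes[i]
        h1 = "".join("?" if g[j] == MISSING else h1[j] for j in range(L))
        h2 = "".join("?" if g[j] == MISSING else h2[j] for j in range(L))
        final_pairs[acc] = (h1, h2)

    if refine:
        final_pairs = _four_gamete_refine(sg, final_pairs)

    return HaplotypeSet(sg.locus, list(sg.accession_ids), final_pairs,
                        list(sg.snp_positions), confidence)


def _four_gamete_refine(
    sg: SnpGenotypes, pairs: dict[str, tuple[str, str]]
) -> dict[str, tuple[str, str]]:
    """Resolve double-het phase from population two-site gamete evidence.

    For a non-recombining locus the sample approximates a perfect phylogeny:
    at two biallelic sites at most three of the four gametes exist, and the
    gametes observable in phase-obvious individuals (at most one of the two
    sites heterozygous) dictate the cis/trans configuration of double
    heterozygotes.  Site pairs with tied or absent evidence keep the EM
    phase.  The refinement never changes the implied genotypes.
    """
    G = sg.genotypes
    n, L = G.shape
    out: dict[str, tuple[str, str]] = {}
    for i, acc in enumerate(sg.accession_ids):
        g = G[i]
        het = np.nonzero(g == 1)[0]
        if len(het) < 2:
            out[acc] = pairs[acc]
            continue
        others = np.delete(np.arange(n), i)
        em1 = np.array(
            [0 if c == "?" else int(c) for c in pairs[acc][0]], dtype=int
        )
        j = het[0]
        oj = G[others, j]
        rel = np.zeros(len(het), dtype=int)  # phase relative to site j
        for t, k in enumerate(het[1:], start=1):
            ok = G[others, k]
            valid = (oj >= 0) & (ok >= 0) & ~((oj == 1) & (ok == 1))
            a, b = oj[valid], ok[valid]
            cnt = np.zeros((2, 2))
            hom_both = (a != 1) & (b != 1)
            for aa in (0, 1):
                for bb in (0, 1):
                    cnt[aa, bb] += 2 * np.sum(
                        hom_both & (a // 2 == aa) & (b // 2 == bb)
                    )
            jhom_khet = (a != 1) & (b == 1)
            for aa in (0, 1):
                m = np.sum(jhom_khet & (a // 2 == aa))
                cnt[aa, 0] += m
                cnt[aa, 1] += m
            jhet_khom = (a == 1) & (b != 1)
            for bb in (0, 1):
                m = np.sum(jhet_khom & (b // 2 == bb))
                cnt[0, bb] += m
                cnt[1, bb] += m
            cis = min(cnt[0, 0], cnt[1, 1])
            trans = min(cnt[0, 1], cnt[1, 0])
            if cis > trans:
                rel[t] = 0
            elif trans > cis:
                rel[t] = 1
            else:
                rel[t] = 0 if em1[j] == em1[k] else 1
        h1 = np.where(g == 2, 1, 0)
        h2 = h1.copy()
        h1[het] = rel
        h2[het] = 1 - rel
        if tuple(h2[het]) < tuple(h1[het]):
            h1, h2 = h2, h1
        s1 = "".join("?" if g[x] < 0 else str(h1[x]) for x in range(L))
        s2 = "".join("?" if g[x] < 0 else str(h2[x]) for x in range(L))
        out[acc] = (s1, s2)
    return out


def interhap_differences(haps: HaplotypeSet) -> dict[str, int]:
    """Hamming distance between each accession's two haplotypes
    (over sites where both are called)."""
    out = {}
    for acc in haps.accession_ids:
        h1, h2 = haps.pairs[acc]
        out[acc] = sum(
            1 for a, b in zip(h1, h2) if a != "?" and b != "?" and a != b
        )
    return out


def collapse_to_genotype(pair: tuple[str, str]) -> list[int]:
    """Re-derive the genotype vector from a phased pair (consistency checks)."""
    out = []
    for a, b in zip(*pair):
        if a == "?" or b == "?":
            out.append(MISSING)
        else:
            out.append(int(a) + int(b))
    return out
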