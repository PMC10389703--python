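"""Median-joining haplotype networks (Bandelt-style) and clade lookups.

The network starts from the minimum spanning network (all minimal alternative
links, tolerance epsilon) over the observed haplotypes, then repeatedly adds
the per-site majority consensus of node triplets (a candidate Steiner point)
whenever connecting the triplet through it is cheaper than its current
spanning cost.  Inferred nodes that end up on degree-<=2 paths are pruned,
merging their incident edges.  Input haplotypes must be equal length with no
missing states and at most two states per site (the phasing module's SNP
strings satisfy this).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass
class NetNode:
    node_id: int
    sequence: str
    multiplicity: int = 0
    inferred: bool = False
    clades: Counter = field(default_factory=Counter)


@dataclass
class HaploNetwork:
    nodes: list[NetNode]
    edges: list[tuple[int, int, int]]  # (node_id, node_id, hamming steps)

    def node_by_sequence(self, seq: str) -> NetNode | None:
        for n in self.nodes:
            if n.sequence == seq:
                return n
        return None

    def degree(self, node_id: int) -> int:
        return sum(1 for u, v, _ in self.edges if node_id in (u, v))

    def total_cost(self) -> int:
        """Sum of edge weights of a minimum spanning tree over the final
        node set (the network may carry alternative equal-cost links)."""
        seqs = [n.sequence for n in self.nodes]
        return _mst_cost(_distance_matrix(seqs))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotype length mismatch")
    return sum(1 for x, y in zip(a, b) if x != y)


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    k = len(seqs)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = hamming(seqs[i], seqs[j])
    return d


def _mst_cost(d: np.ndarray) -> int:
    """Prim's algorithm (vectorized); total MST weight."""
    k = d.shape[0]
    if k <= 1:
        return 0
    d = np.asarray(d)
    in_tree = np.zeros(k, dtype=bool)
    in_tree[0] = True
    dist = d[0].astype(np.int64).copy()
    dist[0] = np.iinfo(np.int64).max
    cost = 0
    for _ in range(k - 1):
        j = int(np.argmin(np.where(in_tree, np.iinfo(np.int64).max, dist)))
        cost += int(dist[j])
        in_tree[j] = True
        dist = np.minimum(dist, d[j])
        dist[in_tree] = np.iinfo(np.int64).max
    return cost


class _UnionFind:
    def __init__(self, k: int) -> None:
        self.parent = list(range(k))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _msn_edges(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum spanning network: keep link (i,j) unless i and j are already
    connected using only links shorter than d(i,j) - epsilon."""
    k = d.shape[0]
    pairs = sorted(
        ((int(d[i, j]), i, j) for i in range(k) for j in range(i + 1, k))
    )
    edges = []
    uf = _UnionFind(k)  # connectivity over links of weight < w - epsilon
    lag = 0  # index into pairs of next link to absorb into uf
    for idx, (w, i, j) in enumerate(pairs):
        while lag < len(pairs) and pairs[lag][0] < w - epsilon:
            _, a, b = pairs[lag]
            uf.union(a, b)
            lag += 1
        if uf.find(i) != uf.find(j):
            edges.append((i, j, w))
    return edges


def _majority_median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        counts = Counter((x, y, z))
        out.append(counts.most_common(1)[0][0])
    return "".join(out)


def build_mj_network(
    haplotypes: list[str],
    multiplicities: list[int] | None = None,
    clade_labels: list[str] | None = None,
    epsilon: int = 0,
    max_median_rounds: int = 200,
) -> HaploNetwork:
    """Median-joining network over distinct haplotypes.

    ``haplotypes`` may contain repeats; ``multiplicities``/``clade_labels``
    are per input haplotype copy and are aggregated onto the distinct nodes.
    Deterministic: candidate medians are ranked by (cost gain, lexicographic
    sequence).
    """
    if multiplicities is None:
        multiplicities = [1] * len(haplotypes)
    if clade_labels is None:
        clade_labels = [""] * len(haplotypes)
    if not haplotypes:
        raise ValueError("no haplotypes")
    L = len(haplotypes[0])
    for h in haplotypes:
        if len(h) != L:
            raise ValueError("haplotype length mismatch")
    for j in range(L):
        if len({h[j] for h in haplotypes}) > 2:
            raise ValueError(f"site {j} has >2 states; filter upstream")

    mult: dict[str, int] = {}
    clades: dict[str, Counter] = {}
    order: list[str] = []
    for h, m, c in zip(haplotypes, multiplicities, clade_labels):
        if h not in mult:
            mult[h] = 0
            clades[h] = Counter()
            order.append(h)
        mult[h] += m
        if c:
            clades[h][c] += m
    observed = list(order)
    if len(observed) < 2:
        node = NetNode(0, observed[0], mult[observed[0]], False,
                       clades[observed[0]])
        return HaploNetwork([node], [])

    # binary encoding per column (at most two states, checked above)
    col_states = [sorted({h[j] for h in haplotypes}) for j in range(L)]

    def encode(seq: str) -> np.ndarray:
        return np.array(
            [col_states[j].index(seq[j]) for j in range(L)], dtype=np.uint8
        )

    def decode(vec: np.ndarray) -> str:
        return "".join(
            col_states[j][int(v)] if len(col_states[j]) > int(v) else col_states[j][0]
            for j, v in enumerate(vec)
        )

    current = list(observed)
    arr = np.array([encode(s) for s in current], dtype=np.uint8)
    inferred: set[str] = set()
    for _ in range(max_median_rounds):
        k = len(current)
        if k < 3:
            break
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        base_cost = _mst_cost(d)
        ii, jj, ll = np.array(
            [(i, j, l) for i in range(k) for j in range(i + 1, k)
             for l in range(j + 1, k)]
        ).T
        meds = ((arr[ii].astype(np.int16) + arr[jj] + arr[ll]) >= 2).astype(
            np.uint8
        )
        existing = {bytes(row) for row in arr}
        cand_rows = np.unique(meds, axis=0)
        cand_rows = [r for r in cand_rows if bytes(r) not in existing]
        if not cand_rows:
            break
        # exact criterion: a median joins only if it strictly lowers the
        # minimum spanning cost of the node set
        best: tuple[int, str, np.ndarray] | None = None
        for r in cand_rows:
            dr = (arr != r[None, :]).sum(axis=1)
            d_ext = np.zeros((k + 1, k + 1), dtype=int)
            d_ext[:k, :k] = d
            d_ext[k, :k] = dr
            d_ext[:k, k] = dr
            delta = _mst_cost(d_ext) - base_cost
            if delta < 0:
                cand = (delta, decode(r), r)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        # bounded pair lookahead: two median vectors may jointly pay off more
        # than the best single one (affordable only on small networks)
        pair_best = None
        if k <= 14 and len(cand_rows) <= 60:
            for a_i in range(len(cand_rows)):
                for b_i in range(a_i + 1, len(cand_rows)):
                    ra, rb = cand_rows[a_i], cand_rows[b_i]
                    ext = np.vstack([arr, ra[None, :], rb[None, :]])
                    d2 = (ext[:, None, :] != ext[None, :, :]).sum(axis=2)
                    delta = _mst_cost(d2) - base_cost
                    if delta < 0:
                        cand = (delta, (decode(ra), decode(rb)), (ra, rb))
                        if pair_best is None or cand[:2] < pair_best[:2]:
                            pair_best = cand
        if pair_best is not None and (best is None or pair_best[0] < best[0]):
            for seq, row in zip(pair_best[1], pair_best[2]):
                current.append(seq)
                inferred.add(seq)
                arr = np.vstack([arr, row[None, :]])
            continue
        if best is None:
            break
        current.append(best[1])
        inferred.add(best[1])
        arr = np.vstack([arr, best[2][None, :]])

    # final network and pruning of weakly connected inferred nodes
    while True:
        d = _distance_matrix(current)
        edges = _msn_edges(d, epsilon)
        deg = Counter()
        for i, j, _ in edges:
            deg[i] += 1
            deg[j] += 1
        removable = [
            idx
            for idx, seq in enumerate(current)
            if seq in inferred and deg[idx] <= 2
        ]
        if not removable:
            break
        current = [s for idx, s in enumerate(current) if idx not in removable]

    nodes = [
        NetNode(
            idx,
            seq,
            mult.get(seq, 0),
            seq in inferred,
            clades.get(seq, Counter()),
        )
        for idx, seq in enumerate(current)
    ]
    d = _distance_matrix(current)
    edges = _msn_edges(d, epsilon)
    return HaploNetwork(nodes, [(i, j, int(w)) for i, j, w in edges])


def nearest_clade(
    hap: str, labeled_pool: list[tuple[str, str]]
) -> tuple[str, int]:
    """Clade of the minimum-Hamming labeled haplotype; ties across distinct
    clades return ('UNKNOWN', distance).  Comparison skips sites where either
    haplotype is uncalled ('?')."""
    if not labeled_pool:
        raise ValueError("empty labeled haplotype pool")
    best_d = None
    best_clades: set[str] = set()
    for seq, clade in labeled_pool:
        d = sum(
            1
            for a, b in zip(hap, seq)
            if a != "?" and b != "?" and a != b
        )
        if best_d is None or d < best_d:
            best_d, best_clades = d, {clade}
        elif d == best_d:
            best_clades.add(clade)
    label = best_clades.pop() if len(best_clades) == 1 else "UNKNOWN"
    return label, int(best_d)
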