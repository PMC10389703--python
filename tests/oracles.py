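"""Independent brute-force oracles for cross-checking the library.

Everything here is written from the textbook definitions with plain loops
and exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = set("N-?")


# --- diversity statistics ---------------------------------------------------


def brute_segregating_sites(haps: list[str]) -> int:
    S = 0
    for j in range(len(haps[0])):
        states = {h[j] for h in haps if h[j] not in MISSING}
        if len(states) >= 2:
            S += 1
    return S


def brute_theta_w(haps: list[str], L: int | None = None) -> float:
    n = len(haps)
    S = brute_segregating_sites(haps)
    a1 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
    return S / (a1 * (L if L is not None else len(haps[0])))


def brute_pair_stats(h1: str, h2: str) -> tuple[int, int]:
    """(differences, comparable sites) for one haplotype pair."""
    d = m = 0
    for a, b in zip(h1, h2):
        if a in MISSING or b in MISSING:
            continue
        m += 1
        if a != b:
            d += 1
    return d, m


def brute_pi(haps: list[str]) -> float:
    vals = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d, m = brute_pair_stats(haps[i], haps[j])
            if m:
                vals.append(d / m)
    return sum(vals) / len(vals)


def brute_he(haps: list[str]) -> float:
    keep = [
        j
        for j in range(len(haps[0]))
        if all(h[j] not in MISSING for h in haps)
    ]
    keys = {}
    for h in haps:
        k = "".join(h[j] for j in keep)
        keys[k] = keys.get(k, 0) + 1
    n = len(haps)
    p2 = sum((c / n) ** 2 for c in keys.values())
    return n / (n - 1) * (1 - p2)


def brute_tajimas_d(haps: list[str]) -> float | None:
    n = len(haps)
    S = brute_segregating_sites(haps)
    if S == 0:
        return None
    per_site, comp = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d, m = brute_pair_stats(haps[i], haps[j])
            if m:
                per_site.append(d / m)
                comp.append(m)
    big_pi = (sum(per_site) / len(per_site)) * (sum(comp) / len(comp))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (big_pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# --- Steiner minimum for haplotype networks ---------------------------------


def _mst_cost_from(d: np.ndarray, idx: list[int]) -> int:
    k = len(idx)
    if k <= 1:
        return 0
    sub = d[np.ix_(idx, idx)]
    in_tree = [0]
    out = set(range(1, k))
    cost = 0
    while out:
        best = min((sub[i, j], j) for i in in_tree for j in out)
        cost += int(best[0])
        in_tree.append(best[1])
        out.remove(best[1])
    return cost


def brute_steiner_min(haps: list[str], max_extra: int = 2) -> int:
    """Minimum spanning cost over the observed binary haplotypes allowing up
    to ``max_extra`` added Steiner points, by exhaustive enumeration."""
    pts = [tuple(h) for h in haps]
    L = len(haps[0])
    alphabet = [tuple(sorted({h[j] for h in haps})) for j in range(L)]
    candidates = [
        c for c in itertools.product(*alphabet) if c not in set(pts)
    ]
    allpts = np.array(
        [[ord(x) for x in p] for p in pts + candidates], dtype=np.int16
    )
    d = (allpts[:, None, :] != allpts[None, :, :]).sum(axis=2)
    n = len(pts)
    base = list(range(n))
    best = _mst_cost_from(d, base)
    for r in range(1, max_extra + 1):
        for combo in itertools.combinations(range(n, n + len(candidates)), r):
            cost = _mst_cost_from(d, base + list(combo))
            if cost < best:
                best = cost
    return best


# --- exhaustive NJ-topology oracle ------------------------------------------


def enumerate_unrooted_topologies(labels: list[str]):
    """Yield each unrooted binary topology as (edges, next_internal_id).

    Leaves are 0..n-1 mapped to ``labels``; internal nodes get ids >= n.
    """
    n = len(labels)
    base_edges = [(0, n), (1, n), (2, n)]

    def insert(edges, next_id, leaf):
        for idx, (u, v) in enumerate(edges):
            new = list(edges)
            del new[idx]
            mid = next_id
            new.extend([(u, mid), (mid, v), (leaf, mid)])
            yield new, next_id + 1

    trees = [(base_edges, n + 1)]
    for leaf in range(3, n):
        trees = [
            t for edges, nid in trees for t in insert(edges, nid, leaf)
        ]
    return trees


def topology_bipartitions(edges, labels: list[str]) -> frozenset:
    """Non-trivial bipartitions (canonical smaller side) of one topology."""
    n = len(labels)
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in edges:
        # leaves on the u-side of this edge
        seen, stack = {v}, [u]
        side = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                side.add(labels[x])
            stack.extend(adj[x] - seen)
        if 1 < len(side) < n - 1:
            other = frozenset(labels) - side
            out.add(
                min(frozenset(side), other, key=lambda s: (len(s), sorted(s)))
            )
    return frozenset(out)


def additive_fit_topologies(dm: np.ndarray, labels: list[str]):
    """Topologies whose least-squares branch fit reproduces ``dm`` exactly
    (residual ~0, nonnegative branches)."""
    n = len(labels)
    hits = []
    for edges, _ in enumerate_unrooted_topologies(labels):
        adj: dict[int, list[tuple[int, int]]] = {}
        for ei, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, ei))
            adj.setdefault(v, []).append((u, ei))

        def path_edges(a, b):
            prev = {a: (None, None)}
            stack = [a]
            while stack:
                x = stack.pop()
                if x == b:
                    break
                for y, ei in adj[x]:
                    if y not in prev:
                        prev[y] = (x, ei)
                        stack.append(y)
            out = []
            x = b
            while prev[x][0] is not None:
                out.append(prev[x][1])
                x = prev[x][0]
            return out

        rows, rhs = [], []
        for i in range(n):
            for j in range(i + 1, n):
                row = np.zeros(len(edges))
                for ei in path_edges(i, j):
                    row[ei] = 1.0
                rows.append(row)
                rhs.append(dm[i, j])
        A = np.array(rows)
        b = np.array(rhs)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ x - b)) < 1e-8 and np.min(x) > -1e-8:
            hits.append(topology_bipartitions(edges, labels))
    return hits
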