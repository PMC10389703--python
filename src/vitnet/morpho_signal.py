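"""Trait preparation, PCA, Abouheif's test and phylogenetic PCA.

Leaf measurements are summarized to one value per accession (median over
leaves, then averaging of left/right paired parameters) with derived shape
ratios such as circularity Circ = 4*pi*area/perimeter^2.  Ordinary PCA runs
on the correlation matrix by default (unit-variance scaling), as is standard
for mixed-unit morphometric tables; OIV ordinal codes are treated as numeric.

Phylogenetic signal per trait is Abouheif's Cmean: a Moran-type
autocorrelation statistic whose weights derive from the tree topology alone
— the proximity of two tips is the inverse product of the number of direct
descendants of each internal node on the path between them.  Significance
comes from a one-sided permutation test of tip labels.  Phylogenetic PCA
(pPCA) diagonalizes the proximity-weighted covariance of the scaled traits;
positive eigenvalues capture global (clade-level) structure, negative ones
local contrasts between close relatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import TraitTable

logger = logging.getLogger(__name__)


# --- trait preparation ------------------------------------------------------


def prepare_traits(
    per_leaf: pd.DataFrame,
    accession_col: str = "accession",
    pair_suffixes: tuple[str, str] = ("_left", "_right"),
    min_leaves: int = 3,
    trait_types: dict[str, str] | None = None,
) -> TraitTable:
    """Per-accession trait table from raw per-leaf measurements.

    Median per parameter per accession; parameters measured on both leaf
    halves (columns ``X_left``/``X_right``) are averaged after the medians;
    circularity is derived per leaf from ``area`` and ``perimeter`` columns
    when present.  Accessions with fewer than ``min_leaves`` leaves are kept
    with a warning.
    """
    df = per_leaf.copy()
    if "area" in df.columns and "perimeter" in df.columns:
        df["Circ"] = 4.0 * math.pi * df["area"] / df["perimeter"] ** 2
    counts = df.groupby(accession_col).size()
    for acc, c in counts.items():
        if c < min_leaves:
            logger.warning("%s has only %d leaves (min %d)", acc, c, min_leaves)
    med = df.groupby(accession_col).median(numeric_only=True)
    ls, rs = pair_suffixes
    out = pd.DataFrame(index=med.index)
    done = set()
    for col in med.columns:
        if col in done:
            continue
        if col.endswith(ls):
            base = col[: -len(ls)]
            right = base + rs
            if right in med.columns:
                out[base] = (med[col] + med[right]) / 2.0
                done.update((col, right))
                continue
        if col.endswith(rs):
            base = col[: -len(rs)]
            left = base + ls
            if left in med.columns:
                out[base] = (med[left] + med[col]) / 2.0
                done.update((col, left))
                continue
        out[col] = med[col]
        done.add(col)
    return TraitTable(out, trait_types or {})


# --- ordinary PCA -----------------------------------------------------------


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # traits x axes, correlation-style coordinates
    scores: pd.DataFrame  # accessions x axes
    scaled: bool


def pca(tt: TraitTable, scale: bool = True) -> PCAResult:
    """Centered (optionally unit-variance) eigen-decomposition PCA."""
    X = tt.values.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 1:
        raise ValueError("need >=3 accessions and >=1 trait")
    if np.isnan(X).any():
        raise ValueError("missing values; prepare traits first")
    names = list(tt.trait_names)
    sd = X.std(axis=0, ddof=0)
    if scale:
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            logger.warning("dropping zero-variance traits: %s", dropped)
            X = X[:, keep]
            sd = sd[keep]
            names = [n for n, k in zip(names, keep) if k]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    n = Xc.shape[0]
    cov = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    pct = 100.0 * evals / evals.sum()
    axes = [f"PC{i+1}" for i in range(len(evals))]
    loadings = pd.DataFrame(
        evecs * np.sqrt(evals), index=names, columns=axes
    )
    scores = pd.DataFrame(Xc @ evecs, index=tt.values.index, columns=axes)
    return PCAResult(evals, pct, loadings, scores, scale)


# --- Abouheif proximity and test -------------------------------------------


def abouheif_proximity(
    tree: TreeNode, tip_order: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Topology-only tip proximities: 1 / product of direct-descendant counts
    of the internal nodes on the path between two tips; zero diagonal.

    Returns (raw, row_normalized) DataFrames in ``tip_order``.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree has fewer than 2 tips")
    if tip_order is None:
        tip_order = tips
    missing = set(tip_order) - set(tips)
    if missing:
        raise ValueError(f"tips missing from tree: {sorted(missing)}")
    n = len(tip_order)
    tip_nodes = {t.name: t for t in tree.tips()}
    # ancestor chains (tip -> root) for path computation
    chains: dict[str, list] = {}
    for name in tip_order:
        chain = []
        node = tip_nodes[name]
        while node is not None:
            chain.append(node)
            node = node.parent
        chains[name] = chain
    dd = {id(node): len(node.children) for node in tree.traverse()
          if node.children}
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci = chains[tip_order[i]]
            cj = set(id(x) for x in chains[tip_order[j]])
            mrca = next(x for x in ci if id(x) in cj)
            path_internals = []
            for chain in (chains[tip_order[i]], chains[tip_order[j]]):
                for node in chain[1:]:  # skip the tip itself
                    if node is mrca:
                        break
                    path_internals.append(node)
            path_internals.append(mrca)
            prod = 1.0
            for node in path_internals:
                prod *= dd[id(node)]
            raw[i, j] = raw[j, i] = 1.0 / prod
    raw_df = pd.DataFrame(raw, index=tip_order, columns=tip_order)
    rownorm = raw / raw.sum(axis=1, keepdims=True)
    return raw_df, pd.DataFrame(rownorm, index=tip_order, columns=tip_order)


@dataclass
class PhyloSignalResult:
    trait: str
    cmean: float | None
    p_value: float | None
    n_permutations: int
    proximity: str = "abouheif"

    @property
    def undefined(self) -> bool:
        return self.cmean is None


def _cmean(z: np.ndarray, W: np.ndarray) -> float:
    return float(z @ W @ z / (z @ z))


def abouheif_test(
    values: pd.Series | np.ndarray,
    proximity: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 1,
    trait_name: str = "",
) -> PhyloSignalResult:
    """Abouheif's Cmean with a one-sided upper permutation p-value.

    ``proximity`` must be the row-normalized matrix, rows/cols aligned with
    ``values``.  p = (#{C* >= Cobs} + 1) / (n_perm + 1).  Constant traits
    yield an undefined (flagged) result.
    """
    x = np.asarray(values, dtype=float)
    W = proximity.to_numpy(dtype=float)
    if x.std() == 0:
        return PhyloSignalResult(trait_name, None, None, n_perm)
    z = x - x.mean()
    cobs = _cmean(z, W)
    rng = np.random.default_rng(seed)
    n = len(z)
    # vectorized: all permuted trait vectors as columns
    perm = rng.permuted(np.tile(z, (n_perm, 1)), axis=1).T
    cstar = np.einsum("ik,ij,jk->k", perm, W, perm) / (perm * perm).sum(axis=0)
    p = (float((cstar >= cobs).sum()) + 1.0) / (n_perm + 1.0)
    return PhyloSignalResult(trait_name, cobs, p, n_perm)


def phylo_signal_table(
    tt: TraitTable,
    proximity_rownorm: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-trait Cmean, permutation p, and p<0.01 / p<0.05 flags."""
    order = [a for a in proximity_rownorm.index if a in tt.values.index]
    vals = tt.values.loc[order]
    W = proximity_rownorm.loc[order, order]
    rows = []
    for i, trait in enumerate(tt.trait_names):
        res = abouheif_test(
            vals[trait], W, n_perm=n_perm, seed=seed + i, trait_name=trait
        )
        rows.append(
            {
                "trait": trait,
                "cmean": res.cmean,
                "p_value": res.p_value,
                "sig_0.01": (res.p_value is not None and res.p_value < 0.01),
                "sig_0.05": (
                    res.p_value is not None and 0.01 <= res.p_value < 0.05
                ),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


# --- phylogenetic PCA -------------------------------------------------------


@dataclass
class PPCAResult:
    eigenvalues: np.ndarray  # signed; positive = global, negative = local
    loadings: pd.DataFrame
    scores: pd.DataFrame
    axis_kind: list[str] = field(default_factory=list)


def ppca(tt: TraitTable, proximity_rownorm: pd.DataFrame) -> PPCAResult:
    """Eigenanalysis of the proximity-weighted cross-product of scaled traits.

    Decomposes (1/n) X' W_sym X with X centered/scaled and W_sym the
    symmetrized row-normalized proximity; with W = I this reduces to
    ordinary correlation PCA.  Eigenvalues keep their sign.
    """
    order = [a for a in proximity_rownorm.index if a in tt.values.index]
    X = tt.values.loc[order].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    names = [n for n, k in zip(tt.trait_names, keep) if k]
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    W = proximity_rownorm.loc[order, order].to_numpy(dtype=float)
    Wsym = (W + W.T) / 2.0
    n = X.shape[0]
    M = X.T @ Wsym @ X / n
    evals, evecs = np.linalg.eigh(M)
    order_idx = np.argsort(np.abs(evals))[::-1]
    evals, evecs = evals[order_idx], evecs[:, order_idx]
    axes = [f"pPC{i+1}" for i in range(len(evals))]
    kinds = ["global" if e > 0 else "local" for e in evals]
    loadings = pd.DataFrame(evecs, index=names, columns=axes)
    scores = pd.DataFrame(X @ evecs, index=order, columns=axes)
    return PPCAResult(evals, loadings, scores, kinds)


def select_top_loadings(
    loadings: pd.Series, lower_q: float = 0.1, upper_q: float = 0.9
) -> list[str]:
    """Traits whose axis loading is below the ``lower_q`` or above the
    ``upper_q`` quantile of the loading distribution.  With fewer than 10
    traits the selection returns everything (logged)."""
    a = loadings.astype(float)
    if len(a) < 10:
        logger.warning("fewer than 10 traits; returning all")
        return list(a.index)
    lo, hi = a.quantile(lower_q), a.quantile(upper_q)
    return [t for t in a.index if a[t] < lo or a[t] > hi]
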