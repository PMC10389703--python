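import numpy as np
import pandas as pd
import pytest

import oracles
from vitnet import distance_trees as dt
from vitnet.io_formats import GenotypeMatrix, LocusAlignment


def aln(*seqs):
    return LocusAlignment("t", [f"s{i}" for i in range(len(seqs))], list(seqs))


def gm(calls, panels=None):
    calls = np.asarray(calls, dtype=float)
    n_snps = calls.shape[1]
    snp_ids = [f"s{j}" for j in range(n_snps)]
    meta = pd.DataFrame(
        {
            "discovery_panel": panels or ["vinifera"] * n_snps,
            "genome": ["nuclear"] * n_snps,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        [f"a{i}" for i in range(calls.shape[0])], snp_ids, calls, meta
    )


class TestSeqDistance:
    def test_identical_sequences(self):
        d = dt.seq_distance(aln("ACGT", "ACGT", "ACGT"))
        assert np.all(d.matrix == 0)

    def test_single_difference(self):
        d = dt.seq_distance(aln("ACGT", "ACGA", "ACGT"))
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_het_vs_shared_hom_is_half(self):
        # R = A/G vs A: one shared allele -> 0.5 difference at that site
        d = dt.seq_distance(aln("AR", "AA", "AA"))
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_het_vs_same_het_is_zero(self):
        d = dt.seq_distance(aln("AR", "AR", "AA"))
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_metric_triangle_inequality(self):
        rng = np.random.default_rng(4)
        seqs = [
            "".join(rng.choice(list("ACGTRYKMSW"), size=30)) for _ in range(6)
        ]
        m = dt.seq_distance(aln(*seqs)).matrix
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-12


class TestSnpDistance:
    def test_identical_rows(self):
        d = dt.snp_distance(gm([[0, 1, 2], [0, 1, 2]]))
        assert d.matrix[0, 1] == 0

    def test_opposite_homozygotes_maximal(self):
        d = dt.snp_distance(gm([[0, 2], [2, 0]]))
        assert d.matrix[0, 1] == 1

    def test_het_vs_hom(self):
        d = dt.snp_distance(gm([[1, 1, 1, 1], [0, 0, 0, 0]]))
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_missing_pairwise_deleted(self):
        d = dt.snp_distance(gm([[0, np.nan], [2, 2]]))
        assert d.matrix[0, 1] == 1.0


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): additive distances
        m = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        dm = dt.DistanceMatrix(["A", "B", "C", "D"], m)
        st = dt.nj_tree(dm)
        bps = dt.tree_bipartitions(st.tree)
        assert frozenset({"A", "B"}) in bps
        # branch lengths reproduce the additive metric exactly
        t = st.tree
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert t.find(a).distance(t.find(b)) == pytest.approx(
                        m[i, j]
                    )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_topology_oracle(self, seed):
        """NJ recovers the unique additive topology found by brute-force
        enumeration with least-squares branch fitting."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        labels = [f"t{i}" for i in range(n)]
        # random additive matrix from a random topology with random lengths
        topos = oracles.enumerate_unrooted_topologies(labels)
        edges, _ = topos[rng.integers(0, len(topos))]
        lengths = {e: rng.uniform(0.5, 2.0) for e in range(len(edges))}
        adj = {}
        for ei, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, ei))
            adj.setdefault(v, []).append((u, ei))

        def dist(a, b):
            prev = {a: (None, None)}
            stack = [a]
            while stack:
                x = stack.pop()
                for y, ei in adj[x]:
                    if y not in prev:
                        prev[y] = (x, ei)
                        stack.append(y)
            s = 0.0
            x = b
            while prev[x][0] is not None:
                s += lengths[prev[x][1]]
                x = prev[x][0]
            return s

        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = dist(i, j)
        st = dt.nj_tree(dt.DistanceMatrix(labels, m))
        fits = oracles.additive_fit_topologies(m, labels)
        assert len(fits) == 1  # generic lengths -> unique additive topology
        assert dt.tree_bipartitions(st.tree) == set(fits[0])


class TestBootstrap:
    def test_deterministic_and_supported(self, small_dataset):
        from vitnet.io_formats import concatenate

        cat = concatenate(list(small_dataset.loci.values()), "union_fill_N")
        t1 = dt.bootstrap_seq_tree(cat, B=20, seed=9)
        t2 = dt.bootstrap_seq_tree(cat, B=20, seed=9)
        assert t1.supports == t2.supports
        assert all(0 <= v <= 100 for v in t1.supports.values())

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(6)]
        ids = [f"x{i}" for i in range(6)]
        a1 = LocusAlignment("l", ids, seqs)
        order = [3, 1, 5, 0, 4, 2]
        a2 = LocusAlignment("l", [ids[i] for i in order],
                            [seqs[i] for i in order])
        t1 = dt.bootstrap_seq_tree(a1, B=25, seed=5)
        t2 = dt.bootstrap_seq_tree(a2, B=25, seed=5)
        assert dt.tree_bipartitions(t1.tree) == dt.tree_bipartitions(t2.tree)


class TestSubsampleByPanel:
    def test_identity_when_target_is_all(self, small_dataset):
        g = small_dataset.genotypes
        nuc = g.subset_snps(g.nuclear_snp_ids())
        n_vin = sum(
            nuc.snp_meta.loc[s, "discovery_panel"] == "vinifera"
            for s in nuc.snp_ids
        )
        out = dt.subsample_by_panel(nuc, "vinifera", n_vin, seed=1)
        assert out.snp_ids == nuc.snp_ids

    def test_target_exceeding_available_errors(self, small_dataset):
        g = small_dataset.genotypes
        with pytest.raises(ValueError, match="exceeds"):
            dt.subsample_by_panel(g, "vinifera", 10**6)

    def test_counts_invariant_membership_varies(self, small_dataset):
        g = small_dataset.genotypes
        nuc = g.subset_snps(g.nuclear_snp_ids())
        picks = []
        for seed in range(6):
            out = dt.subsample_by_panel(nuc, "vinifera", 40, seed=seed)
            n_vin = sum(
                out.snp_meta.loc[s, "discovery_panel"] == "vinifera"
                for s in out.snp_ids
            )
            assert n_vin == 40
            n_other = len(out.snp_ids) - n_vin
            assert n_other == sum(
                nuc.snp_meta.loc[s, "discovery_panel"] != "vinifera"
                for s in nuc.snp_ids
            )
            picks.append(tuple(out.snp_ids))
        assert len(set(picks)) > 1


class TestCladeBranchSummary:
    def test_ultrametric_tree_gives_unit_ratios(self, small_dataset):
        # build an exactly ultrametric star-of-clades distance matrix
        acc = small_dataset.accessions
        ids = [a for a in acc.accession_ids]
        n = len(ids)
        m = np.full((n, n), 0.2)
        np.fill_diagonal(m, 0.0)
        for i in range(n):
            for j in range(n):
                if i != j and acc.clade_of(ids[i]) == acc.clade_of(ids[j]):
                    m[i, j] = 0.05
        st = dt.nj_tree(dt.DistanceMatrix(ids, m))
        st.supports = {}
        out = dt.clade_branch_summary(st, acc)
        for clade, s in out.items():
            assert s["ratio_vs_overall"] == pytest.approx(1.0, abs=0.05)

    def test_missing_outgroup_errors(self):
        m = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0.0]])
        st = dt.nj_tree(dt.DistanceMatrix(["a", "b", "c"], m))
        import pandas as pd

        from vitnet.io_formats import AccessionTable

        acc = AccessionTable(
            pd.DataFrame(
                {
                    "species_label": ["x"] * 3,
                    "clade_label": ["EU", "EU", "NA1"],
                    "known_hybrid": [False] * 3,
                },
                index=pd.Index(["a", "b", "c"], name="accession"),
            )
        )
        with pytest.raises(ValueError, match="outgroup"):
            dt.clade_branch_summary(st, acc)
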