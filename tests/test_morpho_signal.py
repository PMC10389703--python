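import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from vitnet import morpho_signal as ms
from vitnet.io_formats import TraitTable


def tree_from(nwk):
    return TreeNode.read([nwk], format="newick")


class TestPrepareTraits:
    def test_circle_circularity_is_one(self):
        r = 3.0
        df = pd.DataFrame(
            {
                "accession": ["a"] * 3,
                "area": [math.pi * r * r] * 3,
                "perimeter": [2 * math.pi * r] * 3,
            }
        )
        tt = ms.prepare_traits(df)
        assert tt.values.loc["a", "Circ"] == pytest.approx(1.0)

    def test_single_leaf_median_is_that_leaf(self, caplog):
        import logging

        df = pd.DataFrame({"accession": ["a"], "x": [7.0]})
        with caplog.at_level(logging.WARNING):
            tt = ms.prepare_traits(df)
        assert tt.values.loc["a", "x"] == 7.0
        assert "only 1 leaves" in caplog.text

    def test_median_then_left_right_average(self):
        # 5 leaves; median per half first, halves averaged afterwards
        left = [10.0, 11.0, 12.0, 13.0, 14.0]  # median 12
        right = [20.0, 21.0, 22.0, 23.0, 40.0]  # median 22
        df = pd.DataFrame(
            {
                "accession": ["a"] * 5,
                "angle_left": left,
                "angle_right": right,
            }
        )
        tt = ms.prepare_traits(df)
        assert tt.values.loc["a", "angle"] == pytest.approx((12 + 22) / 2)


class TestPCA:
    def test_single_trait_pc1_100(self):
        tt = TraitTable(pd.DataFrame({"x": [1.0, 2.0, 3.0]},
                                     index=["a", "b", "c"]))
        res = ms.pca(tt)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_perfectly_correlated_traits(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        tt = TraitTable(
            pd.DataFrame({"x": x, "y": 2 * x}, index=list("abcd"))
        )
        res = ms.pca(tt)
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.percent_variance[1] == pytest.approx(0.0, abs=1e-9)

    def test_percents_sum_and_score_orthogonality(self):
        rng = np.random.default_rng(0)
        tt = TraitTable(
            pd.DataFrame(
                rng.normal(size=(12, 5)),
                index=[f"a{i}" for i in range(12)],
                columns=[f"t{j}" for j in range(5)],
            )
        )
        res = ms.pca(tt)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        S = res.scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.max(np.abs(off)) < 1e-8

    def test_zero_variance_trait_dropped_when_scaled(self, caplog):
        import logging

        tt = TraitTable(
            pd.DataFrame(
                {"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]},
                index=list("abc"),
            )
        )
        with caplog.at_level(logging.WARNING):
            res = ms.pca(tt, scale=True)
        assert list(res.loadings.index) == ["x"]


class TestAbouheifProximity:
    def test_three_leaf_asymmetry(self):
        raw, _ = ms.abouheif_proximity(tree_from("((a,b),c);"))
        assert raw.loc["a", "b"] > raw.loc["a", "c"]

    def test_star_tree_uniform_offdiagonal(self):
        raw, _ = ms.abouheif_proximity(tree_from("(a,b,c,d,e);"))
        m = raw.to_numpy()
        off = m[~np.eye(5, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.all(np.diag(m) == 0)

    def test_missing_tip_errors(self):
        with pytest.raises(ValueError, match="missing"):
            ms.abouheif_proximity(tree_from("((a,b),c);"),
                                  tip_order=["a", "ghost"])

    def test_single_tip_errors(self):
        with pytest.raises(ValueError):
            ms.abouheif_proximity(tree_from("(a);"))


class TestAbouheifTest:
    def test_constant_trait_flagged_undefined(self):
        _, prox = ms.abouheif_proximity(tree_from("((a,b),(c,d));"))
        res = ms.abouheif_test(
            pd.Series([1.0] * 4, index=list("abcd")), prox
        )
        assert res.undefined
        assert res.p_value is None

    def test_deterministic_given_seed(self):
        _, prox = ms.abouheif_proximity(
            tree_from("((a,b),(c,(d,e)));")
        )
        x = pd.Series([1.0, 1.2, 3.0, 3.1, 2.9], index=list("abcde"))
        r1 = ms.abouheif_test(x, prox, n_perm=199, seed=4)
        r2 = ms.abouheif_test(x, prox, n_perm=199, seed=4)
        assert r1.cmean == r2.cmean
        assert r1.p_value == r2.p_value

    def test_clade_structured_trait_significant(self):
        nwk = "((a,b),(c,d),(e,f));"
        _, prox = ms.abouheif_proximity(tree_from(nwk))
        x = pd.Series([0.0, 0.1, 5.0, 5.1, 10.0, 10.2],
                      index=list("abcdef"))
        res = ms.abouheif_test(x, prox, n_perm=999, seed=1)
        assert res.cmean > 0
        assert res.p_value < 0.05


class TestPPCA:
    def test_identity_proximity_matches_ordinary_pca(self):
        rng = np.random.default_rng(7)
        idx = [f"a{i}" for i in range(10)]
        tt = TraitTable(
            pd.DataFrame(
                rng.normal(size=(10, 4)), index=idx,
                columns=[f"t{j}" for j in range(4)],
            )
        )
        W = pd.DataFrame(np.eye(10), index=idx, columns=idx)
        pp = ms.ppca(tt, W)
        ordinary = ms.pca(tt, scale=True)
        # same eigenvalues (correlation PCA) and same leading subspace
        assert np.allclose(
            np.sort(pp.eigenvalues)[::-1], ordinary.eigenvalues, atol=1e-9
        )
        v1 = pp.loadings["pPC1"].to_numpy()
        u1 = ordinary.loadings["PC1"].to_numpy()
        u1 = u1 / np.linalg.norm(u1)
        assert abs(abs(v1 @ u1)) == pytest.approx(1.0, abs=1e-8)

    def test_global_local_sign_convention(self, default_dataset):
        from vitnet.morpho_signal import abouheif_proximity

        tree = default_dataset.tree
        tips = [t.name for t in tree.tips()]
        _, prox = abouheif_proximity(tree, tip_order=tips)
        tt = TraitTable(default_dataset.leaf_traits.values.loc[tips])
        pp = ms.ppca(tt, prox)
        assert pp.axis_kind[0] == "global"
        assert pp.eigenvalues[0] > 0


class TestSelectTopLoadings:
    def test_fewer_than_ten_returns_all(self, caplog):
        import logging

        s = pd.Series(np.arange(5, dtype=float),
                      index=[f"t{i}" for i in range(5)])
        with caplog.at_level(logging.WARNING):
            out = ms.select_top_loadings(s)
        assert out == list(s.index)

    def test_decile_rule(self):
        s = pd.Series(np.arange(20, dtype=float),
                      index=[f"t{i}" for i in range(20)])
        out = ms.select_top_loadings(s)
        assert "t0" in out and "t19" in out
        assert "t10" not in out
        assert len(out) == 4


class TestTypeIErrorQuick:
    def test_permutation_null_close_to_nominal(self):
        """Small-scale calibration check of the permutation p-value."""
        rng = np.random.default_rng(3)
        nwk = "((((a,b),(c,d)),((e,f),(g,h))),(((i,j),(k,l)),((m,n),(o,p))));"
        tree = tree_from(nwk)
        tips = [t.name for t in tree.tips()]
        _, prox = ms.abouheif_proximity(tree, tip_order=tips)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            x = pd.Series(rng.normal(size=len(tips)), index=tips)
            res = ms.abouheif_test(x, prox, n_perm=199, seed=s)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.09
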