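import numpy as np
import pandas as pd
import pytest

from vitnet import hybrid_inference as hyb
from vitnet.io_formats import AccessionTable, GenotypeMatrix
from vitnet.phasing import HaplotypeSet


def acc_table(rows):
    return AccessionTable(
        pd.DataFrame(
            {
                "species_label": [r[1] for r in rows],
                "clade_label": [r[2] for r in rows],
                "known_hybrid": [r[3] if len(r) > 3 else False for r in rows],
            },
            index=pd.Index([r[0] for r in rows], name="accession"),
        )
    )


def hapset(locus, pairs):
    ids = list(pairs)
    L = len(next(iter(pairs.values()))[0])
    return HaplotypeSet(locus, ids, pairs, list(range(L)))


class TestDbar:
    def test_arithmetic_mean_over_loci(self):
        sets = {
            "l1": hapset("l1", {"a": ("00", "11")}),  # 2 diffs
            "l2": hapset("l2", {"a": ("0000", "1111")}),  # 4
            "l3": hapset("l3", {"a": ("000000", "111111")}),  # 6
        }
        assert hyb.dbar_statistic(sets)["a"] == pytest.approx(4.0)

    def test_homozygous_accession_zero(self):
        sets = {"l1": hapset("l1", {"a": ("01", "01")})}
        assert hyb.dbar_statistic(sets)["a"] == 0.0

    def test_absent_loci_do_not_contribute(self):
        sets = {
            "l1": hapset("l1", {"a": ("00", "11"), "b": ("00", "00")}),
            "l2": hapset("l2", {"b": ("01", "01")}),
        }
        d = hyb.dbar_statistic(sets)
        assert d["a"] == 2.0  # only sequenced at l1


class TestFlagOutliers:
    def test_hand_computed_tukey_fence(self):
        vals = {k: v for k, v in zip("abcde", [1, 1, 2, 2, 9])}
        grouping = {k: "G" for k in vals}
        flags = hyb.flag_outliers(vals, grouping)
        assert flags == {"a": False, "b": False, "c": False, "d": False,
                         "e": True}

    def test_all_equal_no_outliers(self):
        vals = {k: 3.0 for k in "abcdef"}
        flags = hyb.flag_outliers(vals, {k: "G" for k in vals})
        assert not any(flags.values())

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = {f"a{i}": float(v) for i, v in enumerate(rng.normal(size=12))}
        grouping = {k: "G" for k in vals}
        f1 = hyb.flag_outliers(vals, grouping)
        f2 = hyb.flag_outliers({k: v + 100 for k, v in vals.items()}, grouping)
        assert f1 == f2

    def test_small_group_uses_pooled(self, caplog):
        import logging

        vals = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 50.0, "f": 1.0}
        grouping = dict.fromkeys("abcd", "G1") | dict.fromkeys("ef", "G2")
        with caplog.at_level(logging.INFO):
            flags = hyb.flag_outliers(vals, grouping)
        assert flags["e"]  # outlier against the pooled distribution
        assert "pooled" in caplog.text


class TestAssignParents:
    def setup_method(self):
        self.acc = acc_table(
            [
                ("eu1", "v", "EU"), ("eu2", "v", "EU"),
                ("na1", "r", "NA1"), ("na2", "r", "NA1"),
                ("hyb", "h", "EU"),
            ]
        )

    def make_sets(self, hyb_pair):
        pairs = {
            "eu1": ("0000", "0000"), "eu2": ("0001", "0000"),
            "na1": ("1111", "1111"), "na2": ("1110", "1111"),
            "hyb": hyb_pair,
        }
        return {f"l{k}": hapset(f"l{k}", dict(pairs)) for k in range(4)}

    def test_pure_accession_double_label(self):
        sets = self.make_sets(("0000", "0001"))
        pair, _ = hyb.assign_parents("hyb", sets, self.acc)
        assert pair == ("EU", "EU")

    def test_f1_recovers_both_parents(self):
        sets = self.make_sets(("0000", "1111"))
        pair, per_locus = hyb.assign_parents("hyb", sets, self.acc)
        assert pair == ("EU", "NA1")
        assert len(per_locus) == 4

    def test_quarter_locus_threshold_blocks_single_locus_noise(self):
        # one aberrant locus out of 8 must not create a second parent
        pairs = {
            "eu1": ("0000", "0000"), "eu2": ("0001", "0000"),
            "na1": ("1111", "1111"), "na2": ("1110", "1111"),
            "hyb": ("0000", "0001"),
        }
        sets = {f"l{k}": hapset(f"l{k}", dict(pairs)) for k in range(7)}
        aberrant = dict(pairs)
        aberrant["hyb"] = ("0000", "1111")
        sets["l7"] = hapset("l7", aberrant)
        pair, _ = hyb.assign_parents("hyb", sets, self.acc)
        assert pair == ("EU", "EU")


class TestArrayHeterozygosity:
    def test_values(self):
        meta = pd.DataFrame(
            {"discovery_panel": ["vinifera"] * 4, "genome": ["nuclear"] * 4},
            index=pd.Index([f"s{j}" for j in range(4)], name="snp_id"),
        )
        g = GenotypeMatrix(
            ["a", "b"], [f"s{j}" for j in range(4)],
            np.array([[0.0, 1.0, 1.0, 2.0], [0.0, 0.0, 2.0, 2.0]]), meta,
        )
        het = hyb.array_heterozygosity(g)
        assert het["a"] == pytest.approx(0.5)
        assert het["b"] == 0.0


class TestChlorotypes:
    def make_gm(self, strings):
        n_loci = len(strings[0])
        snp_ids = [f"cp{j}" for j in range(n_loci)]
        meta = pd.DataFrame(
            {
                "discovery_panel": ["american"] * n_loci,
                "genome": ["chloroplast"] * n_loci,
            },
            index=pd.Index(snp_ids, name="snp_id"),
        )
        calls = np.array(
            [[2.0 * int(c) if c != "." else np.nan for c in s]
             for s in strings]
        )
        ids = [f"a{i}" for i in range(len(strings))]
        return GenotypeMatrix(ids, snp_ids, calls, meta)

    def test_direct_grouping(self):
        gm = self.make_gm(["000", "000", "011", "111"])
        assigns, inf = hyb.define_chlorotypes(gm)
        assert len({a.chlorotype_id for a in assigns}) == 3

    def test_monomorphic_loci_dropped(self):
        # first locus monomorphic -> only loci 1,2 informative
        gm = self.make_gm(["000", "001", "011"])
        assigns, inf = hyb.define_chlorotypes(gm)
        assert len(inf) == 2

    def test_het_calls_treated_missing(self):
        gm = self.make_gm(["00", "01", "11"])
        gm.calls[1, 0] = 1.0  # het artifact
        assigns, _ = hyb.define_chlorotypes(gm)
        a1 = next(a for a in assigns if a.accession == "a1")
        assert a1.snp_string[0] == "."

    def test_single_linkage_chain_collapse(self):
        gm = self.make_gm(["000", "001", "011", "111"])
        assigns, _ = hyb.define_chlorotypes(gm)
        hyb.collapse_chlorotypes(assigns, threshold=1)
        assert len({a.collapsed_group_id for a in assigns}) == 1

    def test_collapse_at_zero_is_noop(self):
        gm = self.make_gm(["000", "011", "110", "101"])
        assigns, _ = hyb.define_chlorotypes(gm)
        hyb.collapse_chlorotypes(assigns, threshold=0)
        assert len({a.collapsed_group_id for a in assigns}) == len(
            {a.chlorotype_id for a in assigns}
        )


class TestInferMaternal:
    def setup_method(self):
        self.acc = acc_table(
            [
                ("eu1", "v", "EU"), ("na1", "r", "NA1"),
                ("cal1", "c", "CAL"), ("hyb", "h", "EU"),
            ]
        )

    def assigns(self, strings):
        out = []
        for i, (name, s) in enumerate(strings.items()):
            out.append(hyb.ChlorotypeAssignment(name, i, s))
        hyb.collapse_chlorotypes(out, threshold=0)
        # manual regroup at threshold 1 for realistic sharing
        hyb.collapse_chlorotypes(out, threshold=1)
        return out

    def test_maternal_clade_recovered(self):
        a = self.assigns(
            {"eu1": "0000", "na1": "1111", "cal1": "0011", "hyb": "1111"}
        )
        maternal, ev = hyb.infer_maternal("hyb", ("EU", "NA1"), a, self.acc)
        assert maternal == "NA1"

    def test_both_parents_share_is_unknown(self):
        a = self.assigns(
            {"eu1": "0000", "na1": "0000", "cal1": "1111", "hyb": "0000"}
        )
        maternal, ev = hyb.infer_maternal("hyb", ("EU", "NA1"), a, self.acc)
        assert maternal == "UNKNOWN"

    def test_neither_parent_reports_nearest(self):
        a = self.assigns(
            {"eu1": "000000", "na1": "111111", "cal1": "001100",
             "hyb": "001101"}
        )
        maternal, ev = hyb.infer_maternal("hyb", ("EU", "NA1"), a, self.acc)
        assert maternal == "UNKNOWN"
        assert ev.get("nearest_chlorotype_clade") == "CAL"


class TestEndToEndOnSynthetic:
    def test_planted_hybrids_detected_with_parents_and_maternal(
        self, default_dataset
    ):
        from vitnet.pipeline import phase_all_loci

        ds = default_dataset
        hs = phase_all_loci(ds.loci, seed=3)
        reports = hyb.hybrid_report(hs, ds.accessions, gm=ds.genotypes)
        by_acc = {r.accession: r for r in reports}
        truth = {h["accession"]: h for h in ds.truth.hybrids}
        for acc, spec in truth.items():
            r = by_acc[acc]
            assert r.outlier, f"{acc} not flagged"
            assert set(r.parental_clades) == {spec["parent1"], spec["parent2"]}
            assert r.maternal_clade == spec["maternal"]
        false_pos = [
            r.accession for r in reports
            if r.is_hybrid_call and r.accession not in truth
        ]
        assert false_pos == []
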