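"""End-to-end orchestration: diversity -> phasing -> hybrid detection ->
networks -> trees (with hybrid-free rerun) -> ascertainment -> morphometrics.

The pipeline consumes either a synthetic dataset (simulated in memory from a
:class:`~vitnet.synthetic_data.SimConfig`) or a manifest file mapping input
roles to paths.  Every stage is individually toggleable; stage outputs land
in a single report dictionary and can be written out as a JSON/TSV bundle.
Hybrid-free reruns exclude known hybrids plus newly detected ones (dbar
outliers with a resolved parental-clade pair).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distance_trees as dt
from . import hybrid_inference as hyb
from . import morpho_signal as ms
from . import popgen_stats as pg
from .hapnet import build_mj_network
from .io_formats import (
    AccessionTable,
    GenotypeMatrix,
    LocusAlignment,
    TraitTable,
    concatenate,
    read_accessions,
    read_fasta_alignment,
    read_genotypes,
    read_newick,
    read_traits,
    write_network_gml,
)
from .phasing import HaplotypeSet, extract_snp_genotypes, phase_em
from .synthetic_data import SimConfig, SyntheticDataset, simulate

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "diversity",
    "phasing",
    "hybrids",
    "networks",
    "trees",
    "ascertainment",
    "morpho",
)


@dataclass
class PipelineConfig:
    seed: int = 1
    manifest: str | None = None
    sim: SimConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    bootstrap_B: int = 100
    n_perm: int = 999
    epsilon: int = 0
    outlier_k: float = 1.5
    collapse_threshold: int = 1
    panel_class: str = "vinifera"
    subsample_targets: tuple[int, ...] | None = None
    max_het_sites: int = 16

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.manifest is None and self.sim is None:
            self.sim = SimConfig(seed=self.seed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: dict = field(default_factory=dict)
    diversity: pd.DataFrame | None = None
    haplotype_sets: dict[str, HaplotypeSet] = field(default_factory=dict)
    hybrid_reports: list = field(default_factory=list)
    networks: dict = field(default_factory=dict)
    trees: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def write_bundle(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.report, indent=1, default=_jsonable)
        )
        if self.diversity is not None:
            self.diversity.to_csv(outdir / "diversity.tsv", sep="\t")
        if self.hybrid_reports:
            rows = [
                {
                    "accession": r.accession,
                    "dbar": r.dbar,
                    "clade_group": r.clade_group,
                    "outlier": r.outlier,
                    "parent1": r.parental_clades[0],
                    "parent2": r.parental_clades[1],
                    "maternal_clade": r.maternal_clade,
                    "array_het": r.array_het,
                }
                for r in self.hybrid_reports
            ]
            pd.DataFrame(rows).to_csv(
                outdir / "hybrids.tsv", sep="\t", index=False
            )
        for locus, net in self.networks.items():
            write_network_gml(net, outdir / f"network_{locus}.gml")
        for name, stree in self.trees.items():
            stree.tree.write(str(outdir / f"tree_{name}.nwk"), format="newick")
        return outdir


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    return str(x)


@dataclass
class InputBundle:
    loci: dict[str, LocusAlignment]
    accessions: AccessionTable
    genotypes: GenotypeMatrix | None = None
    leaf_traits: TraitTable | None = None
    oiv_traits: TraitTable | None = None
    tree: object | None = None


def load_manifest(manifest_path: str | Path) -> InputBundle:
    """Load the input bundle described by a manifest JSON (role -> path)."""
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    loci = {
        locus: read_fasta_alignment(base / rel, locus)
        for locus, rel in spec.get("loci", {}).items()
    }
    roles = spec.get("roles", {})
    accessions = read_accessions(base / roles["accessions"])
    gm = None
    if "genotypes" in roles:
        gm = read_genotypes(base / roles["genotypes"], base / roles["snp_meta"])
    leaf = read_traits(base / roles["leaf_traits"]) if "leaf_traits" in roles else None
    oiv = read_traits(base / roles["oiv_traits"]) if "oiv_traits" in roles else None
    tree = read_newick(base / roles["tree"]) if "tree" in roles else None
    return InputBundle(loci, accessions, gm, leaf, oiv, tree)


def _inputs(config: PipelineConfig) -> InputBundle:
    if config.manifest is not None:
        return load_manifest(config.manifest)
    ds: SyntheticDataset = simulate(config.sim)
    return InputBundle(
        ds.loci, ds.accessions, ds.genotypes, ds.leaf_traits, ds.oiv_traits,
        ds.tree,
    )


def phase_all_loci(
    loci: dict[str, LocusAlignment],
    seed: int = 1,
    max_het_sites: int = 16,
) -> dict[str, HaplotypeSet]:
    out = {}
    for i, (locus, aln) in enumerate(sorted(loci.items())):
        sg = extract_snp_genotypes(aln)
        out[locus] = phase_em(sg, max_het_sites=max_het_sites, seed=seed + i)
    return out


def clade_supports(
    stree: dt.SupportTree, accessions: AccessionTable
) -> dict[str, float]:
    """Bootstrap support (0-100) of each clade's bipartition; 0 when the
    clade is not monophyletic in the base tree."""
    tips = stree.tip_names()
    out = {}
    for clade in sorted(set(accessions.df["clade_label"])):
        members = frozenset(
            a for a in accessions.members(clade, include_hybrids=True)
            if a in tips
        )
        if len(members) < 2 or len(members) > len(tips) - 2:
            continue
        other = frozenset(tips) - members
        key = min(members, other, key=lambda s: (len(s), sorted(s)))
        out[clade] = stree.supports.get(key, 0.0)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    result = PipelineResult(config=config)
    report = result.report
    report["seed"] = config.seed
    report["stages"] = list(config.stages)
    inputs = _inputs(config)
    stages = set(config.stages)

    try:
        concat = concatenate(list(inputs.loci.values()), "union_fill_N")

        if stages & {"phasing", "diversity", "hybrids", "networks"}:
            result.haplotype_sets = phase_all_loci(
                inputs.loci, seed=config.seed,
                max_het_sites=config.max_het_sites,
            )

        if "diversity" in stages:
            sc = pg.classify_sites(concat)
            report["site_classes"] = {
                "n_variable": sc.n_variable,
                "n_parsimony_informative": sc.n_parsimony_informative,
                "n_singleton": sc.n_singleton,
                "alignment_length": concat.length_bp,
                "n_accessions": concat.n_accessions,
            }
            out_ids = set(inputs.accessions.members("OUT", True))
            haps_by_locus, og_by_locus, lengths = {}, {}, {}
            for locus, h in result.haplotype_sets.items():
                haps_by_locus[locus] = h.all_haplotypes()
                og_by_locus[locus] = [
                    x for a in h.accession_ids if a in out_ids
                    for x in h.pairs[a]
                ]
                lengths[locus] = inputs.loci[locus].length_bp
            result.diversity = pg.diversity_table(
                haps_by_locus, og_by_locus, lengths
            )
            report["diversity_means"] = (
                result.diversity.loc["mean", ["theta_w", "pi", "he"]]
                .to_dict()
            )

        exclusion: set[str] = {
            a for a in inputs.accessions.accession_ids
            if inputs.accessions.is_known_hybrid(a)
        }
        if "hybrids" in stages:
            reports = hyb.hybrid_report(
                result.haplotype_sets,
                inputs.accessions,
                gm=inputs.genotypes,
                chlorotype_collapse_threshold=config.collapse_threshold,
            )
            result.hybrid_reports = reports
            detected = [r.accession for r in reports if r.is_hybrid_call]
            exclusion |= set(detected)
            report["hybrids"] = {
                "detected": detected,
                "excluded_from_reruns": sorted(exclusion),
            }
            if inputs.genotypes is not None:
                assignments, inf_ids = hyb.define_chlorotypes(inputs.genotypes)
                hyb.collapse_chlorotypes(assignments, config.collapse_threshold)
                report["chlorotypes"] = {
                    "n_informative_loci": len(inf_ids),
                    "n_chlorotypes": len(
                        {a.chlorotype_id for a in assignments}
                    ),
                    "n_collapsed_groups": len(
                        {a.collapsed_group_id for a in assignments}
                    ),
                }

        if "networks" in stages:
            for locus, h in result.haplotype_sets.items():
                haps, labels = [], []
                for acc in h.accession_ids:
                    clade = (
                        inputs.accessions.clade_of(acc)
                        if acc in inputs.accessions.accession_ids
                        else "UNKNOWN"
                    )
                    for hap in h.pairs[acc]:
                        if "?" in hap:
                            continue
                        haps.append(hap)
                        labels.append(clade)
                if len(set(haps)) >= 2:
                    result.networks[locus] = build_mj_network(
                        haps, clade_labels=labels, epsilon=config.epsilon
                    )
            report["networks"] = {
                locus: {
                    "n_nodes": len(net.nodes),
                    "n_median_vectors": sum(1 for n in net.nodes if n.inferred),
                    "total_cost": net.total_cost(),
                }
                for locus, net in result.networks.items()
            }

        if "trees" in stages:
            stree = dt.bootstrap_seq_tree(
                concat, B=config.bootstrap_B, seed=config.seed
            )
            result.trees["seq_all"] = stree
            keep = [a for a in concat.accession_ids if a not in exclusion]
            concat_pure = LocusAlignment(
                concat.locus_name + "_pure",
                keep,
                [concat.sequence_of(a) for a in keep],
            )
            stree_pure = dt.bootstrap_seq_tree(
                concat_pure, B=config.bootstrap_B, seed=config.seed + 1
            )
            result.trees["seq_hybrid_free"] = stree_pure
            report["clade_support_seq_hybrid_free"] = clade_supports(
                stree_pure, inputs.accessions
            )
            if inputs.genotypes is not None:
                gm_pure = inputs.genotypes.subset_accessions(
                    [a for a in inputs.genotypes.accession_ids
                     if a not in exclusion]
                )
                snp_tree = dt.bootstrap_snp_tree(
                    gm_pure, B=config.bootstrap_B, seed=config.seed + 2
                )
                result.trees["snp_hybrid_free"] = snp_tree
                report["clade_support_snp_hybrid_free"] = clade_supports(
                    snp_tree, inputs.accessions
                )

        if "ascertainment" in stages and inputs.genotypes is not None:
            gm_pure = inputs.genotypes.subset_accessions(
                [a for a in inputs.genotypes.accession_ids
                 if a not in exclusion]
            )
            nuclear = gm_pure.subset_snps(gm_pure.nuclear_snp_ids())
            n_panel = sum(
                nuclear.snp_meta.loc[s, "discovery_panel"] == config.panel_class
                for s in nuclear.snp_ids
            )
            targets = config.subsample_targets or tuple(
                max(1, int(n_panel * f)) for f in (0.5, 0.15, 0.05)
            )
            series = {}
            for label, gm_i in [("all", nuclear)] + [
                (str(t), dt.subsample_by_panel(
                    nuclear, config.panel_class, t, seed=config.seed))
                for t in targets
            ]:
                stree = dt.nj_tree(dt.snp_distance(gm_i))
                summary = dt.clade_branch_summary(stree, inputs.accessions)
                series[label] = {
                    clade: s["ratio_vs_overall"]
                    for clade, s in summary.items()
                }
            report["ascertainment"] = {
                "panel_class": config.panel_class,
                "targets": list(targets),
                "clade_ratio_series": series,
            }

        if "morpho" in stages and inputs.leaf_traits is not None:
            pure = [
                a for a in inputs.leaf_traits.accession_ids
                if a not in exclusion
            ]
            leaf = TraitTable(
                inputs.leaf_traits.values.loc[pure],
                inputs.leaf_traits.trait_types,
            )
            leaf_pca = ms.pca(leaf, scale=True)
            report["leaf_pca_pc1_pc2_percent"] = float(
                leaf_pca.percent_variance[:2].sum()
            )
            # phylogeny for signal tests: the sequence NJ surrogate tree if
            # available, else the provided tree
            tree = None
            if "seq_hybrid_free" in result.trees:
                tree = result.trees["seq_hybrid_free"].tree
            elif inputs.tree is not None:
                tree = inputs.tree
            if tree is not None:
                tips = {t.name for t in tree.tips()}
                scored = [a for a in pure if a in tips]
                sheared = tree.shear(scored)
                _, prox = ms.abouheif_proximity(sheared, tip_order=scored)
                leaf_scored = TraitTable(
                    leaf.values.loc[scored], leaf.trait_types
                )
                sig = ms.phylo_signal_table(
                    leaf_scored, prox, n_perm=config.n_perm, seed=config.seed
                )
                report["leaf_signal"] = {
                    "n_sig_0.01": int(sig["sig_0.01"].sum()),
                    "n_sig_0.05": int(sig["sig_0.05"].sum()),
                    "n_traits": len(sig),
                }
                pp = ms.ppca(leaf_scored, prox)
                report["leaf_ppca_top_eigenvalue"] = float(pp.eigenvalues[0])
                report["leaf_selected_traits"] = ms.select_top_loadings(
                    pp.loadings["pPC1"]
                )
                if inputs.oiv_traits is not None:
                    oiv = TraitTable(
                        inputs.oiv_traits.values.loc[
                            [a for a in scored
                             if a in inputs.oiv_traits.values.index]
                        ],
                        inputs.oiv_traits.trait_types,
                    )
                    oiv_pca = ms.pca(oiv, scale=True)
                    report["oiv_pca_pc1_pc2_percent"] = float(
                        oiv_pca.percent_variance[:2].sum()
                    )
                    sig_oiv = ms.phylo_signal_table(
                        oiv, prox.loc[oiv.accession_ids, oiv.accession_ids],
                        n_perm=config.n_perm, seed=config.seed + 1,
                    )
                    report["oiv_signal"] = {
                        "n_sig_0.01": int(sig_oiv["sig_0.01"].sum()),
                        "n_sig_0.05": int(sig_oiv["sig_0.05"].sum()),
                        "n_traits": len(sig_oiv),
                    }
    except Exception as exc:
        logger.exception("pipeline stage failed; returning partial bundle")
        result.failed_stage = f"{type(exc).__name__}: {exc}"
        report["partial"] = True
        report["failure"] = result.failed_stage
    return result
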