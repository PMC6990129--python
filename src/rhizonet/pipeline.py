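"""End-to-end orchestration of the two survey designs.

``run_gradient_analysis`` covers the multi-site design: table filters,
rarefaction, taxa-level group tests, alpha diversity, weighted
UniFrac / PCoA / PERMANOVA, per-site rhizosphere specificity with the
core-microbiome intersection, and the ensemble co-occurrence network.
``run_temporal_analysis`` covers the rainy-vs-dry-year design at a
single site, with the pooled bulk + bare reference for specificity and
the active/dormant rhizosphere overlap. Both take a single
:class:`PipelineConfig`, write tab-separated reports plus a JSON
summary into an output directory, and are deterministic given (inputs,
config, seed): one master seed is split into independent per-stage
substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

import rhizonet
from rhizonet import beta, diversity, network, specificity, synthetic, tables_io
from rhizonet.tables_io import CountTable, FilterConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one pipeline run.

    Exactly one of ``synthetic`` or the real-input paths
    (``fungal_table``/``bacterial_table``/``metadata``) must be set.
    """

    synthetic: synthetic.SyntheticConfig | None = None
    fungal_table: str | None = None
    bacterial_table: str | None = None
    metadata: str | None = None
    fungal_tree: str | None = None
    bacterial_tree: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    specificity: specificity.SpecificityConfig = field(
        default_factory=specificity.SpecificityConfig
    )
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    adonis_factors: tuple[str, ...] = ("site", "habitat")
    n_permutations: int = 999
    rarefaction_depth: int | None = None
    out_dir: str = "rhizonet_out"
    seed: int = 0

    def __post_init__(self):
        synthetic_set = self.synthetic is not None
        real_set = self.fungal_table is not None
        if synthetic_set == real_set:
            raise ValueError("set exactly one of synthetic config or input paths")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        fungal, bacterial, metadata, truth = synthetic.generate_dataset(config.synthetic)
        tax = None
    else:
        fungal, tax_f = tables_io.read_count_table(config.fungal_table)
        bacterial, tax_b = tables_io.read_count_table(config.bacterial_table)
        metadata = tables_io.read_metadata(config.metadata)
        parts = [t for t in (tax_f, tax_b) if t is not None]
        tax = pd.concat(parts) if parts else None
        truth = None
    tables_io.validate_metadata(metadata)
    return fungal, bacterial, metadata, tax, truth


def _filter_and_rarefy(table: CountTable, tax, config: PipelineConfig, seed: int):
    filtered = tables_io.filter_low_count_otus(table, config.filters)
    filtered = tables_io.remove_organelle_otus(filtered, tax, config.filters)
    rarefied = tables_io.rarefy(filtered, depth=config.rarefaction_depth, seed=seed)
    return filtered, rarefied


def _kingdom_stages(
    name: str,
    filtered: CountTable,
    rarefied: CountTable,
    metadata: pd.DataFrame,
    tree,
    config: PipelineConfig,
    seeds: list[int],
    out: Path,
    summary: dict,
):
    """Alpha, beta/ordination/ADONIS and specificity for one kingdom."""
    md = metadata.loc[[s for s in rarefied.sample_ids if s in metadata.index]].copy()
    md["group"] = md["site"].astype(str) + ":" + md["habitat"].astype(str)

    alpha_df, alpha_cmp = diversity.alpha_by_group(rarefied, md, factor="group")
    report = alpha_df.copy()
    for metric, cmp in alpha_cmp.items():
        if cmp is not None:
            report[f"{metric}_letter"] = [
                cmp.letters.get(md.loc[s, "group"], "") for s in report.index
            ]
    report.to_csv(out / f"{name}_alpha.tsv", sep="\t")
    summary[f"{name}_alpha_anova_p"] = {
        m: (c.p_value if c else None) for m, c in alpha_cmp.items()
    }

    dm = beta.weighted_unifrac(rarefied.drop_empty_otus(), tree)
    beta.write_distance_matrix(dm, out / f"{name}_weighted_unifrac.tsv")
    ord_res = beta.pcoa(dm, dimensions=3)
    coords = ord_res.samples
    coords.to_csv(out / f"{name}_pcoa.tsv", sep="\t")
    adonis_rows = []
    for i, factor in enumerate(config.adonis_factors):
        if factor not in md.columns:
            logger.warning("ADONIS factor %r not in metadata; skipped", factor)
            continue
        res = beta.adonis(dm, md, factor, n_permutations=config.n_permutations,
                          seed=seeds[3] + i)
        adonis_rows.append(
            {"factor": factor, "R2": res.r2, "pseudo_F": res.pseudo_f,
             "p": res.p_value, "permutations": res.n_permutations}
        )
    pd.DataFrame(adonis_rows).to_csv(out / f"{name}_adonis.tsv", sep="\t", index=False)
    summary[f"{name}_adonis"] = adonis_rows

    per_site: dict[str, set[str]] = {}
    exclusive: dict[str, set[str]] = {}
    for site in sorted(md["site"].astype(str).unique()):
        habs = set(md.loc[md["site"].astype(str) == site, "habitat"])
        if "rhizosphere" not in habs or not ({"bulk", "bare"} & habs):
            logger.warning("site %s lacks a habitat; specificity skipped", site)
            continue
        rec = specificity.specificity_records(rarefied, md, site, config.specificity)
        rec.to_csv(out / f"{name}_specificity_{site}.tsv", sep="\t")
        per_site[site] = set(rec.index[rec["specific"]])
        exclusive[site] = set(rec.index[rec["specific"] & rec["exclusive"]])
    core = specificity.core_microbiome(per_site) if per_site else None
    if core is not None:
        core.venn_table().to_csv(out / f"{name}_venn.tsv", sep="\t", index=False)
        summary[f"{name}_specific_per_site"] = {k: len(v) for k, v in per_site.items()}
        summary[f"{name}_exclusive_per_site"] = {k: len(v) for k, v in exclusive.items()}
        summary[f"{name}_core_otus"] = sorted(core.core)
    return per_site, core


def run_gradient_analysis(config: PipelineConfig) -> dict:
    """Multi-site (latitudinal-gradient style) analysis; returns the
    report bundle as a dict and writes everything under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    fungal, bacterial, metadata, tax, truth = _load_inputs(config)
    summary: dict = {
        "design": "gradient",
        "version": rhizonet.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "rarefaction_depth": config.rarefaction_depth,
        "n_permutations": config.n_permutations,
    }
    bundle: dict = {"summary": summary, "truth": truth}

    results = {}
    for name, table, tree_path, seed in (
        ("fungal", fungal, config.fungal_tree, seeds[0]),
        ("bacterial", bacterial, config.bacterial_tree, seeds[1]),
    ):
        filtered, rarefied = _filter_and_rarefy(table, tax, config, seed)
        if tree_path is not None:
            tree = beta.read_tree(tree_path)
        else:
            tree = synthetic.generate_tree(filtered.otu_ids, seed=seed)
        if tax is not None:
            rel = diversity.aggregate_by_rank(rarefied, tax, "phylum")
            anova, ttests = diversity.test_taxa_between_groups(rel, metadata)
            ttests.to_csv(out / f"{name}_taxa_ttests.tsv", sep="\t", index=False)
        per_site, core = _kingdom_stages(
            name, filtered, rarefied, metadata, tree, config, seeds, out, summary
        )
        results[name] = {
            "filtered": filtered, "rarefied": rarefied,
            "per_site_specific": per_site, "core": core,
        }
    bundle.update(results)

    merged, kingdom = network.merge_kingdom_tables(
        results["fungal"]["filtered"], results["bacterial"]["filtered"],
        min_otu_reads=config.network.min_otu_reads,
    )
    net_config = replace(config.network, seed=seeds[2])
    net = network.build_network(merged, kingdom, net_config)
    network.write_edge_list(net, out / "network_edges.tsv")
    network.write_gml(net, out / "network.gml")
    summary["network_nodes"] = int(net.graph.number_of_nodes())
    summary["network_edges"] = int(net.graph.number_of_edges())
    summary["network_candidates"] = int(net.n_candidates)
    summary["network_clusters"] = [sorted(c) for c in net.clusters]
    bundle["network"] = net
    if net.clusters:
        profile, cluster_cmp = network.cluster_abundance_profile(net, merged, metadata)
        profile.to_csv(out / "cluster_abundance.tsv", sep="\t")
        net.cluster_membership().to_csv(out / "cluster_membership.tsv", sep="\t")
        summary["cluster_anova_p"] = {
            c: (cmp.p_value if cmp else None) for c, cmp in cluster_cmp.items()
        }
        bundle["cluster_profile"] = profile

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return bundle


def run_temporal_analysis(config: PipelineConfig) -> dict:
    """Rainy-vs-dry-year analysis at one site.

    Per-year alpha diversity, PERMANOVA on the factors year and sample
    type, rainy-year specificity against the pooled bulk + bare
    reference, and the overlap of the active-rhizosphere specific set
    with the full dormant-rhizosphere community.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    if config.synthetic is not None:
        fungal, bacterial, metadata, truth = synthetic.generate_temporal_dataset(
            config.synthetic
        )
        tax = None
    else:
        fungal, bacterial, metadata, tax, truth = _load_inputs(config)[:5]
    tables_io.validate_metadata(metadata)
    years = sorted(metadata["year"].unique())
    if len(years) != 2:
        raise ValueError(f"temporal design needs exactly 2 years, got {years}")
    rainy, dry = years
    summary: dict = {
        "design": "temporal", "version": rhizonet.__version__, "seed": config.seed,
        "years": {"rainy": int(rainy), "dry": int(dry)},
    }
    bundle: dict = {"summary": summary, "truth": truth}
    spec_cfg = replace(config.specificity, reference_mode="bulk_plus_bare")

    for name, table, seed in (("fungal", fungal, seeds[0]), ("bacterial", bacterial, seeds[1])):
        filtered, rarefied = _filter_and_rarefy(table, tax, config, seed)
        md = metadata.loc[[s for s in rarefied.sample_ids if s in metadata.index]].copy()
        md["group"] = md["year"].astype(str) + ":" + md["habitat"].astype(str)
        md["year_label"] = md["year"].astype(str)
        alpha_df, alpha_cmp = diversity.alpha_by_group(rarefied, md, factor="group")
        alpha_df.to_csv(out / f"{name}_alpha.tsv", sep="\t")
        summary[f"{name}_alpha_anova_p"] = {
            m: (c.p_value if c else None) for m, c in alpha_cmp.items()
        }
        tree = synthetic.generate_tree(filtered.otu_ids, seed=seed)
        dm = beta.weighted_unifrac(rarefied.drop_empty_otus(), tree)
        beta.write_distance_matrix(dm, out / f"{name}_weighted_unifrac.tsv")
        adonis_rows = []
        for i, factor in enumerate(("year_label", "habitat")):
            res = beta.adonis(dm, md, factor, n_permutations=config.n_permutations,
                              seed=seeds[3] + i)
            adonis_rows.append(
                {"factor": "year" if factor == "year_label" else "sample_type",
                 "R2": res.r2, "pseudo_F": res.pseudo_f, "p": res.p_value}
            )
        pd.DataFrame(adonis_rows).to_csv(out / f"{name}_adonis.tsv", sep="\t", index=False)
        summary[f"{name}_adonis"] = adonis_rows

        rainy_ids = md.index[md["year"] == rainy]
        dry_rhizo_ids = md.index[(md["year"] == dry) & (md["habitat"] == "rhizosphere")]
        rainy_table = rarefied.select_samples(list(rainy_ids))
        site = str(md["site"].astype(str).iloc[0])
        rec = specificity.specificity_records(rainy_table, md, site, spec_cfg)
        rec.to_csv(out / f"{name}_specificity_rainy.tsv", sep="\t")
        active_specific = set(rec.index[rec["specific"]])
        active_rhizo = rainy_table.select_samples(
            [s for s in rainy_ids if md.loc[s, "habitat"] == "rhizosphere"]
        )
        dormant = rarefied.select_samples(list(dry_rhizo_ids))
        overlap = specificity.temporal_overlap(active_specific, active_rhizo, dormant)
        overlap.to_csv(out / f"{name}_temporal_overlap.tsv", sep="\t")
        summary[f"{name}_n_active_specific"] = len(active_specific)
        summary[f"{name}_n_shared_active_dormant"] = int(len(overlap))
        bundle[name] = {
            "rarefied": rarefied, "specific": active_specific, "overlap": overlap,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return bundle
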