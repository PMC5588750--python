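"""End-to-end orchestration: filter -> RPKM -> taxa -> diversity -> DE ->
enrichment -> ordination -> coordinated pathway runs.

A :class:`PipelineConfig` (loadable from YAML) either points at the three
input TSVs plus a pathway definition, or embeds a synthetic-data
configuration.  ``run_pipeline`` executes every stage, writes one TSV per
result table plus a JSON manifest of seeds, thresholds and per-stage row
counts, and is byte-reproducible under a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import diversity as div_mod
from . import multivariate as mv
from . import pathways as pw
from . import quantify as qt
from .data_model import COMPARISONS, AnnotatedCounts, load_dataset, write_table
from .synthetic import SynthConfig, generate_dataset, save_synthetic

logger = logging.getLogger("gutmtx")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; every stochastic stage has its own seed."""

    outdir: str = "results"
    # either input paths ...
    counts: str | None = None
    annotations: str | None = None
    samples: str | None = None
    pathway: str | None = None  # KGML or edge-list; optional
    # ... or a synthetic spec
    synthetic: dict[str, Any] | None = None
    # thresholds
    min_reads: int = 5
    q_cut: float = 0.05
    log2_efc_cut: float = 2.0
    rpkm_tiers: tuple[float, ...] = (0.0, 10.0, 100.0)
    min_run_length: int = 3
    distance_metric: str = "bray-curtis"
    n_perm: int = 9999
    rarefaction_depths: int = 5  # grid points up to the smallest library
    rarefaction_reps: int = 20
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.q_cut <= 0 or self.log2_efc_cut <= 0:
            raise ValueError("thresholds must be positive")
        if self.synthetic is None and not (self.counts and self.annotations and self.samples):
            raise ValueError("config needs either input paths or a synthetic spec")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rpkm_tiers" in raw:
            raw["rpkm_tiers"] = tuple(raw["rpkm_tiers"])
        return cls(**raw)


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.synthetic is not None:
        synth = SynthConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        data, truth = generate_dataset(synth)
        save_synthetic(data, truth, outdir / "synthetic")
        pathway = truth.pathway
        logger.info("simulated %d transcripts x %d samples", data.n_transcripts, data.n_samples)
        return data, pathway
    data = load_dataset(config.counts, config.annotations, config.samples)
    pathway = pw.build_pathway_graph(config.pathway) if config.pathway else None
    logger.info("loaded %d transcripts x %d samples", data.n_transcripts, data.n_samples)
    return data, pathway


def _pathway_sets(pathway: nx.DiGraph) -> dict[str, set[str]]:
    """Enrichment sets from a pathway graph: one set per weakly connected
    component (a multi-pathway file yields one set per pathway)."""
    pid = pathway.graph.get("pathway_id", "pathway")
    comps = list(nx.weakly_connected_components(pathway))
    if len(comps) == 1:
        return {pid: set(comps[0])}
    return {f"{pid}.{i + 1}": set(c) for i, c in enumerate(sorted(map(sorted, comps)))}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }

    data, pathway = _load_or_simulate(config, outdir)

    # --- quantification -------------------------------------------------
    filtered, report = qt.filter_low_expression(data, min_reads=config.min_reads)
    expr = qt.rpkm(filtered)
    expr.min_reads = config.min_reads
    write_table(
        expr.rpkm.rename_axis("transcript_id").reset_index(), outdir / "expression.tsv"
    )
    taxa_table = qt.taxon_abundance(expr, filtered.annotations, filtered.taxa)
    write_table(taxa_table.reset_index(), outdir / "taxon_abundance.tsv")
    partitions = qt.presence_partition(expr, filtered.samples, config.rpkm_tiers)
    for threshold, part in partitions.items():
        rows = [
            {"groups": "+".join(key), "count": count}
            for key, count in sorted(part.region_counts.items())
        ]
        write_table(pd.DataFrame(rows), outdir / f"venn_{threshold:g}.tsv")
    totals = filtered.counts.sum(axis=0)
    depth_grid = np.unique(
        np.linspace(0, int(totals.min()), config.rarefaction_depths + 1).astype(int)
    )
    rare = qt.rarefaction_curve(
        filtered, depth_grid, reps=config.rarefaction_reps, seed=config.seed
    )
    write_table(rare.reset_index(), outdir / "rarefaction.tsv")
    manifest["stages"]["quantify"] = {
        "n_removed": report.n_removed,
        "n_retained": report.n_retained,
        "removed_reads_fraction": report.removed_reads_fraction,
        "venn_present": {f"{t:g}": p.n_present for t, p in partitions.items()},
    }
    logger.info(
        "filtered %d low-expression transcripts (%.2f%% of reads)",
        report.n_removed,
        100 * report.removed_reads_fraction,
    )

    # --- diversity ------------------------------------------------------
    summary, tests = div_mod.diversity_report(filtered, expr, seed=config.seed)
    flat = summary.copy()
    flat.columns = [f"{index}_{stat}" for index, stat in flat.columns]
    write_table(flat.reset_index(), outdir / "diversity.tsv")
    write_table(tests, outdir / "diversity_tests.tsv")
    manifest["stages"]["diversity"] = {"n_groups": len(summary)}

    # --- differential expression ---------------------------------------
    sf = de_mod.size_factors(filtered.counts)
    group_ids = [
        list(filtered.samples.index[(filtered.group_labels == g)])
        for g in sorted(filtered.group_labels.unique())
    ]
    model = de_mod.fit_dispersions(filtered.counts, sf, group_ids)
    has_ec = filtered.annotations["ec_numbers"].map(len).gt(0).any()
    de_tables: dict[str, pd.DataFrame] = {}
    enzyme_tables: dict[str, pd.DataFrame] = {}
    taxon_aefc: dict[str, pd.DataFrame] = {}
    de_counts: dict[str, Any] = {}
    for name, spec in COMPARISONS.items():
        result = de_mod.run_comparison(
            filtered, expr, model, spec, q_cut=config.q_cut, log2_efc_cut=config.log2_efc_cut
        )
        de_tables[name] = result
        write_table(result, outdir / f"de_{name}.tsv")
        de_counts[name] = {"n_sig": int(result["is_sig"].sum())}
        if has_ec:
            enzymes, per_taxon = de_mod.enzyme_aggregate(
                result, expr, filtered.annotations, spec, filtered.samples, filtered.taxa
            )
            enzyme_tables[name] = enzymes
            taxon_aefc[name] = per_taxon
            write_table(enzymes, outdir / f"enzymes_{name}.tsv")
            write_table(
                per_taxon.reset_index(), outdir / f"enzymes_taxon_aefc_{name}.tsv"
            )
            de_counts[name]["n_sig_enzymes"] = int(enzymes["is_sig"].sum())
        logger.info("%s: %d significant transcripts", name, de_counts[name]["n_sig"])
    manifest["stages"]["de"] = de_counts

    # --- enrichment -----------------------------------------------------
    universe = set(expr.rpkm.index[(expr.rpkm > 0).any(axis=1)])
    taxon_sets = {
        taxon: set(filtered.annotations.index[filtered.annotations["taxon"] == taxon])
        for taxon in filtered.taxa
    }
    enrich_counts: dict[str, Any] = {}
    for name, result in de_tables.items():
        sig_ids = set(result.loc[result["is_sig"], "transcript_id"]) & universe
        taxa_enrich = pw.hypergeom_enrich(taxon_sets, universe, sig_ids)
        write_table(taxa_enrich, outdir / f"enrichment_taxa_{name}.tsv")
        enrich_counts[name] = {
            "taxa_enriched": int((taxa_enrich["q"] < config.q_cut).sum())
        }
    if has_ec and pathway is not None:
        sets = _pathway_sets(pathway)
        for name, enzymes in enzyme_tables.items():
            ec_universe = set(enzymes["ec"])
            sig_ecs = set(enzymes.loc[enzymes["is_sig"], "ec"])
            path_enrich = pw.hypergeom_enrich(sets, ec_universe, sig_ecs)
            write_table(path_enrich, outdir / f"enrichment_pathways_{name}.tsv")
            enrich_counts[name]["pathways_enriched"] = int(
                (path_enrich["q"] < config.q_cut).sum()
            )
            enrich_counts[name]["pathways_tested"] = int(len(path_enrich))
    else:
        logger.warning("no EC annotations or pathway file: enrichment of pathways skipped")
    manifest["stages"]["enrichment"] = enrich_counts

    # --- multivariate ---------------------------------------------------
    labels = {
        "genotype": filtered.samples["genotype"].to_numpy(),
        "diet": filtered.samples["diet"].to_numpy(),
    }
    d_taxa = mv.distance(taxa_table.T, metric=config.distance_metric)
    perm_overall = mv.permanova(d_taxa, labels, n_perm=config.n_perm, seed=config.seed)
    perm_overall.insert(0, "response", "taxon_abundance")
    per_taxon_rows = []
    for taxon in taxa_table.index:
        row = taxa_table.loc[[taxon]].T
        if (row.to_numpy() == 0).all():
            continue
        res = mv.permanova(
            mv.distance(row, metric="euclidean"), labels, n_perm=config.n_perm, seed=config.seed
        )
        res.insert(0, "response", taxon)
        per_taxon_rows.append(res)
    perm_all = pd.concat([perm_overall] + per_taxon_rows, ignore_index=True)
    perm_all["q"] = pw.bh_adjust(perm_all["p"])  # one family, per the study's adjustment
    write_table(perm_all, outdir / "permanova.tsv")

    pca_expr = mv.pca(expr.rpkm.T)
    write_table(
        pca_expr.scores.rename_axis("sample_id").reset_index(), outdir / "pca_scores.tsv"
    )
    write_table(
        pca_expr.variance_fraction.rename_axis("component").reset_index(),
        outdir / "pca_variance.tsv",
    )
    pc_tests = mv.pc_separation_test(
        pca_expr, filtered.samples, n_perm=config.n_perm, seed=config.seed
    )
    write_table(pc_tests, outdir / "pca_separation.tsv")
    manifest["stages"]["multivariate"] = {
        "n_permanova": int(len(perm_all)),
        "pc1_variance": float(pca_expr.variance_fraction.iloc[0]),
    }

    # --- coordinated pathway runs ---------------------------------------
    if has_ec and pathway is not None:
        run_counts = {}
        for name, enzymes in enzyme_tables.items():
            values = dict(
                zip(enzymes.loc[enzymes["is_sig"], "ec"], enzymes.loc[enzymes["is_sig"], "aefc"])
            )
            runs = pw.find_coordinated_runs(
                pathway, values, min_len=config.min_run_length, comparison=name
            )
            rows = [
                {
                    "comparison": r.comparison,
                    "direction": r.direction,
                    "length": r.length,
                    "mean_abs_aefc": r.mean_abs_aefc,
                    "ecs": ">".join(r.ecs),
                }
                for r in runs
            ]
            write_table(
                pd.DataFrame(rows, columns=["comparison", "direction", "length", "mean_abs_aefc", "ecs"]),
                outdir / f"runs_{name}.tsv",
            )
            pw.export_cytoscape(
                pathway,
                dict(zip(enzymes["ec"], enzymes["aefc"])),
                set(enzymes.loc[enzymes["is_sig"], "ec"]),
                outdir / f"pathway_{name}",
            )
            run_counts[name] = len(runs)
        manifest["stages"]["pathway_runs"] = run_counts
    else:
        logger.warning("no EC annotations or pathway file: coordinated-run stage skipped")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
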