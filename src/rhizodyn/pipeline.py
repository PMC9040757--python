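"""Pipeline orchestration: stage wiring, artifacts and the run manifest.

``run_pipeline`` executes, per kingdom: rarefaction -> alpha diversity
(repeated-rarefaction Shannon + rank-sum group comparisons) -> beta
diversity (Bray-Curtis, PCoA, PERMANOVA) -> the phylum pipeline
(aggregation, rare-phylum grouping, phylum-level Bray-Curtis) ->
the stable/dynamic partition -> the convergence level contrast ->
taxa-metabolite covariation (root samples only).  Every stage writes
tidy tab-separated artifacts; a JSON manifest records stage order,
derived seeds, sample/taxon counts after every filter, and versions.

The master seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage_index,))``, so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    aggregate_taxa,
    group_rare_taxa,
    rarefy,
    read_metadata,
    read_table,
    read_taxonomy,
    to_relative,
    write_metadata,
    write_table,
    write_taxonomy,
)
from .covariation import (
    MetaboliteMatrix,
    correlation_network,
    preprocess_metabolites,
    rank_predictive_taxa,
    stage_ra_ratio,
)
from .convergence import level_contrast
from .diversity import bray_curtis, pcoa, permanova, rarefied_shannon, wilcoxon_fdr
from .stability import compartment_overlap, partition_table, stability_partition
from .synthetic_data import SimConfig, generate_experiment, generate_metabolites

STAGES = (
    "rarefaction",
    "alpha_diversity",
    "beta_diversity",
    "phylum_pipeline",
    "stability",
    "convergence",
    "covariation",
)

_DEFAULT_DEPTHS = {"bacteria": 1000, "fungi": 10000, "oomycetes": 2000}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Paths and tunables of a pipeline run.

    Defaults follow the analysis conventions: rarefaction depths of
    1000 (bacteria), 10000 (fungi) and 2000 (oomycetes); 999
    rarefactions for the Shannon index; prevalence threshold 0.8 for
    the stable partition; |rho| > 0.5 and p < 0.05 with K = 25 taxa for
    the covariation network; 999 permutations for every permutation
    test.
    """

    table_paths: Mapping[str, str]  # kingdom -> count-table path (taxa-in-rows)
    metadata_path: str
    taxonomy_path: str
    metabolite_paths: Mapping[str, str] = field(default_factory=dict)
    output_dir: str = "rhizodyn_out"
    rarefaction_depths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_DEPTHS)
    )
    n_rarefactions: int = 999
    stability_threshold: float = 0.8
    r_min: float = 0.5
    alpha: float = 0.05
    k_taxa: int = 25
    n_trees: int = 500
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        for kingdom, depth in self.rarefaction_depths.items():
            if depth <= 0:
                raise ValueError(f"rarefaction depth for {kingdom!r} must be positive")
        if not 0.0 < self.stability_threshold < 1.0:
            raise ValueError("stability threshold must lie in (0, 1)")


def _stage_seed(master: int, stage_index: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for every kingdom; return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, i) for i, s in enumerate(STAGES)},
        "stages": [],
        "kingdoms": {},
    }

    stage = "input"
    try:
        metadata = read_metadata(config.metadata_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        tables = {
            k: read_table(p, orientation="taxa-in-rows", kingdom=k)
            for k, p in config.table_paths.items()
        }
        for k, t in tables.items():
            metadata.validate_against(t)
    except Exception as exc:
        raise PipelineError(f"stage 'input' (metadata/taxonomy/table readers): {exc}") from exc

    for kingdom, table in tables.items():
        kdir = out / kingdom
        kdir.mkdir(exist_ok=True)
        log: dict = {"n_samples_raw": table.shape[0], "n_taxa_raw": table.shape[1]}
        depth = config.rarefaction_depths.get(kingdom, 1000)

        try:
            stage = "rarefaction"
            seed = manifest["stage_seeds"][stage]
            rr = rarefy(table, depth, seed=seed)
            rare = rr.table
            log["rarefaction_depth"] = depth
            log["n_dropped_below_depth"] = len(rr.dropped)
            log["dropped_samples"] = rr.dropped
            write_table(rare, kdir / "rarefied.tsv")

            stage = "alpha_diversity"
            seed = manifest["stage_seeds"][stage]
            shannon_vals, _ = rarefied_shannon(
                table, depth, n_rarefactions=config.n_rarefactions, seed=seed
            )
            alpha = shannon_vals.to_frame()
            alpha["compartment"] = metadata.data.loc[alpha.index, "compartment"]
            alpha["stage"] = metadata.data.loc[alpha.index, "stage"]
            alpha.index.name = "sample_id"
            alpha.to_csv(kdir / "alpha_shannon.tsv", sep="\t", float_format="%.6f")
            comp_cmp = wilcoxon_fdr(
                alpha["shannon"], alpha["compartment"], alpha=config.alpha
            )
            comp_cmp.pairs.to_csv(
                kdir / "alpha_compartment_tests.tsv", sep="\t",
                index=False, float_format="%.6g",
            )
            rows = []
            for compartment in alpha["compartment"].unique():
                sub = alpha[alpha["compartment"] == compartment]
                if sub["stage"].nunique() < 2 or (sub.groupby("stage").size() < 2).any():
                    continue
                cmp_st = wilcoxon_fdr(sub["shannon"], sub["stage"], alpha=config.alpha)
                t = cmp_st.pairs.assign(compartment=compartment)
                rows.append(t)
            if rows:
                pd.concat(rows).to_csv(
                    kdir / "alpha_stage_tests.tsv", sep="\t",
                    index=False, float_format="%.6g",
                )

            stage = "beta_diversity"
            seed = manifest["stage_seeds"][stage]
            dm = bray_curtis(rare)
            dm.write(kdir / "bray_curtis.tsv")
            ord_res = pcoa(dm, n_axes=4)
            ord_res.coordinates.to_csv(
                kdir / "pcoa_coordinates.tsv", sep="\t", float_format="%.6g"
            )
            pd.DataFrame(
                {
                    "eigenvalue": ord_res.eigenvalues[: len(ord_res.proportion_explained)],
                    "proportion_explained": ord_res.proportion_explained,
                }
            ).to_csv(kdir / "pcoa_eigenvalues.tsv", sep="\t", float_format="%.6g")
            terms = ["compartment", "stage", "management"]
            usable = [
                t for t in terms if metadata.data.loc[dm.sample_ids, t].nunique() > 1
            ]
            perma = permanova(dm, metadata, usable, n_perm=config.n_perm, seed=seed)
            perma.table.to_csv(kdir / "permanova.tsv", sep="\t", float_format="%.6g")

            stage = "phylum_pipeline"
            rel = to_relative(rare)
            phylum = aggregate_taxa(rel, taxonomy, "phylum")
            phylum = group_rare_taxa(phylum, threshold=0.001)
            write_table(phylum, kdir / "phylum_relative.tsv")
            phylum_dm = bray_curtis(phylum)
            phylum_dm.write(kdir / "bray_curtis_phylum.tsv")

            stage = "stability"
            partitions = {}
            for compartment in ("rhizosphere", "root"):
                ids = metadata.select(
                    compartment=compartment, stage=("vegetative", "reproductive")
                )
                if not any(s in rare.data.index for s in ids):
                    continue
                part = stability_partition(
                    rel, metadata, compartment,
                    detection_table=rare,
                    threshold=config.stability_threshold,
                )
                part.to_json(kdir / f"stability_{compartment}.json")
                partition_table(part, rare, metadata).to_csv(
                    kdir / f"stability_{compartment}.tsv", sep="\t",
                    index=False, float_format="%.6g",
                )
                partitions[compartment] = part
            if len(partitions) >= 2:
                overlap = compartment_overlap(
                    {c: p.stable for c, p in partitions.items()}
                )
                overlap_doc = {
                    "+".join(sorted(k)): v for k, v in overlap.items()
                }
                (kdir / "stable_overlap.json").write_text(
                    json.dumps(overlap_doc, indent=2, sort_keys=True)
                )
            log["n_stable_root"] = (
                len(partitions["root"].stable) if "root" in partitions else None
            )

            stage = "convergence"
            seed = manifest["stage_seeds"][stage]
            init_set = [
                s
                for s in metadata.select(compartment="soil", stage="unplanted")
                if s in rel.data.index
            ]
            final_set = [
                s
                for s in metadata.select(compartment="root", stage="reproductive")
                if s in rel.data.index
            ]
            group_a = [
                s
                for s in metadata.select(compartment="soil", stage="vegetative")
                if s in rel.data.index
            ]
            group_b = [
                s
                for s in metadata.select(compartment="soil", stage="reproductive")
                if s in rel.data.index
            ]
            if init_set and final_set and group_a and group_b:
                phylum_rel = aggregate_taxa(rel, taxonomy, "phylum")
                contrast = level_contrast(
                    rel, phylum_rel, init_set, final_set, group_a, group_b,
                    n_perm=config.n_perm, seed=seed,
                )
                contrast.to_json(kdir / "convergence_contrast.json")
                log["convergence"] = contrast.__dict__
            else:
                log["convergence"] = "skipped (missing reference or group samples)"

            stage = "covariation"
            seed = manifest["stage_seeds"][stage]
            met_path = config.metabolite_paths.get(kingdom)
            if met_path:
                metab = MetaboliteMatrix.read(met_path)
                metab = preprocess_metabolites(metab)
                root_ids = [
                    s
                    for s in metadata.select(compartment="root")
                    if s in rel.data.index and s in metab.data.index
                ]
                root_rel = rel.subset_samples(root_ids)
                ranking = rank_predictive_taxa(
                    root_rel, metab, k=config.k_taxa,
                    n_trees=config.n_trees, seed=seed,
                )
                ranking.scores.rename("importance").to_csv(
                    kdir / "predictive_taxa.tsv", sep="\t", float_format="%.6g"
                )
                network = correlation_network(
                    root_rel, metab, list(ranking.scores.index),
                    r_min=config.r_min, alpha=config.alpha,
                )
                ratios_taxa = stage_ra_ratio(
                    root_rel.data, metadata, list(ranking.scores.index)
                )
                ratios_cmp = stage_ra_ratio(
                    metab.data, metadata, metab.compound_ids
                )
                network.node_ratios = pd.concat([ratios_taxa, ratios_cmp])
                network.write_tables(
                    kdir / "network_nodes.tsv", kdir / "network_edges.tsv"
                )
                network.to_graphml(kdir / "network.graphml")
                log["n_network_edges"] = len(network.edges)
            else:
                log["covariation"] = "skipped (no metabolite matrix)"
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed for kingdom {kingdom!r}: {exc}"
            ) from exc

        manifest["kingdoms"][kingdom] = log

    manifest["stages"] = list(STAGES)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_demo(directory: str | Path, seed: int = 0) -> PipelineConfig:
    """Write a small synthetic experiment bundle and its truth ledger.

    Emits per-kingdom count tables, metadata, taxonomy, a bacterial
    metabolite matrix and the truth JSON, and returns a
    ``PipelineConfig`` pointing at the files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = SimConfig.demo(seed=seed)
    experiment = generate_experiment(config)
    table_paths = {}
    for kingdom, table in experiment.tables.items():
        path = directory / f"{kingdom}_counts.tsv"
        write_table(table, path)
        table_paths[kingdom] = str(path)
    write_metadata(experiment.metadata, directory / "metadata.tsv")
    write_taxonomy(experiment.taxonomy, directory / "taxonomy.tsv")
    rel_bac = to_relative(experiment.tables["bacteria"])
    metab = generate_metabolites(
        experiment.metadata, rel_bac, experiment.truth, config
    )
    metab.write(directory / "bacteria_metabolites.tsv")
    experiment.truth.to_json(directory / "truth.json")
    return PipelineConfig(
        table_paths=table_paths,
        metadata_path=str(directory / "metadata.tsv"),
        taxonomy_path=str(directory / "taxonomy.tsv"),
        metabolite_paths={"bacteria": str(directory / "bacteria_metabolites.tsv")},
        output_dir=str(directory / "results"),
        seed=seed,
    )
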