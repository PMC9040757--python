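"""Synthetic field-experiment generator with known ground truth.

Emulates the statistical structure the analysis assumes, for a design
of 3 compartments (soil, rhizosphere, root) x 3 sampling times
(unplanted, vegetative, reproductive) x 4 soil managements x up to 5
genotypes with replicated plants per plot:

* every condition has a latent composition ``pi``; counts are drawn
  Dirichlet-multinomial(alpha0 * pi, depth) with log-normal depths
  around 3x the kingdom's rarefaction depth, so rarefaction drops a
  small known fraction of samples;
* a planted *stable core* of taxa carries a fixed share of the
  community (``core_mean_ra``) at both planted stages in the
  rhizosphere and root, while every other ("dynamic") taxon is
  strongly suppressed away from its preferred stage;
* soil and rhizosphere phylum compositions are pulled toward the
  reproductive-root ("final") phylum composition with strength
  ``kappa_s`` (0 when unplanted, kappa/2 vegetative, kappa
  reproductive), broadcast proportionally to member taxa -- so the
  host footprint is a phylum-level, not ASV-level, signal;
* root metabolite compounds respond to growth stage and, for planted
  links, to a taxon's (standardized) relative abundance with effect
  size beta, through an exponential link that keeps intensities
  positive.

The generator writes the same file formats ``core_data`` reads and a
JSON truth ledger, and is byte-deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import CommunityTable, SampleMetadata, TaxonomyMap
from .covariation import MetaboliteMatrix

_DEFAULT_DEPTHS = {"bacteria": 1000, "fungi": 10000, "oomycetes": 2000}
_DEMO_MANAGEMENTS = ("NK", "NPK")  # DEMO field; CONMIN/BIODYN belong to DOK


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    The default design mirrors the field layout: one plot for each of
    NK and NPK, three plots for each of CONMIN and BIODYN, five
    genotypes, six replicate plants per genotype x plot x stage, six
    unplanted and three bulk-soil samples per plot.
    """

    kingdoms: tuple[str, ...] = ("bacteria", "fungi", "oomycetes")
    n_taxa: int = 150
    n_phyla: int = 10
    managements: tuple[str, ...] = ("NK", "NPK", "CONMIN", "BIODYN")
    plots_per_management: Mapping[str, int] | None = None
    genotypes: tuple[str, ...] = ("B73", "PH207", "DK105", "F2", "pht1;6")
    n_replicates: int = 6
    n_unplanted_per_plot: int = 6
    n_soil_per_plot_stage: int = 3
    stable_core_size: int = 20
    core_mean_ra: float = 0.4
    convergence_strength: float = 0.5  # kappa at the reproductive stage
    kappa_vegetative_fraction: float = 0.5  # kappa_veg = fraction * kappa_rep
    dirichlet_concentration: float = 500.0
    rarefaction_depths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_DEPTHS)
    )
    depth_multiple: float = 3.0  # depth log-mean = multiple * rarefaction depth
    depth_sigma: float = 0.5
    dynamic_offstage_factor: float = 0.01
    management_effect_sd: float = 0.1
    plot_effect_sd: float = 0.05
    genotype_effect_sd: float = 0.05
    n_compounds: int = 12
    n_linked_taxa: int = 3
    link_beta: float = 5.0
    stage_effect_sd: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plots_per_management is None:
            self.plots_per_management = {
                m: (3 if m in ("CONMIN", "BIODYN") else 1) for m in self.managements
            }
        if not 0.0 <= self.convergence_strength <= 1.0:
            raise ValueError("convergence_strength (kappa) must lie in [0, 1]")
        if self.n_taxa <= 0 or self.n_phyla <= 0 or self.n_replicates <= 0:
            raise ValueError("sizes must be positive")
        if self.stable_core_size > self.n_taxa:
            raise ValueError("stable_core_size cannot exceed n_taxa")
        if not 0.0 < self.core_mean_ra < 1.0:
            raise ValueError("core_mean_ra must lie in (0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.n_linked_taxa > self.n_compounds:
            raise ValueError("n_linked_taxa cannot exceed n_compounds")
        for k in self.kingdoms:
            if k not in self.rarefaction_depths:
                raise ValueError(f"no rarefaction depth for kingdom {k!r}")

    @classmethod
    def demo(cls, seed: int = 0) -> "SimConfig":
        """Reduced design (~240 samples, 200 taxa/kingdom) for demos/docs."""
        return cls(
            n_taxa=200,
            plots_per_management={"NK": 1, "NPK": 1, "CONMIN": 1, "BIODYN": 1},
            genotypes=("B73", "PH207", "DK105"),
            n_replicates=4,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    ``core``: kingdom -> compartment -> planted stable taxon ids (soil
    is stage-stationary and has no planted partition, hence empty).
    ``expected_composition``: kingdom -> DataFrame of the latent
    ``pi`` per (compartment|stage) condition, before management/plot
    effects.  ``links``: kingdom -> list of (taxon, compound, beta).
    """

    core: dict[str, dict[str, set[str]]]
    expected_composition: dict[str, pd.DataFrame]
    links: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "core": {
                k: {c: sorted(s) for c, s in comps.items()}
                for k, comps in self.core.items()
            },
            "links": {
                k: [[t, c, b] for t, c, b in links] for k, links in self.links.items()
            },
            "expected_composition": {
                k: df.to_dict(orient="index")
                for k, df in self.expected_composition.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            core={
                k: {c: set(s) for c, s in comps.items()}
                for k, comps in doc["core"].items()
            },
            expected_composition={
                k: pd.DataFrame.from_dict(d, orient="index")
                for k, d in doc["expected_composition"].items()
            },
            links={
                k: [(t, c, float(b)) for t, c, b in links]
                for k, links in doc["links"].items()
            },
        )


@dataclass
class SyntheticExperiment:
    """Bundle returned by :func:`generate_experiment`."""

    tables: dict[str, CommunityTable]
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    truth: SyntheticTruth


def _build_metadata(config: SimConfig) -> pd.DataFrame:
    rows = []
    for management in config.managements:
        fld = "DEMO" if management in _DEMO_MANAGEMENTS else "DOK"
        for plot_i in range(1, config.plots_per_management[management] + 1):
            plot = f"{management}-{plot_i}"
            for i in range(1, config.n_unplanted_per_plot + 1):
                rows.append(
                    dict(
                        sample_id=f"so.unp.{plot}.{i}",
                        field=fld,
                        management=management,
                        plot=plot,
                        genotype="none",
                        compartment="soil",
                        stage="unplanted",
                    )
                )
            for stage in ("vegetative", "reproductive"):
                st = stage[:3]
                for i in range(1, config.n_soil_per_plot_stage + 1):
                    rows.append(
                        dict(
                            sample_id=f"so.{st}.{plot}.{i}",
                            field=fld,
                            management=management,
                            plot=plot,
                            genotype="none",
                            compartment="soil",
                            stage=stage,
                        )
                    )
                for genotype in config.genotypes:
                    geno = genotype.replace(";", "")
                    for i in range(1, config.n_replicates + 1):
                        for compartment in ("rhizosphere", "root"):
                            rows.append(
                                dict(
                                    sample_id=f"{compartment[:2]}.{st}.{plot}.{geno}.{i}",
                                    field=fld,
                                    management=management,
                                    plot=plot,
                                    genotype=genotype,
                                    compartment=compartment,
                                    stage=stage,
                                )
                            )
    return pd.DataFrame(rows).set_index("sample_id")


def _rescale_phylum(
    weights: np.ndarray, phylum_idx: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Rescale taxa so phylum totals match ``target`` (broadcast within phylum)."""
    out = weights.copy()
    for p in range(target.size):
        members = phylum_idx == p
        current = weights[members].sum()
        if current > 0:
            out[members] *= target[p] / current
    return out / out.sum()


def _kingdom_tables(
    config: SimConfig,
    kingdom: str,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """Counts, taxonomy frame, planted cores and expected compositions."""
    n = config.n_taxa
    prefix = {"bacteria": "B", "fungi": "F", "oomycetes": "O"}.get(kingdom, "X")
    taxa = [f"{prefix}ASV_{i:04d}" for i in range(1, n + 1)]
    phylum_idx = rng.integers(0, config.n_phyla, size=n)
    phyla = [f"{prefix}_Phylum_{j + 1:02d}" for j in range(config.n_phyla)]

    z_global = rng.normal(size=n)
    base = {
        c: np.exp(0.5 * z_global + 1.5 * rng.normal(size=n))
        for c in ("soil", "rhizosphere", "root")
    }

    # planted stable cores: rhizosphere core shares ~60% of the root core
    root_core_idx = rng.choice(n, size=config.stable_core_size, replace=False)
    n_shared = max(1, int(round(0.6 * config.stable_core_size)))
    remaining = np.setdiff1d(np.arange(n), root_core_idx)
    rhizo_core_idx = np.concatenate(
        [
            root_core_idx[:n_shared],
            rng.choice(remaining, size=config.stable_core_size - n_shared, replace=False),
        ]
    )
    cores = {
        "soil": set(),
        "rhizosphere": {taxa[i] for i in rhizo_core_idx},
        "root": {taxa[i] for i in root_core_idx},
    }
    core_idx = {"rhizosphere": rhizo_core_idx, "root": root_core_idx}
    # core members get a mild, stage-independent weight profile so every
    # planted taxon keeps expected prevalence > 0.9 at both stages
    core_profile = {
        c: np.exp(0.3 * rng.normal(size=config.stable_core_size))
        for c in ("rhizosphere", "root")
    }

    # preferred stage of every non-core taxon, per planted compartment
    preferred = {
        c: rng.integers(0, 2, size=n)  # 0 = vegetative, 1 = reproductive
        for c in ("rhizosphere", "root")
    }

    def planted_weights(compartment: str, stage: str) -> np.ndarray:
        w = base[compartment].copy()
        idx = core_idx[compartment]
        is_core = np.zeros(n, dtype=bool)
        is_core[idx] = True
        stage_code = 0 if stage == "vegetative" else 1
        off = (~is_core) & (preferred[compartment] != stage_code)
        w[off] *= config.dynamic_offstage_factor
        # core carries exactly core_mean_ra of the community at this stage
        m = config.core_mean_ra
        s_rest = w[~is_core].sum()
        profile = core_profile[compartment]
        w[idx] = profile / profile.sum() * (m / (1.0 - m)) * s_rest
        return w / w.sum()

    kappa_rep = config.convergence_strength
    kappa = {
        "unplanted": 0.0,
        "vegetative": config.kappa_vegetative_fraction * kappa_rep,
        "reproductive": kappa_rep,
    }

    pi_final = planted_weights("root", "reproductive")
    phylum_final = np.array(
        [pi_final[phylum_idx == p].sum() for p in range(config.n_phyla)]
    )

    conditions: dict[tuple[str, str], np.ndarray] = {}
    for stage in ("unplanted", "vegetative", "reproductive"):
        w = base["soil"] / base["soil"].sum()
        if kappa[stage] > 0:
            phylum_now = np.array(
                [w[phylum_idx == p].sum() for p in range(config.n_phyla)]
            )
            target = (1 - kappa[stage]) * phylum_now + kappa[stage] * phylum_final
            w = _rescale_phylum(w, phylum_idx, target)
        conditions[("soil", stage)] = w
    for compartment in ("rhizosphere", "root"):
        for stage in ("vegetative", "reproductive"):
            w = planted_weights(compartment, stage)
            if compartment == "rhizosphere" and kappa[stage] > 0:
                phylum_now = np.array(
                    [w[phylum_idx == p].sum() for p in range(config.n_phyla)]
                )
                target = (1 - kappa[stage]) * phylum_now + kappa[stage] * phylum_final
                w = _rescale_phylum(w, phylum_idx, target)
            conditions[(compartment, stage)] = w

    # small, stage-constant nuisance effects
    mgmt_effect = {
        m: np.exp(config.management_effect_sd * rng.normal(size=n))
        for m in config.managements
    }
    plot_effect = {
        p: np.exp(config.plot_effect_sd * rng.normal(size=n))
        for p in sorted(meta["plot"].unique())
    }
    geno_effect = {
        g: np.exp(config.genotype_effect_sd * rng.normal(size=n))
        for g in config.genotypes
    }
    geno_effect["none"] = np.ones(n)

    depth0 = config.rarefaction_depths[kingdom] * config.depth_multiple
    alpha0 = config.dirichlet_concentration

    counts = np.empty((len(meta), n), dtype=np.int64)
    for i, (sid, row) in enumerate(meta.iterrows()):
        pi = conditions[(row["compartment"], row["stage"])]
        pi = pi * mgmt_effect[row["management"]] * plot_effect[row["plot"]]
        pi = pi * geno_effect[row["genotype"]]
        pi = pi / pi.sum()
        depth = max(1, int(round(rng.lognormal(np.log(depth0), config.depth_sigma))))
        p = rng.dirichlet(np.maximum(alpha0 * pi, 1e-9))
        counts[i] = rng.multinomial(depth, p)

    count_frame = pd.DataFrame(counts, index=meta.index, columns=taxa)
    tax_frame = pd.DataFrame(
        {
            "kingdom": kingdom,
            "phylum": [phyla[j] for j in phylum_idx],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    expected = pd.DataFrame(
        {f"{c}|{s}": pi for (c, s), pi in conditions.items()}, index=taxa
    ).T
    return count_frame, tax_frame, cores, expected


def generate_experiment(config: SimConfig) -> SyntheticExperiment:
    """Generate per-kingdom count tables, metadata, taxonomy and truth."""
    meta = _build_metadata(config)
    tables: dict[str, CommunityTable] = {}
    tax_frames = []
    core: dict[str, dict[str, set[str]]] = {}
    expected: dict[str, pd.DataFrame] = {}
    for k_i, kingdom in enumerate(config.kingdoms):
        rng = np.random.default_rng([config.seed, k_i])
        count_frame, tax_frame, cores, exp = _kingdom_tables(config, kingdom, meta, rng)
        tables[kingdom] = CommunityTable(count_frame, kingdom=kingdom, level="ASV")
        tax_frames.append(tax_frame)
        core[kingdom] = cores
        expected[kingdom] = exp
    taxonomy = TaxonomyMap(pd.concat(tax_frames))
    truth = SyntheticTruth(core=core, expected_composition=expected)
    return SyntheticExperiment(
        tables=tables,
        metadata=SampleMetadata(meta),
        taxonomy=taxonomy,
        truth=truth,
    )


def generate_metabolites(
    metadata: SampleMetadata,
    table: CommunityTable,
    truth: SyntheticTruth,
    config: SimConfig,
) -> MetaboliteMatrix:
    """Simulate root metabolite intensities linked to planted taxa.

    For every root sample, compound ``j`` has
    ``log intensity = stage_effect_j * 1[reproductive] +
    beta * z(RA of linked taxon) + N(0, noise_sd)``; the exponential
    link keeps intensities strictly positive.  The first
    ``n_linked_taxa`` compounds are each linked to one planted
    stable-core taxon of the table's kingdom; the realized links are
    recorded in ``truth.links``.  The link operates on the taxon's
    standardized RA, so ``link_beta`` is an effect size per RA
    standard deviation.
    """
    if not table.is_relative:
        raise ValueError("generate_metabolites expects a relative table")
    kingdom = table.kingdom
    root_ids = [
        s for s in metadata.select(compartment="root") if s in table.data.index
    ]
    if not root_ids:
        raise ValueError("no root samples available")
    rng = np.random.default_rng([config.seed, 977, list(config.kingdoms).index(kingdom)])
    core = sorted(truth.core[kingdom]["root"])
    core = [t for t in core if t in table.data.columns]
    if len(core) < config.n_linked_taxa:
        raise ValueError("fewer planted core taxa than requested links")
    linked = [str(t) for t in rng.choice(core, size=config.n_linked_taxa, replace=False)]
    compounds = [f"Lipid_{j + 1:02d}" for j in range(config.n_compounds)]
    stage_effects = rng.normal(0.0, config.stage_effect_sd, size=config.n_compounds)
    is_rep = (
        metadata.data.loc[root_ids, "stage"] == "reproductive"
    ).to_numpy(dtype=float)

    values = np.empty((len(root_ids), config.n_compounds))
    for j, compound in enumerate(compounds):
        eta = stage_effects[j] * is_rep
        if j < len(linked):
            ra = table.data.loc[root_ids, linked[j]].to_numpy(dtype=float)
            sd = ra.std()
            z = (ra - ra.mean()) / sd if sd > 0 else np.zeros_like(ra)
            eta = eta + config.link_beta * z
        if config.noise_sd > 0:
            eta = eta + rng.normal(0.0, config.noise_sd, size=len(root_ids))
        values[:, j] = np.exp(eta)
    truth.links[kingdom] = [
        (linked[j], compounds[j], config.link_beta) for j in range(len(linked))
    ]
    return MetaboliteMatrix(
        pd.DataFrame(values, index=root_ids, columns=compounds), state="raw"
    )
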