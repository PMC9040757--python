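"""Stable/dynamic partition of the root-associated microbiota.

A taxon is *stable* in a compartment when it is widespread -- detected
(nonzero) in more than a threshold fraction (default 80%) of that
compartment's samples -- at **both** the vegetative and reproductive
growth stages.  Everything else observed in the compartment is
*dynamic*.  The partition is summarized by the aggregated relative
abundance (aRA, percent) of each side and by the stable-to-dynamic
ratio aRA_stable / aRA_dynamic; e.g. a stable aRA of 39.35% gives a
dynamic aRA of 60.65% and a ratio of 0.65.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_data import CommunityTable, SampleMetadata


@dataclass
class StabilityPartition:
    """Stable/dynamic taxon sets for one compartment and kingdom."""

    compartment: str
    kingdom: str
    threshold: float
    stable: set[str]
    dynamic: set[str]
    stable_ara: dict[str, float]  # stage -> aRA percent of the stable set
    ratio: dict[str, float]  # stage -> stable-to-dynamic ratio

    def to_json(self, path: str | Path) -> None:
        doc = {
            "compartment": self.compartment,
            "kingdom": self.kingdom,
            "threshold": self.threshold,
            "stable": sorted(self.stable),
            "dynamic": sorted(self.dynamic),
            "stable_ara_percent": self.stable_ara,
            "stable_to_dynamic_ratio": self.ratio,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def prevalence(table: CommunityTable, sample_set: Sequence[str]) -> pd.Series:
    """Per-taxon fraction of the given samples with nonzero abundance."""
    ids = list(sample_set)
    if not ids:
        raise ValueError("empty sample set")
    sub = table.subset_samples(ids)
    return (sub.data > 0).mean(axis=0)


def stable_taxa(
    table: CommunityTable,
    metadata: SampleMetadata,
    compartment: str,
    threshold: float = 0.8,
    strict: bool = True,
) -> set[str]:
    """Taxa widespread at both planted growth stages in a compartment.

    Prevalence must exceed ``threshold`` ("more than 80% of samples",
    hence strictly greater by default) among the compartment's
    vegetative samples AND among its reproductive samples.  Prevalence
    is pooled across managements and genotypes.
    """
    per_stage = {}
    for stage in ("vegetative", "reproductive"):
        ids = metadata.select(compartment=compartment, stage=stage)
        ids = [s for s in ids if s in table.data.index]
        if not ids:
            raise ValueError(
                f"no {stage} samples for compartment {compartment!r} in the table"
            )
        per_stage[stage] = prevalence(table, ids)
    veg, rep = per_stage["vegetative"], per_stage["reproductive"]
    if strict:
        mask = (veg > threshold) & (rep > threshold)
    else:
        mask = (veg >= threshold) & (rep >= threshold)
    return set(veg.index[mask])


def aggregated_ra(
    table: CommunityTable, taxon_set: Iterable[str], sample_set: Sequence[str]
) -> float:
    """Aggregated relative abundance of a taxon set, in percent.

    Per sample, the set's proportions are summed; the per-sample sums
    are then averaged over the sample set and expressed as a percent.
    """
    if not table.is_relative:
        raise ValueError("aggregated_ra requires a relative table")
    ids = list(sample_set)
    if not ids:
        raise ValueError("empty sample set")
    taxa = [t for t in taxon_set if t in table.data.columns]
    sub = table.subset_samples(ids)
    if not taxa:
        return 0.0
    return float(sub.data[taxa].sum(axis=1).mean() * 100.0)


def stable_dynamic_ratio(stable_ara: float) -> float:
    """Stable-to-dynamic ratio from the stable aRA (percent).

    ratio = stable_aRA / (100 - stable_aRA); e.g. 39.35 -> 0.65 and
    80.49 -> 4.13 (2 d.p.).  Undefined at 0 or 100.
    """
    if not 0.0 < stable_ara < 100.0:
        raise ValueError(
            f"stable aRA must be strictly between 0 and 100, got {stable_ara}"
        )
    return stable_ara / (100.0 - stable_ara)


def compartment_overlap(sets: Mapping[str, set[str]]) -> dict[frozenset, int]:
    """Counts for every region of the Venn (inclusion-exclusion) partition.

    Keys are frozensets of set names; the value for key {A, B} is the
    number of elements in exactly A and B and no other set.  Regions
    with zero members are included.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two named sets")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def stability_partition(
    rel_table: CommunityTable,
    metadata: SampleMetadata,
    compartment: str,
    detection_table: CommunityTable | None = None,
    threshold: float = 0.8,
    strict: bool = True,
) -> StabilityPartition:
    """Full stable/dynamic partition of a compartment's community.

    ``rel_table`` supplies relative abundances for the aRA; detection
    (presence) is evaluated on ``detection_table`` (typically the
    rarefied counts) or on ``rel_table`` itself when omitted.  The
    dynamic set is every other taxon observed (nonzero anywhere) in the
    compartment's planted samples.
    """
    det = detection_table if detection_table is not None else rel_table
    stable = stable_taxa(det, metadata, compartment, threshold=threshold, strict=strict)
    planted = [
        s
        for s in metadata.select(
            compartment=compartment, stage=("vegetative", "reproductive")
        )
        if s in det.data.index
    ]
    observed = set(det.data.columns[(det.subset_samples(planted).data > 0).any(axis=0)])
    stable &= observed
    dynamic = observed - stable
    stable_ara: dict[str, float] = {}
    ratios: dict[str, float] = {}
    for stage in ("vegetative", "reproductive"):
        ids = [
            s
            for s in metadata.select(compartment=compartment, stage=stage)
            if s in rel_table.data.index
        ]
        ara = aggregated_ra(rel_table, stable, ids)
        stable_ara[stage] = ara
        ratios[stage] = (
            stable_dynamic_ratio(ara) if 0.0 < ara < 100.0 else float("nan")
        )
    return StabilityPartition(
        compartment=compartment,
        kingdom=rel_table.kingdom,
        threshold=threshold,
        stable=stable,
        dynamic=dynamic,
        stable_ara=stable_ara,
        ratio=ratios,
    )


def partition_table(
    partition: StabilityPartition,
    det_table: CommunityTable,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Tidy per-taxon table: stage prevalences and the stable flag."""
    rows = []
    stage_ids = {
        stage: [
            s
            for s in metadata.select(compartment=partition.compartment, stage=stage)
            if s in det_table.data.index
        ]
        for stage in ("vegetative", "reproductive")
    }
    prev = {
        stage: prevalence(det_table, ids) for stage, ids in stage_ids.items() if ids
    }
    for taxon in sorted(partition.stable | partition.dynamic):
        rows.append(
            {
                "taxon": taxon,
                "compartment": partition.compartment,
                "prevalence_vegetative": float(prev["vegetative"].get(taxon, 0.0)),
                "prevalence_reproductive": float(prev["reproductive"].get(taxon, 0.0)),
                "stable": taxon in partition.stable,
            }
        )
    return pd.DataFrame(rows)
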