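"""Data model and I/O for amplicon community profiling.

The package's substrate is the sample x taxon count table produced by
marker-gene surveys (16S for bacteria, ITS for fungi and oomycetes),
together with per-sample experimental metadata, a taxonomy map, and
optionally the representative sequences of the amplicon sequence
variants (ASVs).  Everything downstream -- rarefaction, diversity,
the stable/dynamic partition, convergence, covariation -- consumes the
types defined here.

Tables are stored samples-in-rows internally; the common taxa-in-rows
text dialect (QIIME-style, with a leading ``#OTU ID`` header) is
accepted on read and available on write.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

KINGDOMS = ("bacteria", "fungi", "oomycetes")
LEVELS = ("ASV", "OTU", "phylum", "custom")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

FIELDS = ("DEMO", "DOK")
MANAGEMENTS = ("NK", "NPK", "CONMIN", "BIODYN")
GENOTYPES = ("B73", "PH207", "DK105", "F2", "pht1;6", "none")
COMPARTMENTS = ("soil", "rhizosphere", "root")
STAGES = ("unplanted", "vegetative", "reproductive")

#: Sentinel bucket for taxa without an assignment at the requested rank.
UNASSIGNED = "unassigned"
#: Bucket name used when grouping rare phyla.
OTHERS = "Others"

_METADATA_COLUMNS = ("field", "management", "plot", "genotype", "compartment", "stage")


class CommunityTableError(ValueError):
    """Raised when a table violates the community-table contract."""


@dataclass
class CommunityTable:
    """Sample x taxon abundance matrix for one microbial kingdom.

    Parameters
    ----------
    data:
        DataFrame with samples as the index and taxa as columns.
        Counts (integers) unless ``is_relative``.
    kingdom:
        One of ``bacteria``, ``fungi``, ``oomycetes``.
    level:
        Taxonomic unit of the columns: ``ASV``, ``OTU``, ``phylum`` or
        ``custom``.
    is_relative:
        True when rows are proportions summing to one.
    """

    data: pd.DataFrame
    kingdom: str
    level: str = "ASV"
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise CommunityTableError(
                f"unknown kingdom {self.kingdom!r}; expected one of {KINGDOMS}"
            )
        if self.level not in LEVELS:
            raise CommunityTableError(
                f"unknown level {self.level!r}; expected one of {LEVELS}"
            )
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise CommunityTableError(f"duplicate sample identifier {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise CommunityTableError(f"duplicate taxon identifier {dup!r}")
        values = df.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            i, j = np.unravel_index(np.argmin(values), values.shape)
            raise CommunityTableError(
                f"negative value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                s = df.index[np.argmax(bad)]
                raise CommunityTableError(
                    f"relative table row {s!r} sums to {sums[np.argmax(bad)]:.12g}, not 1"
                )
        else:
            if values.size and not np.allclose(values, np.round(values)):
                frac = np.abs(values - np.round(values))
                i, j = np.unravel_index(np.argmax(frac), frac.shape)
                raise CommunityTableError(
                    f"non-integer count at sample {df.index[i]!r}, "
                    f"taxon {df.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        """Restrict to the given samples (order preserved as given)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise CommunityTableError(f"samples not in table: {missing[:5]}")
        return CommunityTable(
            self.data.loc[list(sample_ids)].copy(),
            kingdom=self.kingdom,
            level=self.level,
            is_relative=self.is_relative,
        )


@dataclass
class SampleMetadata:
    """Per-sample experimental factors.

    Rows are indexed by sample id; columns are the design factors
    ``field``, ``management``, ``plot``, ``genotype``, ``compartment``
    and ``stage``.  Unplanted soil carries genotype ``none``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        for col, allowed in (
            ("field", FIELDS),
            ("management", MANAGEMENTS),
            ("genotype", GENOTYPES),
            ("compartment", COMPARTMENTS),
            ("stage", STAGES),
        ):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise ValueError(f"metadata column {col!r} has unknown levels {sorted(bad)}")
        unplanted = (df["compartment"] == "soil") & (df["stage"] == "unplanted")
        if (df.loc[unplanted, "genotype"] != "none").any():
            bad_id = df.index[unplanted & (df["genotype"] != "none")][0]
            raise ValueError(
                f"unplanted soil sample {bad_id!r} must have genotype 'none'"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate_against(self, table: CommunityTable) -> None:
        """Every sample in the table must have exactly one metadata row."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    def select(self, **criteria: str | Sequence[str]) -> list[str]:
        """Sample ids matching all factor=value (or factor=values) criteria."""
        mask = pd.Series(True, index=self.data.index)
        for col, value in criteria.items():
            if col not in self.data.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            if isinstance(value, str):
                mask &= self.data[col] == value
            else:
                mask &= self.data[col].isin(list(value))
        return list(self.data.index[mask])


@dataclass
class TaxonomyMap:
    """Taxon id -> taxonomic ranks, plus optional ASV -> OTU membership."""

    data: pd.DataFrame
    asv_to_otu: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for rank in RANKS:
            if rank not in self.data.columns:
                self.data[rank] = np.nan
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id in taxonomy: {dup!r}")

    def rank_label(self, taxon_id: str, rank: str) -> str:
        """Label at ``rank`` or the ``unassigned`` sentinel."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if taxon_id not in self.data.index:
            return UNASSIGNED
        label = self.data.at[taxon_id, rank]
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            return UNASSIGNED
        return str(label)


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by record id, with optional abundances."""

    records: "OrderedDict[str, str]"
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("sequence set is empty")
        alphabet = set("ACGTN")
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            extra = set(seq.upper()) - alphabet
            if extra:
                raise ValueError(f"record {rid!r} has invalid characters {sorted(extra)}")

    def abundance(self, rid: str) -> float:
        return self.abundances.get(rid, 1.0)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path,
    orientation: str = "taxa-in-rows",
    kingdom: str = "bacteria",
    level: str = "ASV",
) -> CommunityTable:
    """Read a tab-separated count table.

    ``orientation`` declares the file layout; the returned table is
    always samples-in-rows.  A leading ``#`` on the header id column
    (QIIME's ``#OTU ID``) is accepted.
    """
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if orientation == "taxa-in-rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    df = df.apply(pd.to_numeric)
    return CommunityTable(df, kingdom=kingdom, level=level, is_relative=False)


def write_table(
    table: CommunityTable, path: str | Path, orientation: str = "taxa-in-rows"
) -> None:
    """Write a table as tab-separated text (proportions with 6 decimals)."""
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = table.data
    if not table.is_relative:
        df = df.round().astype(np.int64)
    if orientation == "taxa-in-rows":
        df = df.T.rename_axis(index="#OTU ID")
    else:
        df = df.rename_axis(index="#SampleID")
    fmt = "%.6f" if table.is_relative else None
    df.to_csv(path, sep="\t", float_format=fmt)


def read_biom_json(path: str | Path, kingdom: str = "bacteria", level: str = "ASV") -> CommunityTable:
    """Read a BIOM 1.0 JSON table (sparse or dense) into a CommunityTable."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    matrix = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        matrix[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            matrix[int(i), int(j)] = v
    df = pd.DataFrame(matrix.T, index=samples, columns=taxa)
    return CommunityTable(df, kingdom=kingdom, level=level, is_relative=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read tab-separated metadata; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a taxonomy table.

    Two dialects are accepted: one column per rank, or a single
    ``Taxonomy`` column with semicolon-joined ranks ordered
    kingdom;phylum;class;order;family;genus.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    lower = {c.lower(): c for c in df.columns}
    if "taxonomy" in lower and not any(r in lower for r in RANKS):
        parts = df[lower["taxonomy"]].fillna("").str.split(";", expand=True)
        parts = parts.reindex(columns=range(len(RANKS)))
        parts.columns = list(RANKS)
        for rank in RANKS:
            parts[rank] = parts[rank].map(
                lambda v: v.strip() if isinstance(v, str) else np.nan
            ).replace("", np.nan)
        df = parts
    else:
        df = df.rename(columns={v: k for k, v in lower.items()})
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    df = taxonomy.data.reindex(columns=list(RANKS))
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA records; ``;size=N`` suffixes are parsed as abundances."""
    records: "OrderedDict[str, str]" = OrderedDict()
    abundances: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if ";size=" in rid:
            rid, size = rid.split(";size=", 1)
            abundances[rid] = float(size.rstrip(";"))
        if rid in records:
            raise ValueError(f"duplicate record id {rid!r}")
        records[rid] = str(rec.seq).upper()
    return SequenceSet(records, abundances)


# ---------------------------------------------------------------------------
# Core transformations
# ---------------------------------------------------------------------------


@dataclass
class RarefactionResult:
    """Rarefied table plus the ids of samples below the requested depth."""

    table: CommunityTable
    dropped: list[str]


def rarefy(table: CommunityTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample's counts to ``depth`` reads without replacement.

    Each retained row is a multivariate-hypergeometric draw from that
    sample's count multiset, so retained row sums equal ``depth``
    exactly.  Samples whose total is below ``depth`` are dropped and
    reported.  Deterministic given ``seed``.
    """
    if table.is_relative:
        raise CommunityTableError("rarefy requires a count table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    kept_rows = []
    kept_ids = []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        kept_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    out = pd.DataFrame(
        np.asarray(kept_rows, dtype=np.int64).reshape(len(kept_ids), len(table.taxon_ids)),
        index=kept_ids,
        columns=table.taxon_ids,
    )
    rarefied = CommunityTable(out, kingdom=table.kingdom, level=table.level)
    return RarefactionResult(rarefied, dropped)


def to_relative(table: CommunityTable) -> CommunityTable:
    """Row-normalize to proportions (relative abundances)."""
    values = table.values()
    sums = values.sum(axis=1)
    if (sums == 0).any():
        sid = table.data.index[int(np.argmax(sums == 0))]
        raise CommunityTableError(f"sample {sid!r} has zero total count")
    rel = values / sums[:, None]
    df = pd.DataFrame(rel, index=table.data.index, columns=table.data.columns)
    return CommunityTable(df, kingdom=table.kingdom, level=table.level, is_relative=True)


def aggregate_taxa(
    table: CommunityTable, taxonomy: TaxonomyMap, rank: str
) -> CommunityTable:
    """Sum columns within each label at ``rank``; row sums are preserved.

    Taxa that do not resolve at the rank fall into the ``unassigned``
    bucket, which is kept separate from any rare-taxon grouping.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [taxonomy.rank_label(t, rank) for t in table.taxon_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    # keep the unassigned bucket last for readability
    cols = [c for c in grouped.columns if c != UNASSIGNED]
    if UNASSIGNED in grouped.columns:
        cols.append(UNASSIGNED)
    grouped = grouped[cols]
    level = "phylum" if rank == "phylum" else "custom"
    return CommunityTable(
        grouped, kingdom=table.kingdom, level=level, is_relative=table.is_relative
    )


def group_rare_taxa(table: CommunityTable, threshold: float = 0.001) -> CommunityTable:
    """Merge phyla with mean relative abundance below ``threshold`` into ``Others``."""
    if not table.is_relative:
        raise CommunityTableError("group_rare_taxa requires a relative table")
    if table.level != "phylum":
        raise CommunityTableError("group_rare_taxa operates on phylum-level tables")
    means = table.data.mean(axis=0)
    rare = means.index[means < threshold]
    if len(rare) == 0:
        return table
    kept = table.data.drop(columns=rare)
    kept[OTHERS] = table.data[rare].sum(axis=1)
    return CommunityTable(
        kept, kingdom=table.kingdom, level=table.level, is_relative=True
    )


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Global-alignment identity: matches / alignment columns."""
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    c = aln.counts()
    return c.identities / (c.gaps + c.identities + c.mismatches)


def cluster_otus(
    seqs: SequenceSet,
    identity_threshold: float = 0.97,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> dict[str, str]:
    """Greedy centroid clustering of ASV sequences into OTUs.

    Sequences are processed in decreasing abundance (ties broken by
    lexicographic id).  Each sequence joins the first existing centroid
    whose global pairwise identity is at or above the threshold, else
    founds a new OTU.  Deterministic and independent of input order.
    """
    aligner = _make_aligner(match, mismatch, gap)
    order = sorted(seqs.records, key=lambda rid: (-seqs.abundance(rid), rid))
    centroids: list[tuple[str, str]] = []  # (otu_id, sequence)
    mapping: dict[str, str] = {}
    for rid in order:
        seq = seqs.records[rid]
        assigned = None
        for otu_id, centroid_seq in centroids:
            if identity_threshold <= 0:
                assigned = otu_id
                break
            aln = aligner.align(centroid_seq, seq)[0]
            c = aln.counts()
            if c.identities / (c.gaps + c.identities + c.mismatches) >= identity_threshold:
                assigned = otu_id
                break
        if assigned is None:
            assigned = f"OTU_{len(centroids) + 1:04d}"
            centroids.append((assigned, seq))
        mapping[rid] = assigned
    return mapping
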