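"""Taxa-metabolite covariation analysis.

The procedure links root-associated taxa to root metabolite (lipid)
profiles in three steps: (1) metabolite intensities are log10
transformed and range-normalized per compound; (2) taxa are ranked by
random-forest predictive importance -- for each compound a forest
regresses the compound on all taxon relative abundances and the
importance of a taxon is its permutation increase in out-of-bag MSE;
the taxon's score is the maximum across compounds and the top K (25)
are kept; (3) every (selected taxon, compound) pair is tested by
Spearman correlation and pairs with |rho| > 0.5 and raw p < 0.05
become network edges.  Nodes carry the ratio of mean vegetative to
mean reproductive abundance/intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .core_data import CommunityTable, SampleMetadata

_STATES = ("raw", "log", "log-range")


@dataclass
class MetaboliteMatrix:
    """Samples x compounds intensity matrix with a transform-state flag."""

    data: pd.DataFrame
    state: str = "raw"
    constant_compounds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {_STATES}")
        values = self.data.to_numpy(dtype=float)
        if self.state == "raw" and values.size and values.min() < 0:
            i, j = np.unravel_index(np.argmin(values), values.shape)
            raise ValueError(
                f"negative intensity at sample {self.data.index[i]!r}, "
                f"compound {self.data.columns[j]!r}"
            )
        if self.state == "log-range" and values.size:
            if values.min() < -1e-9 or values.max() > 1 + 1e-9:
                raise ValueError("log-range values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path, state: str = "raw") -> "MetaboliteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, state=state)


def preprocess_metabolites(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Log10-transform then range-normalize each compound to [0, 1].

    Zeros are offset by half the compound's smallest positive value
    before the log; compounds that are constant (including all-zero)
    map to 0 and are flagged in ``constant_compounds``.  Idempotent by
    state flag: transformed input is rejected.
    """
    if m.state != "raw":
        raise ValueError(f"expected raw intensities, got state {m.state!r}")
    out = pd.DataFrame(index=m.data.index, columns=m.data.columns, dtype=float)
    constant: list[str] = []
    for compound in m.data.columns:
        x = m.data[compound].to_numpy(dtype=float)
        pos = x[x > 0]
        if pos.size == 0:
            out[compound] = 0.0
            constant.append(compound)
            continue
        eps = pos.min() / 2.0
        logged = np.log10(np.where(x > 0, x, eps))
        lo, hi = logged.min(), logged.max()
        if hi - lo <= 0:
            out[compound] = 0.0
            constant.append(compound)
        else:
            out[compound] = (logged - lo) / (hi - lo)
    return MetaboliteMatrix(out, state="log-range", constant_compounds=constant)


# ---------------------------------------------------------------------------
# Random-forest importance ranking
# ---------------------------------------------------------------------------


def _oob_indices(tree, n_samples: int) -> np.ndarray:
    # mirrors the forest's bootstrap draw: n_samples draws with replacement
    # seeded by the tree's random_state
    rs = np.random.RandomState(tree.random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.where(mask)[0]


def oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Per-feature permutation increase in out-of-bag MSE.

    For every tree, the OOB samples are predicted once with the true
    features and once per feature with that feature's OOB column
    permuted; the importance of a feature is the mean (over trees) of
    the MSE increase.  This is the classic regression-forest
    importance ("%IncMSE" in unscaled form).
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    increases = np.zeros(p)
    n_used = 0
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for tree in forest.estimators_:
        oob = _oob_indices(tree, n)
        if oob.size < 2:
            continue
        x_oob = X32[oob]
        y_oob = y[oob]
        base = tree.tree_.predict(x_oob).ravel()
        base_mse = float(np.mean((y_oob - base) ** 2))
        # one stacked predict per tree: p permuted copies of the OOB block
        stacked = np.repeat(x_oob[None, :, :], p, axis=0)
        for f in range(p):
            stacked[f, :, f] = x_oob[rng.permutation(oob.size), f]
        preds = tree.tree_.predict(
            np.ascontiguousarray(stacked.reshape(p * oob.size, p))
        ).ravel().reshape(p, oob.size)
        mses = np.mean((y_oob[None, :] - preds) ** 2, axis=1)
        increases += mses - base_mse
        n_used += 1
    if n_used == 0:
        raise ValueError("no tree had enough out-of-bag samples")
    return increases / n_used


@dataclass
class TaxonRanking:
    """Taxa ranked by random-forest importance across compounds."""

    scores: pd.Series  # top-K taxa, descending importance score
    per_compound: pd.DataFrame  # taxa x compounds importance matrix
    combine: str


def rank_predictive_taxa(
    table: CommunityTable,
    m: MetaboliteMatrix,
    k: int = 25,
    n_trees: int = 500,
    seed: int = 0,
    prevalence_min: float = 0.1,
    combine: str = "max",
) -> TaxonRanking:
    """Rank taxa by their random-forest predictive importance for compounds.

    One regression forest per compound (compound ~ all taxon RAs);
    per-taxon importance is the permutation increase in out-of-bag MSE;
    the taxon score combines importances across compounds (``max`` by
    default, ``mean`` as an option) and the top ``k`` taxa are
    returned.  Taxa with prevalence below ``prevalence_min`` among the
    shared samples are excluded before fitting.
    """
    if combine not in ("max", "mean"):
        raise ValueError(f"combine must be 'max' or 'mean', got {combine!r}")
    shared = [s for s in table.sample_ids if s in m.data.index]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared samples, got {len(shared)}")
    sub = table.subset_samples(shared).data
    prev = (sub > 0).mean(axis=0)
    taxa = list(prev.index[prev >= prevalence_min])
    if not taxa:
        raise ValueError("no taxa pass the prevalence filter")
    if len(taxa) < k:
        warnings.warn(
            f"only {len(taxa)} taxa after prevalence filtering (< K={k}); "
            "returning all of them"
        )
    X = sub[taxa].to_numpy(dtype=float)
    imp = pd.DataFrame(index=taxa, columns=m.compound_ids, dtype=float)
    rng = np.random.default_rng(seed)
    for compound in m.compound_ids:
        y = m.data.loc[shared, compound].to_numpy(dtype=float)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=fit_seed, n_jobs=1
        )
        forest.fit(X, y)
        imp[compound] = oob_permutation_importance(forest, X, y, seed=fit_seed)
    scores = imp.max(axis=1) if combine == "max" else imp.mean(axis=1)
    scores = scores.sort_values(ascending=False, kind="stable")
    top = scores.iloc[: min(k, len(scores))]
    return TaxonRanking(scores=top, per_compound=imp, combine=combine)


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------


@dataclass
class CovariationNetwork:
    """Bipartite taxon-compound graph with Spearman-correlation edges."""

    edges: pd.DataFrame  # columns: taxon, compound, rho, p
    taxa: list[str]
    compounds: list[str]
    node_ratios: pd.Series | None = None  # vegetative/reproductive ratio
    r_min: float = 0.5
    alpha: float = 0.05
    k: int = 25

    def write_tables(self, node_path: str | Path, edge_path: str | Path) -> None:
        nodes = pd.DataFrame(
            {
                "node": self.taxa + self.compounds,
                "type": ["taxon"] * len(self.taxa) + ["compound"] * len(self.compounds),
            }
        ).set_index("node")
        if self.node_ratios is not None:
            nodes["stage_ratio"] = self.node_ratios.reindex(nodes.index)
        nodes.to_csv(node_path, sep="\t", float_format="%.6g")
        self.edges.to_csv(edge_path, sep="\t", index=False, float_format="%.6g")

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for t in self.taxa:
            g.add_node(t, kind="taxon")
        for c in self.compounds:
            g.add_node(c, kind="compound")
        if self.node_ratios is not None:
            for node, ratio in self.node_ratios.items():
                if node in g and np.isfinite(ratio):
                    g.nodes[node]["stage_ratio"] = float(ratio)
        for row in self.edges.itertuples():
            g.add_edge(row.taxon, row.compound, rho=float(row.rho), p=float(row.p))
        nx.write_graphml(g, str(path))


def correlation_network(
    table: CommunityTable,
    m: MetaboliteMatrix,
    taxa: Sequence[str],
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> CovariationNetwork:
    """Spearman taxon-compound network.

    Every (selected taxon, compound) pair is tested with a two-sided
    Spearman correlation over the shared samples; edges require
    |rho| > ``r_min`` AND p < ``alpha`` (raw p, unadjusted).  Pairs
    with a constant member are skipped with a warning.
    """
    shared = [s for s in table.sample_ids if s in m.data.index]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    sub = table.subset_samples(shared).data
    missing = [t for t in taxa if t not in sub.columns]
    if missing:
        raise KeyError(f"taxa not in table: {missing[:5]}")
    rows = []
    for taxon in taxa:
        x = sub[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"taxon {taxon!r} is constant; skipped")
            continue
        for compound in m.compound_ids:
            y = m.data.loc[shared, compound].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            rho, p = stats.spearmanr(x, y)
            if abs(rho) > r_min and p < alpha:
                rows.append(
                    {"taxon": taxon, "compound": compound, "rho": float(rho), "p": float(p)}
                )
    constant_compounds = [
        c for c in m.compound_ids if np.ptp(m.data.loc[shared, c].to_numpy(float)) == 0
    ]
    if constant_compounds:
        warnings.warn(
            f"constant compounds skipped: {constant_compounds[:5]}"
        )
    edges = pd.DataFrame(rows, columns=["taxon", "compound", "rho", "p"])
    return CovariationNetwork(
        edges=edges,
        taxa=list(taxa),
        compounds=list(m.compound_ids),
        r_min=r_min,
        alpha=alpha,
    )


def stage_ra_ratio(
    values: pd.DataFrame,
    metadata: SampleMetadata,
    node_ids: Sequence[str],
    compartment: str = "root",
) -> pd.Series:
    """Vegetative/reproductive mean-abundance ratio per node.

    ``values`` is any samples x features frame (taxon RAs or compound
    intensities).  The ratio is the mean over the compartment's
    vegetative samples divided by the mean over its reproductive
    samples; 0/0 yields NaN (undefined, excluded from display).
    """
    means = {}
    for stage in ("vegetative", "reproductive"):
        ids = [
            s
            for s in metadata.select(compartment=compartment, stage=stage)
            if s in values.index
        ]
        if not ids:
            raise ValueError(f"no {stage} samples in compartment {compartment!r}")
        means[stage] = values.loc[ids].mean(axis=0)
    out = {}
    for node in node_ids:
        if node not in values.columns:
            raise KeyError(f"node {node!r} not in the value table")
        v, r = float(means["vegetative"][node]), float(means["reproductive"][node])
        if v == 0.0 and r == 0.0:
            out[node] = float("nan")
        elif r == 0.0:
            out[node] = float("inf")
        else:
            out[node] = v / r
    return pd.Series(out, name="stage_ratio")
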