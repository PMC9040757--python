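"""Alpha/beta diversity and permutation statistics.

Implements the diversity machinery used throughout the analysis:
Shannon entropy averaged over repeated rarefactions, Bray-Curtis
dissimilarity, principal-coordinate analysis (PCoA), a sequential
(Type-I) PERMANOVA with free permutations, constrained PCoA
(distance-based redundancy analysis), and pairwise Wilcoxon rank-sum
tests with Benjamini-Hochberg correction plus a compact-letter display.

All permutation tests use the add-one correction
``p = (1 + #{permuted >= observed}) / (1 + n_perm)`` and are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import CommunityTable, SampleMetadata, rarefy


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarity matrix with a metric label."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)], metric=self.metric
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path, metric: str = "braycurtis") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric=metric)


@dataclass
class OrdinationResult:
    """PCoA / constrained-PCoA output."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # for retained axes
    constrained_proportion: float | None = None
    p_value: float | None = None


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition: one row per term plus residual/total."""

    table: pd.DataFrame  # index: term names + "Residual" + "Total"
    n_permutations: int

    def r_squared(self, term: str) -> float:
        return float(self.table.at[term, "R2"])

    def p_value(self, term: str) -> float:
        return float(self.table.at[term, "p"])


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(counts: np.ndarray | Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i over nonzero proportions.

    Natural log by default; pass ``base`` to change the unit.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("shannon expects a 1-D vector")
    if (x < 0).any():
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def rarefied_shannon(
    table: CommunityTable,
    depth: int,
    n_rarefactions: int = 999,
    seed: int = 0,
    base: float | None = None,
) -> tuple[pd.Series, list[str]]:
    """Per-sample Shannon index averaged over repeated rarefactions.

    Returns the per-sample mean over ``n_rarefactions`` independent
    rarefaction draws, plus the ids of samples below ``depth`` (dropped).
    A sample whose total equals ``depth`` has no sampling variability,
    so its value equals the Shannon index of the raw row.
    """
    if table.is_relative:
        raise ValueError("rarefied_shannon requires a count table")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if n_rarefactions < 1:
        raise ValueError("n_rarefactions must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    values: dict[str, float] = {}
    dropped: list[str] = []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        if totals[i] == depth:
            values[sid] = shannon(counts[i], base=base)
            continue
        acc = 0.0
        for _ in range(n_rarefactions):
            acc += shannon(rng.multivariate_hypergeometric(counts[i], depth), base=base)
        values[sid] = acc / n_rarefactions
    return pd.Series(values, name="shannon"), dropped


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y).

    Rows must be comparable: either equal-sum counts (e.g. rarefied)
    or relative abundances.
    """
    x = table.values()
    sums = x.sum(axis=1)
    if (sums == 0).sum() >= 1:
        zero = [table.sample_ids[i] for i in np.where(sums == 0)[0]]
        raise ValueError(f"all-zero samples have undefined dissimilarity: {zero[:5]}")
    if not table.is_relative and np.ptp(sums) > 1e-9:
        raise ValueError(
            "count rows have unequal totals; rarefy or normalize before Bray-Curtis"
        )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        tot = (x[i] + x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff / tot
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d, metric="braycurtis")


def euclidean_distance(
    values: pd.DataFrame, metric_label: str = "euclidean"
) -> DistanceMatrix:
    """Euclidean distance matrix of a samples x features frame."""
    x = values.to_numpy(dtype=float)
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    d = (d + d.T) / 2
    return DistanceMatrix(list(values.index.astype(str)), d, metric=metric_label)


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -1/2 J D^2 J with J = I - 11'/n."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical metric scaling (principal-coordinate analysis).

    Eigendecomposition of the Gower-centered matrix; axes with positive
    eigenvalues are retained up to ``n_axes``.  Proportion explained is
    relative to the sum of positive eigenvalues only (negative
    eigenvalues are reported but excluded from the denominator).  Axis
    sign is fixed so the largest-magnitude loading on each axis is
    positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    g = _gower_center(dm.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if eigvals.size else 0.0)
    positive = eigvals > tol
    n_keep = min(n_axes, int(positive.sum()))
    pos_sum = eigvals[positive].sum()
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    for k in range(n_keep):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    prop = eigvals[:n_keep] / pos_sum if pos_sum > 0 else np.zeros(n_keep)
    frame = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PCo{k + 1}" for k in range(n_keep)],
    )
    return OrdinationResult(frame, eigenvalues=eigvals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _design_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Full dummy coding for a factor or a ':'-crossed interaction."""
    factors = term.split(":")
    combined = meta[factors[0]].astype(str)
    for f in factors[1:]:
        combined = combined + "\x1f" + meta[f].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of x (rank-safe)."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) permutational multivariate ANOVA.

    Partitions the total sum of squared dissimilarities
    ``SS_total = sum_{i<j} d_ij^2 / n`` among the terms in the given
    order, each term's SS being the increment in explained SS after the
    preceding terms.  Pseudo-F uses the full-model residual.  P-values
    come from free permutation of sample labels with the add-one
    correction.  Interaction terms are written ``A:B``.
    """
    ids = dm.sample_ids
    meta = metadata.data.loc[ids]
    n = len(ids)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for term in terms:
        for f in term.split(":"):
            if f not in meta.columns:
                raise KeyError(f"unknown metadata column {f!r}")
        if meta[term.split(":")[0]].nunique() < 2 and ":" not in term:
            raise ValueError(f"term {term!r} has a single level")

    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))

    # sequential hat matrices: H_0 = intercept, H_t adds term t's dummies
    ones = np.ones((n, 1))
    design = ones
    hats = [_hat(design)]
    dfs: list[int] = []
    for term in terms:
        x = _design_matrix(meta, term)
        new_design = np.hstack([design, x])
        h = _hat(new_design)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
        design = new_design
    h_full = hats[-1]
    term_hats = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_hat = np.eye(n) - h_full
    df_res = n - int(round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    ss_terms = np.array([float(np.sum(h * g)) for h in term_hats])
    ss_res = float(np.sum(resid_hat * g))
    f_obs = (ss_terms / np.maximum(dfs, 1)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    chunk = max(1, int(2e7 // (n * n)))  # bound permuted-matrix memory
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        gp = g[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
        ss_res_p = np.einsum("ij,pij->p", resid_hat, gp)
        for k, h in enumerate(term_hats):
            ss_k = np.einsum("ij,pij->p", h, gp)
            f_p = (ss_k / max(dfs[k], 1)) / (ss_res_p / df_res)
            # relative tolerance so exact ties (e.g. the mirror relabeling)
            # survive floating-point jitter in the permuted path
            exceed[k] += np.sum(f_p >= f_obs[k] * (1 - 1e-10) - 1e-12)
        done += m
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "df": dfs[k],
                "SumOfSqs": ss_terms[k],
                "R2": ss_terms[k] / ss_total,
                "F": f_obs[k],
                "p": p_values[k],
            }
        )
    rows.append(
        {"df": df_res, "SumOfSqs": ss_res, "R2": ss_res / ss_total, "F": np.nan, "p": np.nan}
    )
    rows.append(
        {"df": n - 1, "SumOfSqs": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Constrained PCoA (distance-based redundancy analysis)
# ---------------------------------------------------------------------------


def constrained_pcoa(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    constraint_terms: Sequence[str],
    n_axes: int = 2,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """PCoA constrained by experimental factors.

    PCoA scores on all positive axes are regressed (least squares) on
    the constraint design matrix; the eigendecomposition of the fitted
    values gives the constrained axes.  The constrained-variance
    proportion is SS_fitted / SS_total, with significance assessed by
    permuting sample rows.
    """
    full = pcoa(dm, n_axes=len(dm.sample_ids))
    y = full.coordinates.to_numpy(dtype=float)
    n = y.shape[0]
    meta = metadata.data.loc[dm.sample_ids]
    design = np.ones((n, 1))
    for term in constraint_terms:
        design = np.hstack([design, _design_matrix(meta, term)])
    h = _hat(design)
    rank = int(round(np.trace(h))) - 1
    if rank >= n - 1:
        raise ValueError("constraint design is saturated (rank >= n-1)")
    yc = y - y.mean(axis=0)
    fitted = h @ yc
    ss_total = float((yc**2).sum())
    ss_fitted = float((fitted**2).sum())
    proportion = ss_fitted / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_p = float(((h @ yc[perm]) ** 2).sum())
        if ss_p >= ss_fitted * (1 - 1e-10) - 1e-12:
            exceed += 1
    p_value = (1.0 + exceed) / (1.0 + n_perm)

    # constrained axes: eigenvectors of the fitted configuration
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eigvals = s**2
    keep = min(n_axes, int((eigvals > 1e-10 * max(1.0, eigvals[0])).sum()))
    coords = u[:, :keep] * s[:keep]
    for k in range(keep):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    prop = eigvals[:keep] / eigvals.sum() * proportion if eigvals.sum() > 0 else eigvals[:keep]
    frame = pd.DataFrame(
        coords, index=dm.sample_ids, columns=[f"CPCo{k + 1}" for k in range(keep)]
    )
    return OrdinationResult(
        frame,
        eigenvalues=eigvals,
        proportion_explained=prop,
        constrained_proportion=proportion,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Group comparisons: Wilcoxon rank-sum + FDR + compact letters
# ---------------------------------------------------------------------------


def _compact_letters(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Greedy insert-absorb compact-letter display.

    Groups sharing a letter are not significantly different.  Ties are
    broken by the given group order.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in significant:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
        # absorb: drop sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(letter_sets)
            if not any(s < o or (s == o and i > j) for j, o in enumerate(letter_sets))
        ]
    # stable ordering: by first member in group order
    def set_key(s: set[str]) -> int:
        return min(groups.index(g) for g in s)

    letter_sets.sort(key=set_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in groups}
    for k, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[k % len(alphabet)]
    return letters


@dataclass
class GroupComparison:
    """Pairwise rank-sum table plus compact-letter display."""

    pairs: pd.DataFrame  # columns: group_a, group_b, W, p, q
    letters: dict[str, str] = field(default_factory=dict)


def wilcoxon_fdr(
    values: Sequence[float] | pd.Series,
    groups: Sequence[str] | pd.Series,
    alpha: float = 0.05,
) -> GroupComparison:
    """All-pairs two-sided Wilcoxon rank-sum tests with BH correction.

    Returns the pairwise table (statistic W, raw p, BH q) and a
    compact-letter display in which groups sharing a letter are not
    significantly different at ``alpha`` after FDR correction.
    """
    v = np.asarray(values, dtype=float)
    g = pd.Series(list(groups)).astype(str)
    if len(v) != len(g):
        raise ValueError("values and groups differ in length")
    group_order = list(dict.fromkeys(g))
    sizes = g.value_counts()
    if len(group_order) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 observations")

    rows = []
    for i in range(len(group_order)):
        for j in range(i + 1, len(group_order)):
            a, b = group_order[i], group_order[j]
            xa, xb = v[g.to_numpy() == a], v[g.to_numpy() == b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                w, p = float(len(xa) * len(xb) / 2), 1.0
            else:
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                w, p = float(res.statistic), float(res.pvalue)
            rows.append({"group_a": a, "group_b": b, "W": w, "p": p})
    pairs = pd.DataFrame(rows)
    _, q, _, _ = multipletests(pairs["p"].to_numpy(), method="fdr_bh")
    pairs["q"] = q
    significant = {
        (r.group_a, r.group_b)
        for r in pairs.itertuples()
        if r.q < alpha
    }
    letters = _compact_letters(group_order, significant)
    return GroupComparison(pairs, letters)
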