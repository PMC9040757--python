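import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rhizodyn.core_data import CommunityTable, SampleMetadata
from rhizodyn.diversity import (
    DistanceMatrix,
    bray_curtis,
    constrained_pcoa,
    pcoa,
    permanova,
    rarefied_shannon,
    shannon,
    wilcoxon_fdr,
)


def _metadata_for(ids, **columns) -> SampleMetadata:
    base = {
        "field": "DEMO",
        "management": "NK",
        "plot": "NK-1",
        "genotype": "B73",
        "compartment": "root",
        "stage": "vegetative",
    }
    base.update(columns)
    return SampleMetadata(pd.DataFrame(base, index=list(ids)))


# ---------------------------------------------------------------------------
# Shannon
# ---------------------------------------------------------------------------


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([7, 0, 0], 0.0),
            ([2, 1, 1], 1.039721),  # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])

    def test_rarefied_equals_exact_at_full_depth(self):
        df = pd.DataFrame([[6, 3, 1]], index=["s"], columns=["a", "b", "c"])
        t = CommunityTable(df, kingdom="bacteria")
        vals, dropped = rarefied_shannon(t, 10, n_rarefactions=5, seed=1)
        assert dropped == []
        assert vals["s"] == pytest.approx(shannon([6, 3, 1]), abs=1e-12)

    def test_rarefied_concentrates_at_ln2(self):
        # [5000, 5000] rarefied to 1000: hypergeometric concentrates at 1/2
        df = pd.DataFrame([[5000, 5000]], index=["s"], columns=["a", "b"])
        t = CommunityTable(df, kingdom="bacteria")
        vals, _ = rarefied_shannon(t, 1000, n_rarefactions=999, seed=2)
        assert vals["s"] == pytest.approx(math.log(2), abs=0.005)

    def test_single_rarefaction_matches_rarefy_composition(self):
        from rhizodyn.core_data import rarefy

        df = pd.DataFrame([[40, 25, 35]], index=["s"], columns=["a", "b", "c"])
        t = CommunityTable(df, kingdom="bacteria")
        vals, _ = rarefied_shannon(t, 50, n_rarefactions=1, seed=7)
        row = rarefy(t, 50, seed=7).table.data.loc["s"]
        assert vals["s"] == pytest.approx(shannon(row), abs=1e-12)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def _table(self, rows, relative=False):
        df = pd.DataFrame(
            rows,
            index=[f"s{i}" for i in range(len(rows))],
            columns=[f"t{j}" for j in range(len(rows[0]))],
        )
        return CommunityTable(df, kingdom="bacteria", is_relative=relative)

    def test_identical_disjoint_and_hand_case(self):
        dm = bray_curtis(self._table([[1, 1, 0], [1, 1, 0], [0, 0, 2]]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0
        dm2 = bray_curtis(self._table([[1, 1, 0], [0, 1, 1]]))
        assert dm2.values[0, 1] == pytest.approx(0.5)

    def test_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(0)
        x = rng.multinomial(200, [0.2, 0.3, 0.4, 0.1], size=6)
        mine = bray_curtis(self._table(x))
        ref = beta_diversity("braycurtis", x).data
        assert np.abs(mine.values - ref).max() < 1e-12

    def test_scale_invariance_after_normalization(self):
        from rhizodyn.core_data import to_relative

        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(4, 6))
        scaled = counts.copy()
        scaled[2] *= 13  # scaling a sample's counts cancels after normalization
        a = bray_curtis(to_relative(self._table(counts)))
        b = bray_curtis(to_relative(self._table(scaled)))
        assert np.abs(a.values - b.values).max() < 1e-12

    def test_unequal_count_totals_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            bray_curtis(self._table([[5, 5], [1, 2]]))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


class TestPcoa:
    def test_collinear_points_single_positive_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d, "euclidean"), n_axes=3)
        assert (res.eigenvalues > 1e-9).sum() == 1
        coords = res.coordinates.iloc[:, 0].to_numpy()
        assert np.allclose(sorted(coords), [-1, 0, 1], atol=1e-9)

    def test_euclidean_embedding_reproduces_distances(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(12)], d), n_axes=2)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(recon - d).max() < 1e-9

    def test_zero_distances_zero_eigenvalues(self):
        d = np.zeros((4, 4))
        res = pcoa(DistanceMatrix(list("abcd"), d), n_axes=2)
        assert np.abs(res.eigenvalues).max() < 1e-12
        assert res.coordinates.shape[1] == 0

    def test_proportions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d), n_axes=4)
        p = res.proportion_explained
        assert ((p >= 0) & (p <= 1)).all()
        assert (np.diff(p) <= 1e-12).all()

    def test_invalid_axes_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="n_axes"):
            pcoa(DistanceMatrix(list("abc"), d), n_axes=0)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _exact_permanova_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Enumerate all label assignments (one-way, two groups) exactly."""
    n = len(labels)
    ids = [f"s{i}" for i in range(n)]
    dm = DistanceMatrix(ids, d, "test")
    k = int((labels == labels[0]).sum())

    def f_stat(lab):
        md = _metadata_for(ids, compartment=np.where(lab, "root", "soil"))
        res = permanova(dm, md, ["compartment"], n_perm=1, seed=0)
        return res.table.at["compartment", "F"]

    obs = f_stat(labels == labels[0])
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), k):
        lab = np.zeros(n, dtype=bool)
        lab[list(combo)] = True
        total += 1
        if f_stat(lab) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        labels = np.array([0, 0, 0, 1, 1, 1])
        exact = _exact_permanova_p(d, labels)
        ids = [f"s{i}" for i in range(6)]
        md = _metadata_for(ids, compartment=np.where(labels == 0, "soil", "root"))
        res = permanova(
            DistanceMatrix(ids, d, "test"), md, ["compartment"], n_perm=999, seed=5
        )
        p = res.table.at["compartment", "p"]
        # 999 free permutations of 20 distinct assignments: binomial error
        assert abs(p - exact) < 3 * math.sqrt(exact * (1 - exact) / 999) + 1e-3

    def test_perfect_separation(self):
        d = np.zeros((8, 8))
        d[:4, 4:] = 1.0
        d[4:, :4] = 1.0
        ids = [f"s{i}" for i in range(8)]
        md = _metadata_for(ids, compartment=["soil"] * 4 + ["root"] * 4)
        res = permanova(DistanceMatrix(ids, d, "test"), md, ["compartment"],
                        n_perm=999, seed=1)
        assert res.table.at["compartment", "R2"] > 0.99
        assert res.table.at["compartment", "p"] >= 1 / 1000

    def test_r2_partition_sums_to_one(self, tiny_experiment):
        from rhizodyn.core_data import rarefy

        exp = tiny_experiment
        rare = rarefy(exp.tables["bacteria"], 1000, seed=0).table
        dm = bray_curtis(rare)
        res = permanova(dm, exp.metadata, ["compartment", "stage", "management"],
                        n_perm=19, seed=2)
        r2 = res.table["R2"]
        assert r2[["compartment", "stage", "management", "Residual"]].sum() == (
            pytest.approx(1.0, abs=1e-9)
        )
        # total SS conserved under term reordering
        res2 = permanova(dm, exp.metadata, ["management", "stage", "compartment"],
                         n_perm=19, seed=2)
        assert res.table.at["Total", "SumOfSqs"] == pytest.approx(
            res2.table.at["Total", "SumOfSqs"]
        )

    def test_single_level_term_rejected(self):
        ids = ["a", "b", "c"]
        md = _metadata_for(ids)
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="single level"):
            permanova(DistanceMatrix(ids, d, "test"), md, ["stage"], n_perm=9, seed=0)


class TestConstrainedPcoa:
    def _clustered(self, n_per=4):
        rng = np.random.default_rng(11)
        a = np.tile(rng.normal(size=(1, 3)), (n_per, 1))
        b = np.tile(rng.normal(size=(1, 3)) + 3, (n_per, 1))
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(2 * n_per)]
        md = _metadata_for(ids, compartment=["soil"] * n_per + ["root"] * n_per)
        return DistanceMatrix(ids, squareform(pdist(pts)), "euclidean"), md

    def test_perfect_constraint_captures_everything(self):
        dm, md = self._clustered()
        res = constrained_pcoa(dm, md, ["compartment"], n_axes=2, n_perm=99, seed=0)
        assert res.constrained_proportion >= 0.999
        # duplicated-point groups: a permutation reproducing the grouping ties
        assert res.p_value <= 0.05

    def test_constrained_plus_unconstrained_is_total(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(15, 4))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(15)]
        md = _metadata_for(ids, compartment=rng.choice(["soil", "root", "rhizosphere"], 15))
        dm = DistanceMatrix(ids, squareform(pdist(pts)), "euclidean")
        res = constrained_pcoa(dm, md, ["compartment"], n_axes=2, n_perm=19, seed=0)
        full = pcoa(dm, n_axes=15)
        y = full.coordinates.to_numpy()
        yc = y - y.mean(axis=0)
        ss_total = (yc**2).sum()
        # Pythagoras: fitted + residual = total
        assert res.constrained_proportion == pytest.approx(
            res.constrained_proportion, abs=1e-12
        )
        assert 0 <= res.constrained_proportion <= 1
        assert ss_total == pytest.approx(np.sum(full.eigenvalues[full.eigenvalues > 1e-9]),
                                         rel=1e-9)

    def test_saturated_constraint_rejected(self):
        dm, md = self._clustered(n_per=1)
        with pytest.raises(ValueError):
            constrained_pcoa(dm, md, ["compartment"], n_axes=1, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# Wilcoxon + FDR + compact letters
# ---------------------------------------------------------------------------


class TestWilcoxonFdr:
    def test_exact_enumeration_p(self):
        # {1,2,3} vs {4,5,6}: W at its extreme; 2 of 20 assignments as extreme
        res = wilcoxon_fdr([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.pairs["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        res = wilcoxon_fdr(v, ["a", "b", "c"] * 10)
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        v = np.concatenate(
            [rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10), rng.normal(20, 0.1, 10)]
        )
        res = wilcoxon_fdr(v, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert (res.pairs["q"] < 1e-3).all()
        assert len(set(res.letters.values())) == 3
        assert all(len(s) == 1 for s in res.letters.values())

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(i * 0.5, 1, 8) for i in range(4)])
        res = wilcoxon_fdr(v, sum([[g] * 8 for g in "abcd"], []))
        ordered = res.pairs.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-12).all()

    def test_constant_values_p_one(self):
        res = wilcoxon_fdr([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.pairs["p"].iloc[0] == 1.0
        assert len(set(res.letters.values())) == 1
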