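import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from syncomscreen import (
    AbundanceTable,
    CompoundTable,
    DataValidationError,
    DistanceMatrix,
    alpha_diversity,
    anosim,
    assign_amino_acid_group,
    assign_flavor_group,
    assign_major_group,
    distance_matrix,
    mantel_test,
    pairwise_association,
    to_relative_abundance,
)

from oracles import anosim_oracle, mantel_exact_oracle, spearman_rank_pearson


def _abund(matrix, taxa, samples, kingdoms=None):
    data = pd.DataFrame(matrix, index=taxa, columns=samples, dtype=float)
    k = pd.Series(kingdoms or ["bacteria"] * len(taxa), index=taxa)
    return AbundanceTable(data, k)


def _comp(matrix, names, classes, samples):
    data = pd.DataFrame(matrix, index=names, columns=samples, dtype=float)
    return CompoundTable(data, pd.Series(classes, index=names))


SAMPLES6 = [f"s{i}" for i in range(6)]


class TestPairwiseAssociation:
    def test_perfect_monotone_pair(self):
        ab = _abund([[1, 2, 3, 4]], ["T"], SAMPLES6[:4])
        cp = _comp([[10, 20, 30, 40]], ["E"], ["ester"], SAMPLES6[:4])
        res = pairwise_association(ab, cp)
        row = res.iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert not row["degenerate"]
        assert row["n"] == 4

    def test_constant_vector_flagged_degenerate(self):
        ab = _abund([[1, 2, 3, 4]], ["T"], SAMPLES6[:4])
        cp = _comp([[5, 5, 5, 5]], ["E"], ["ester"], SAMPLES6[:4])
        row = pairwise_association(ab, cp).iloc[0]
        assert row["rho"] == 0.0 and row["p"] == 1.0 and row["degenerate"]

    def test_rho_matches_rank_then_pearson_oracle(self):
        x = [1, 4, 2, 6, 5, 3]
        y = [2, 3, 1, 6, 5, 4]
        ab = _abund([x], ["T"], SAMPLES6)
        cp = _comp([y], ["E"], ["ester"], SAMPLES6)
        row = pairwise_association(ab, cp).iloc[0]
        assert row["rho"] == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_requires_four_shared_samples(self):
        ab = _abund([[1, 2, 3]], ["T"], SAMPLES6[:3])
        cp = _comp([[1, 2, 3]], ["E"], ["ester"], SAMPLES6[:3])
        with pytest.raises(DataValidationError, match="4"):
            pairwise_association(ab, cp)

    def test_bh_is_per_class_and_monotone(self, small_dataset):
        abund, comp, _, _ = small_dataset
        res = pairwise_association(to_relative_abundance(abund), comp)
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert (res["q"] <= 1.0 + 1e-12).all()
        for _, fam in res.groupby("compound_class"):
            fam = fam.sort_values("p")
            # step-up adjusted values are non-decreasing along sorted p
            assert (np.diff(fam["q"].to_numpy()) >= -1e-12).all()
            expected = stats.false_discovery_control(fam["p"].to_numpy())
            np.testing.assert_allclose(fam["q"].to_numpy(), expected, atol=1e-12)


class TestGroupAssignment:
    def _results(self, rows):
        df = pd.DataFrame(
            rows, columns=["taxon", "compound", "compound_class", "rho", "q"]
        )
        df["p"] = df["q"]
        df["n"] = 10
        df["degenerate"] = False
        return df

    def test_flavor_needs_both_ester_and_acid(self):
        res = self._results(
            [
                ("A", "E1", "ester", 0.9, 0.001),
                ("A", "L", "organic_acid", 0.8, 0.002),
                ("B", "E1", "ester", 0.9, 0.001),
            ]
        )
        assert assign_flavor_group(res) == {"A"}

    def test_flavor_errors_without_acid_compounds(self):
        res = self._results([("A", "E1", "ester", 0.9, 0.001)])
        with pytest.raises(DataValidationError, match="acid"):
            assign_flavor_group(res)

    def test_amino_group_min_hits(self):
        res = self._results(
            [
                ("A", "aa1", "amino_acid", 0.8, 0.01),
                ("A", "aa2", "amino_acid", 0.7, 0.01),
                ("A", "aa3", "amino_acid", 0.9, 0.01),
                ("B", "aa1", "amino_acid", 0.8, 0.01),
            ]
        )
        assert assign_amino_acid_group(res, min_hits=2) == {"A"}

    def test_random_table_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        taxa = [f"t{i}" for i in range(10)]
        compounds = [
            ("E1", "ester"), ("E2", "ester"), ("A1", "acid"),
            ("O1", "organic_acid"), ("aa1", "amino_acid"), ("aa2", "amino_acid"),
        ]
        rows = [
            (t, c, cls, rng.uniform(-1, 1), rng.uniform(0, 0.2))
            for t in taxa
            for c, cls in compounds
        ]
        res = self._results(rows)
        alpha, rho_min = 0.05, 0.6
        ok = res[(res.rho >= rho_min) & (res.q < alpha)]
        ester = set(ok[ok.compound_class == "ester"].taxon)
        acid = set(ok[ok.compound_class.isin(["acid", "organic_acid"])].taxon)
        amino_counts = ok[ok.compound_class == "amino_acid"].groupby("taxon").size()
        assert assign_flavor_group(res, alpha, rho_min) == ester & acid
        assert assign_amino_acid_group(res, alpha, rho_min, 2) == set(
            amino_counts[amino_counts >= 2].index
        )

    def test_major_group_strict_boundary(self):
        ab = _abund([[0.002, 0.000], [0.05, 0.05], [0.948, 0.95]],
                    ["edge", "big", "huge"], ["s1", "s2"])
        major = assign_major_group(ab, threshold=0.001)
        assert "edge" not in major  # mean exactly 0.001 is not > 0.001
        assert {"big", "huge"} <= major

    def test_major_group_matches_row_mean_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.dirichlet(np.ones(20), size=6).T
        ab = _abund(m, [f"t{i}" for i in range(20)], SAMPLES6)
        expected = {f"t{i}" for i in range(20) if m[i].mean() > 0.001}
        assert assign_major_group(ab) == expected

    def test_assignment_invariant_to_ordering(self, small_dataset):
        abund, comp, _, _ = small_dataset
        rel = to_relative_abundance(abund)
        res = pairwise_association(rel, comp)
        rev = AbundanceTable(
            rel.data.iloc[::-1, ::-1].copy(), rel.kingdom.iloc[::-1].copy()
        )
        comp_rev = CompoundTable(
            comp.data[rev.samples].copy(), comp.compound_class.copy()
        )
        res_rev = pairwise_association(rev, comp_rev)
        assert assign_flavor_group(res) == assign_flavor_group(res_rev)
        assert assign_major_group(rel) == assign_major_group(rev)


class TestDistances:
    def test_identical_columns_distance_zero(self):
        ab = _abund([[0.5, 0.5], [0.5, 0.5]], ["a", "b"], ["s1", "s2"])
        d = distance_matrix(ab, "bray_curtis")
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_distance_one(self):
        ab = _abund([[1, 0], [0, 1]], ["a", "b"], ["s1", "s2"])
        assert distance_matrix(ab, "bray_curtis").values[0, 1] == 1.0
        assert distance_matrix(ab, "jaccard").values[0, 1] == 1.0

    def test_bray_curtis_matches_hand_formula(self):
        x = np.array([0.5, 0.5, 0.0])
        y = np.array([0.25, 0.25, 0.5])
        ab = _abund(np.column_stack([x, y]), ["a", "b", "c"], ["s1", "s2"])
        expected = np.abs(x - y).sum() / (x + y).sum()
        assert distance_matrix(ab, "bray_curtis").values[0, 1] == pytest.approx(expected)

    def test_symmetry_zero_diagonal_bounds(self, small_dataset):
        abund, _, _, _ = small_dataset
        d = distance_matrix(to_relative_abundance(abund), "bray_curtis")
        assert np.allclose(d.values, d.values.T, atol=1e-12)
        assert np.all(np.diag(d.values) == 0)
        assert d.values.min() >= 0 and d.values.max() <= 1


class TestMantel:
    def _dm(self, values, n):
        return DistanceMatrix([f"s{i}" for i in range(n)], values, "euclidean")

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        r, _ = mantel_test(self._dm(d, 6), self._dm(d, 6), permutations=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_transform_pearson_r_one(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        d2 = 3.0 * d + 0.5
        np.fill_diagonal(d2, 0.0)
        r, _ = mantel_test(
            self._dm(d, 6), self._dm(d2, 6), method="pearson", permutations=49, seed=0
        )
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(6)
        d1 = squareform(pdist(rng.normal(size=(5, 2))))
        d2 = squareform(pdist(rng.normal(size=(5, 2))))
        r, p = mantel_test(self._dm(d1, 5), self._dm(d2, 5), exact=True)
        r_o, p_o = mantel_exact_oracle(d1, d2)
        assert r == pytest.approx(r_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_label_mismatch_is_fatal(self):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.normal(size=(5, 2))))
        a = self._dm(d, 5)
        b = DistanceMatrix([f"x{i}" for i in range(5)], d, "euclidean")
        with pytest.raises(DataValidationError):
            mantel_test(a, b)

    def test_cross_check_against_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        d1 = squareform(pdist(rng.normal(size=(8, 3))))
        d2 = squareform(pdist(rng.normal(size=(8, 3))))
        r, _ = mantel_test(self._dm(d1, 8), self._dm(d2, 8), permutations=99, seed=0)
        r_sk, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1),
            skbio_distance.DistanceMatrix(d2),
            method="spearman",
            permutations=0,
        )
        assert r == pytest.approx(r_sk, abs=1e-10)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        dm = DistanceMatrix(list("abcd"), d, "bray_curtis")
        r, _ = anosim(dm, ["g1", "g1", "g2", "g2"], permutations=49, seed=0)
        assert r == pytest.approx(1.0)  # (4.5 - 1.5) / 3

    def test_mean_r_over_permutations_near_zero(self):
        rng = np.random.default_rng(9)
        d = squareform(pdist(rng.normal(size=(8, 3))))
        dm = DistanceMatrix([f"s{i}" for i in range(8)], d, "euclidean")
        labels = np.array(["a"] * 4 + ["b"] * 4)
        rs = []
        for _ in range(300):
            r, _ = anosim(dm, rng.permutation(labels), permutations=1, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_matches_mean_rank_oracle(self):
        rng = np.random.default_rng(10)
        d = squareform(pdist(rng.normal(size=(6, 2))))
        labels = np.array(["a", "a", "b", "b", "b", "a"])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "euclidean")
        r, _ = anosim(dm, labels, permutations=9, seed=0)
        assert r == pytest.approx(anosim_oracle(d, labels), abs=1e-12)

    def test_cross_check_against_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        d = squareform(pdist(rng.normal(size=(9, 3))))
        labels = ["a"] * 4 + ["b"] * 5
        dm = DistanceMatrix([f"s{i}" for i in range(9)], d, "euclidean")
        r, _ = anosim(dm, labels, permutations=9, seed=0)
        res = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(d, ids=dm.labels),
            grouping=list(labels),
            permutations=0,
        )
        assert r == pytest.approx(res["test statistic"], abs=1e-10)

    def test_singleton_group_is_fatal(self):
        d = squareform(pdist(np.arange(4).reshape(-1, 1).astype(float)))
        dm = DistanceMatrix(list("abcd"), d, "euclidean")
        with pytest.raises(DataValidationError, match="single"):
            anosim(dm, ["g1", "g1", "g1", "g2"])

    def test_r_always_in_unit_interval(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            d = squareform(pdist(rng.normal(size=(7, 2))))
            dm = DistanceMatrix([f"s{i}" for i in range(7)], d, "euclidean")
            labels = rng.choice(["a", "b"], size=7)
            if min((labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            r, p = anosim(dm, labels, permutations=19, seed=1)
            assert -1.0 <= r <= 1.0 and 0 < p <= 1


class TestAlphaDiversity:
    def test_uniform_and_single_taxon_limits(self):
        ab = _abund(
            [[0.25, 1.0], [0.25, 0.0], [0.25, 0.0], [0.25, 0.0]],
            ["a", "b", "c", "d"],
            ["u", "mono"],
        )
        res = alpha_diversity(ab)
        assert res.loc["u", "shannon"] == pytest.approx(np.log(4))
        assert res.loc["u", "pielou"] == pytest.approx(1.0)
        assert res.loc["u", "observed"] == 4
        assert res.loc["mono", "shannon"] == 0.0
        assert res.loc["mono", "pielou"] == 0.0
        assert res.loc["mono", "observed"] == 1

    def test_matches_direct_entropy_oracle_and_skbio(self):
        p = np.array([0.5, 0.3, 0.2])
        ab = _abund(p.reshape(-1, 1), ["a", "b", "c"], ["s1"])
        res = alpha_diversity(ab)
        assert res.loc["s1", "shannon"] == pytest.approx(-(p * np.log(p)).sum())
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        assert res.loc["s1", "shannon"] == pytest.approx(
            float(skbio_alpha.shannon(np.round(p * 1000).astype(int), base=np.e)),
            abs=1e-9,
        )
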