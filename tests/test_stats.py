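import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import mannwhitneyu, pearsonr, rankdata, spearmanr

from domfinger.stats import (
    DissimilarityMatrix,
    anosim,
    anosim_r,
    bray_curtis,
    formula_component_correlation,
    pca,
    pearson,
    spearman,
    wilcoxon_rank_sum,
)
from tests.conftest import make_assigned


def naive_anosim_r(matrix, labels):
    """Independent oracle: O(m^2) rank computation and explicit double loop."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [matrix[i][j] for i, j in pairs]
    ranks = []
    for v in vals:
        smaller = sum(1 for w in vals if w < v)
        equal = sum(1 for w in vals if w == v)
        ranks.append(smaller + (equal + 1) / 2)
    rw = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    rb = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (sum(rb) / len(rb) - sum(rw) / len(rw)) / (m / 2)


def random_dissimilarity(rng, n):
    m = rng.uniform(0, 1, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.matrix[0, 1] == 0.0

    def test_disjoint_support_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 3.0]]))
        assert d.matrix[0, 1] == 1.0

    def test_hand_computed(self):
        d = bray_curtis(np.array([[2.0, 2.0], [1.0, 3.0]]))
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 5, (6, 30))
        d = bray_curtis(X)
        for i in range(6):
            for j in range(i + 1, 6):
                assert d.matrix[i, j] == pytest.approx(scipy_braycurtis(X[i], X[j]))

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestAnosim:
    def test_fully_separated_groups_give_r_one(self):
        # between-pair dissimilarities all exceed within-pair ones
        m = np.array([
            [0.0, 0.1, 0.9, 0.9],
            [0.1, 0.0, 0.9, 0.9],
            [0.9, 0.9, 0.0, 0.1],
            [0.9, 0.9, 0.1, 0.0],
        ])
        d = DissimilarityMatrix(ids=list("abcd"), matrix=m)
        res = anosim(d, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_dissimilarities_give_r_zero(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        d = DissimilarityMatrix(ids=list("abcd"), matrix=m)
        assert anosim(d, ["g1", "g1", "g2", "g2"], n_permutations=49, seed=0).r == 0.0

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for k in range(20):
            m = random_dissimilarity(rng, 8)
            labels = list(rng.permutation(["a"] * 4 + ["b"] * 4))
            assert anosim_r(m, labels) == pytest.approx(
                naive_anosim_r(m.tolist(), labels), abs=1e-12
            )

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(2)
        m = random_dissimilarity(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dm = skbio.DistanceMatrix(m, ids=[str(i) for i in range(9)])
        expected = skbio_anosim(dm, grouping=labels, permutations=9)["test statistic"]
        assert anosim_r(m, labels) == pytest.approx(expected, abs=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(3)
        m = random_dissimilarity(rng, 8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        d = DissimilarityMatrix(ids=[str(i) for i in range(8)], matrix=m)
        obs = anosim_r(m, labels)
        # exact null: all 70 assignments of 4 samples to group "a"
        rs = []
        for idx in combinations(range(8), 4):
            lab = np.array(["b"] * 8)
            lab[list(idx)] = "a"
            rs.append(anosim_r(m, lab))
        exact_p = sum(1 for r in rs if r >= obs - 1e-12) / len(rs)
        res = anosim(d, labels, n_permutations=999, seed=5)
        assert res.p == pytest.approx(exact_p, abs=0.03)

    def test_singleton_group_rejected(self):
        m = random_dissimilarity(np.random.default_rng(0), 5)
        d = DissimilarityMatrix(ids=list("abcde"), matrix=m)
        with pytest.raises(ValueError, match=">= 2"):
            anosim(d, ["a", "a", "a", "a", "b"], seed=0)

    def test_null_r_centered_at_zero(self):
        """Mean R over many random labellings of one matrix is ~0."""
        rng = np.random.default_rng(7)
        m = random_dissimilarity(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        rs = [anosim_r(m, rng.permutation(labels)) for _ in range(1000)]
        assert abs(np.mean(rs)) < 0.02


class TestPca:
    def test_collinear_points_single_component(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        res = pca(X)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_reconstruction_roundtrip(self):
        X = np.random.default_rng(1).normal(size=(8, 5))
        res = pca(X)
        recon = res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-9)

    def test_scores_orthogonal(self):
        X = np.random.default_rng(2).normal(size=(12, 6))
        res = pca(X)
        gram = res.scores.T @ res.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-9)

    def test_constant_matrix_warns_zero_variance(self):
        with pytest.warns(UserWarning, match="constant"):
            res = pca(np.ones((4, 3)))
        assert (res.explained_variance_ratio == 0).all()


class TestWilcoxonRankSum:
    def test_identical_samples_p_one_exact(self):
        x = [1.0, 2.0, 3.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p == 1.0

    def test_complete_separation_exact_one_sided_p(self):
        x = [1, 2, 3, 4, 5]
        y = [6, 7, 8, 9, 10]
        _, p = wilcoxon_rank_sum(x, y, alternative="less")
        assert p == pytest.approx(1 / 252)

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=6)
        w1, _ = wilcoxon_rank_sum(x, y)
        w2, _ = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert w1 == w2

    def test_large_sample_agrees_with_scipy_normal_approx(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 30)
        _, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_exact_matches_scipy_exact(self):
        x = [1.2, 3.4, 2.2, 5.0]
        y = [0.3, 4.1, 6.7, 8.8, 2.9]
        _, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_constructed_orthogonal_vectors_r_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y) == pytest.approx(pearson(y, x))

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = pearson(x, y)
        ref = pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = spearman(x, y)
        ref, _ = pearson(rankdata(x), rankdata(y))
        assert rho == pytest.approx(ref, abs=1e-12)
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


class TestFormulaComponentCorrelation:
    def _samples(self, intensities_by_sample):
        out = []
        for sid, mapping in intensities_by_sample.items():
            out.append(make_assigned(sid, mapping))
        return out

    def test_monotone_formula_is_significant_positive(self):
        # C6H12O6 intensity increases with component score; filler constant-ish
        samples = self._samples({
            f"s{i}": {"C6H12O6": 1.0 + i, "C10H12O7": 5.0 + 0.1 * ((-1) ** i)}
            for i in range(8)
        })
        scores = pd.DataFrame({"C1": np.arange(8.0)}, index=[f"s{i}" for i in range(8)])
        res = formula_component_correlation(samples, scores)
        row = res.table[(res.table.formula == "C6H12O6") & (res.table.component == "C1")]
        assert row.rho.iloc[0] == pytest.approx(1.0)
        assert bool(row.significant.iloc[0])

    def test_constant_intensity_formula_skipped(self):
        # totals kept constant so C6H12O6's relative intensity is constant
        samples = self._samples({
            f"s{i}": {"C6H12O6": 2.0, "C10H12O7": 1.0 + i, "C12H14O8": 6.0 - i}
            for i in range(6)
        })
        scores = pd.DataFrame({"C1": np.arange(6.0)}, index=[f"s{i}" for i in range(6)])
        res = formula_component_correlation(samples, scores)
        assert "C6H12O6" not in set(res.table.formula)
        assert res.n_skipped == 1

    def test_rare_formula_skipped(self):
        mapping = {f"s{i}": {"C10H12O7": 1.0 + i} for i in range(6)}
        mapping["s0"]["C6H12O6"] = 1.0
        mapping["s1"]["C6H12O6"] = 2.0
        samples = self._samples(mapping)
        scores = pd.DataFrame({"C1": np.arange(6.0)}, index=list(mapping))
        res = formula_component_correlation(samples, scores)
        assert "C6H12O6" not in set(res.table.formula)

    def test_protein_like_component_selects_high_hc_formulas(self, seed42_dataset):
        """Formulas tracking the decaying protein-like score profile are the
        H-saturated preformed ones: the significant positive set's weighted
        H/C exceeds the all-formula weighted mean."""
        library, _, assigned = seed42_dataset
        from domfinger import simulate_eems
        from domfinger.synthetic import ExperimentDesign

        substrate = [s for s in assigned if s.meta.arm is None]
        design = ExperimentDesign(lysis_arms=("exudate", "mechanical", "viral"))
        eems = simulate_eems(design, seed=44)
        scores = pd.DataFrame(
            eems.true_scores, index=eems.sample_ids,
            columns=["C1", "C2", "C3", "C4"],
        )
        res = formula_component_correlation(substrate, scores)
        summary = res.summary.set_index("component")
        from domfinger.formula import Formula
        from domfinger.stats import abundance_matrix

        mat = abundance_matrix(substrate)
        global_hc = np.average(
            [Formula.from_string(f).h / Formula.from_string(f).c for f in mat.columns],
            weights=mat.mean(axis=0).to_numpy(),
        )
        assert summary.loc["C1", "mean_hc"] > global_hc
        assert summary.loc["C2", "mean_hc"] > global_hc
        # humic-like components track the oxidized remaining pool
        assert summary.loc["C3", "mean_oc"] > summary.loc["C1", "mean_oc"]
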