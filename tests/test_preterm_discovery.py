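"""Count DE screen: CPM, dispersion, NB exact test, permutation, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from cfpreg import preterm_discovery as pdisc
from cfpreg import synthetic_cohort as sc


class TestCpmNormalize:
    def test_single_gene_full_library(self):
        counts = pd.DataFrame({"s1": [10]}, index=["G"])
        cpm, lib = pdisc.cpm_normalize(counts)
        assert cpm.loc["G", "s1"] == pytest.approx(1e6)
        assert lib["s1"] == 10

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (20, 4)))
        cpm1, _ = pdisc.cpm_normalize(counts)
        cpm2, _ = pdisc.cpm_normalize(counts * 2)
        pd.testing.assert_frame_equal(cpm1, cpm2)

    def test_column_sums_exactly_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, (50, 6)))
        cpm, _ = pdisc.cpm_normalize(counts)
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_flagged_and_excluded(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.warns(UserWarning, match="zero-count"):
            cpm, _ = pdisc.cpm_normalize(counts)
        assert list(cpm.columns) == ["a"]


class TestCommonDispersion:
    def test_constant_counts_zero_dispersion(self):
        counts = pd.DataFrame(np.full((10, 6), 7))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        assert pdisc.estimate_common_dispersion(counts, groups) == 0.0

    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(20, 200, 2000)
        counts = pd.DataFrame(rng.poisson(mu[:, None], (2000, 12)))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        assert pdisc.estimate_common_dispersion(counts, groups) < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        phi = 0.2
        r = 1.0 / phi
        mu = rng.uniform(20, 200, 2000)
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), (2000, 12)))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        est = pdisc.estimate_common_dispersion(counts, groups)
        assert 0.15 <= est <= 0.25

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError):
            pdisc.estimate_common_dispersion(counts,
                                             np.array(["a", "a", "b", "b"]))


def exact_test_oracle(counts_g, groups, phi):
    """Brute-force enumeration over every split of the gene's total."""
    counts_g = np.asarray(counts_g, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    g1 = groups == labels[0]
    n1, n2 = int(g1.sum()), int((~g1).sum())
    s1 = int(round(counts_g[g1].sum()))
    total = int(round(counts_g.sum()))
    if total == 0:
        return 1.0
    probs = np.empty(total + 1)
    for y in range(total + 1):
        if phi == 0:
            p1 = n1 / (n1 + n2)
            probs[y] = stats.binom.pmf(y, total, p1)
        else:
            r1, r2 = n1 / phi, n2 / phi
            # NB pmf products with the success probability cancelling
            probs[y] = math.exp(
                gammaln(y + r1) - gammaln(y + 1) - gammaln(r1)
                + gammaln(total - y + r2) - gammaln(total - y + 1)
                - gammaln(r2))
    probs = probs / probs.sum()
    left = probs[:s1 + 1].sum()
    right = probs[s1:].sum()
    return min(1.0, 2.0 * min(left, right))


class TestNbExactTest:
    def test_symmetric_split_p_is_one(self):
        p = pdisc.nb_exact_test([5, 5, 5, 5], np.array(["a", "a", "b", "b"]),
                                0.3)
        assert p == pytest.approx(1.0)

    def test_phi_zero_one_vs_one_matches_binomial(self):
        p = pdisc.nb_exact_test([8, 2], np.array(["a", "b"]), 0.0)
        assert p == pytest.approx(stats.binomtest(8, 10, 0.5).pvalue)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("split", [(1, 1), (3, 4), (2, 5)])
    def test_matches_enumeration_oracle_small_totals(self, phi, split):
        rng = np.random.default_rng(17)
        n1, n2 = split
        for _ in range(6):
            total = int(rng.integers(1, 31))
            s1 = int(rng.integers(0, total + 1))
            counts = np.zeros(n1 + n2)
            counts[0] = s1
            counts[n1] = total - s1
            groups = np.array(["a"] * n1 + ["b"] * n2)
            ours = pdisc.nb_exact_test(counts, groups, phi)
            oracle = exact_test_oracle(counts, groups, phi)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            pdisc.nb_exact_test([1, 2], np.array(["a", "b"]), -0.5)


class TestPermutationTest:
    def test_exhaustive_three_vs_three(self):
        p = pdisc.permutation_test([0, 0, 0, 10, 10, 10],
                                   np.array(["a"] * 3 + ["b"] * 3))
        assert p == pytest.approx(0.1)  # 2 extreme splits of C(6,3)=20

    def test_no_signal_p_near_one(self):
        vals = np.ones(8)
        p = pdisc.permutation_test(vals, np.array(["a"] * 4 + ["b"] * 4))
        assert p == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 24)
        groups = np.array(["a"] * 12 + ["b"] * 12)
        p1 = pdisc.permutation_test(vals, groups, n_perm=999, seed=3,
                                    exhaustive=False)
        p2 = pdisc.permutation_test(vals, groups, n_perm=999, seed=3,
                                    exhaustive=False)
        assert p1 == p2

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            pdisc.permutation_test([1, 2, 3, 4],
                                   np.array(["a", "a", "b", "b"]), n_perm=99)

    def test_batch_matches_single_gene_path(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, (5, 16))
        groups = np.array(["a"] * 8 + ["b"] * 8)
        batch = pdisc._batch_permutation_pvalues(values, groups, 1999, seed=2)
        for i in range(5):
            single = pdisc.permutation_test(values[i], groups, n_perm=1999,
                                            seed=2, exhaustive=False)
            # same seed stream differs; agreement is statistical
            assert batch[i] == pytest.approx(single, abs=0.08)


class TestDiscoverDeGenes:
    def simulate(self, seed, effect_g=0.0, n_genes=120):
        panel, weights = sc.make_seq_panel(n_genes, 38)
        phi = 0.2
        lfc = {g: effect_g * w * math.sqrt(phi) / math.log(2)
               for g, w in weights.items()}
        config = sc.SimulationConfig(
            seed=seed,
            cohorts=(sc.CohortDesign("seq", 15, scheme="sparse", n_draws=1,
                                     window=(17.0, 35.0),
                                     preterm_fraction=8 / 15),))
        counts, outcomes = sc.simulate_count_matrix(config, panel, phi,
                                                    effect_log2fc=lfc)
        groups = outcomes.set_index("subject_id").loc[counts.columns,
                                                      "label"].to_numpy()
        return counts, groups

    def test_equal_mean_noise_free_counts_nothing_significant(self):
        counts = pd.DataFrame(np.tile([[40], [80], [20]], (1, 8)),
                              index=["A", "B", "C"])
        groups = np.array(["term"] * 4 + ["preterm"] * 4)
        de = pdisc.discover_de_genes(counts, groups, n_perm=999)
        assert not de["significant"].any()
        assert (de["p_exact"] == 1.0).all()

    def test_null_counts_controlled(self):
        counts, groups = self.simulate(seed=21, effect_g=0.0)
        de = pdisc.discover_de_genes(counts, groups, seed=0)
        assert de["significant"].sum() <= 1

    def test_injected_effect_recovered_by_exact_test(self):
        """Strong injected effects (standardized ~2 on the log scale) are
        picked up by the count-level exact test far above the null rate;
        the intersection rule is a subset bounded by the permutation test's
        resolution at n = 8 vs 7. Bounds frozen from a simulation-derived
        power envelope at these cohort sizes."""
        for seed in (31, 32, 33):
            counts, groups = self.simulate(seed=seed, effect_g=2.0,
                                           n_genes=500)
            de = pdisc.discover_de_genes(counts, groups, seed=0)
            exact_hits = (de["p_exact"][:38] < 0.001).sum()
            null_hits = (de["p_exact"][38:] < 0.001).sum()
            inter_hits = de["significant"][:38].sum()
            assert exact_hits >= 9
            assert null_hits < exact_hits
            assert 1 <= inter_hits <= exact_hits
            # every intersection call is also an exact-test call
            assert (de["significant"] <= (de["p_exact"] < 0.001)).all()

    def test_significant_requires_both_tests(self):
        counts, groups = self.simulate(seed=41, effect_g=2.0)
        de = pdisc.discover_de_genes(counts, groups, seed=0)
        expected = (de["p_exact"] < 0.001) & (de["p_perm"] < 0.001)
        assert (de["significant"] == expected).all()


class TestTwoGroupCluster:
    def test_separated_blobs_full_agreement(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (30, 8))
        b = rng.normal(6, 1, (30, 7))
        values = pd.DataFrame(np.hstack([a, b]))
        labels = np.array(["x"] * 8 + ["y"] * 7)
        _, agreement = pdisc.two_group_cluster(values, labels)
        assert agreement == 1.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(np.hstack([rng.normal(0, 1, (20, 6)),
                                         rng.normal(4, 1, (20, 6))]))
        labels = np.array(["x"] * 6 + ["y"] * 6)
        _, a1 = pdisc.two_group_cluster(values, labels)
        perm = rng.permutation(12)
        _, a2 = pdisc.two_group_cluster(values.iloc[:, perm], labels[perm])
        assert a1 == a2

    def test_constant_gene_dropped_with_warning(self):
        values = pd.DataFrame([[1.0, 1.0, 1.0, 1.0],
                               [0.0, 0.1, 3.0, 3.2]])
        with pytest.warns(UserWarning, match="constant"):
            clusters, _ = pdisc.two_group_cluster(
                values, np.array(["x", "x", "y", "y"]))
        assert len(np.unique(clusters)) == 2


class TestPlatformConcordance:
    def test_identical_vectors(self):
        r, _ = pdisc.platform_concordance([1, 2, 3.0], [1, 2, 3.0])
        assert r == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        r, _ = pdisc.platform_concordance([1, 2, 3.0], [3, 2, 1.0])
        assert r == pytest.approx(-1.0)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pdisc.platform_concordance([1, 2.0], [1, 2.0])

    def test_shared_truth_with_noise_envelope(self):
        """Two platforms measuring the same fold-changes with independent
        noise stay clearly but imperfectly correlated."""
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(20):
            truth = rng.normal(0, 1, 40)
            a = truth + rng.normal(0, 0.5, 40)
            b = truth + rng.normal(0, 0.5, 40)
            r, _ = pdisc.platform_concordance(a, b)
            rs.append(r)
        assert all(0.5 <= r <= 0.95 for r in rs)
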