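"""PCA encoding, DAPC assignment and k-means/BIC cluster selection."""

import itertools

import numpy as np
import pytest

from conftest import make_table
from thermotrout import clustering, synth
from thermotrout.clustering import (
    best_k,
    dapc_crossvalidate,
    dapc_train,
    encode_and_pca,
    encode_alleles,
    kmeans_bic,
    null_accuracy,
    select_n_pcs,
)


@pytest.fixture(scope="module")
def structured():
    """Three well-separated synthetic 'populations' at high divergence."""
    cfg = synth.GeneratorConfig(
        seed=31, target_fst=0.45,
        genotype_n_per_stream={"P1": 12, "P2": 10, "P3": 9},
    )
    table = synth.generate_genotypes(cfg)
    _, pca = encode_and_pca(table)
    return table, pca


@pytest.fixture(scope="module")
def unstructured():
    cfg = synth.GeneratorConfig(
        seed=32, target_fst=0.0,
        genotype_n_per_stream={"P1": 24, "P2": 15, "P3": 8},
    )
    table = synth.generate_genotypes(cfg)
    _, pca = encode_and_pca(table)
    return table, pca


class TestEncoding:
    def test_row_sums_are_twice_loci_count(self):
        table = make_table(
            {"A": [[(1, 2), (3, 3)], [(1, 1), (3, 4)]]}, loci=["L1", "L2"]
        )
        acm = encode_alleles(table)
        np.testing.assert_allclose(acm.matrix.sum(axis=1), 4.0)

    def test_missing_entries_mean_imputed(self):
        table = make_table({"A": [[(1, 1)], [(1, 2)], [(-1, -1)]]})
        acm = encode_alleles(table)
        # imputed row equals the column means of observed rows
        np.testing.assert_allclose(acm.matrix[2], acm.matrix[:2].mean(axis=0))
        assert acm.imputed_fraction == pytest.approx(1 / 3)


class TestPCA:
    def test_two_fixed_pops_separate_on_pc1(self, ):
        table = make_table(
            {"A": [[(1, 1), (1, 1)]] * 5, "B": [[(2, 2), (2, 2)]] * 5}
        )
        _, pca = encode_and_pca(table)
        pc1 = pca.scores[:, 0]
        assert max(pc1[:5]) < min(pc1[5:]) or min(pc1[:5]) > max(pc1[5:])

    def test_variance_fractions_sum_to_one(self, structured):
        _, pca = structured
        assert pca.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(pca.variance_fractions) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, structured):
        """Variance fractions agree with a dense eigensolve of the centred
        cross-product matrix, and the 95% retention rule matches."""
        table, pca = structured
        acm = encode_alleles(table)
        Xc = acm.matrix - acm.centre
        evals = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
        evals = evals[evals > evals[0] * 1e-10]
        np.testing.assert_allclose(
            pca.variance_fractions, evals / evals.sum(), atol=1e-10
        )
        cum = np.cumsum(evals / evals.sum())
        assert pca.n_pcs_for_variance(0.95) == int(np.searchsorted(cum, 0.95) + 1)

    def test_reconstruction_from_all_pcs(self, structured):
        table, pca = structured
        acm = encode_alleles(table)
        Xc = acm.matrix - acm.centre
        np.testing.assert_allclose(
            pca.scores @ pca.loadings.T, Xc, atol=1e-10
        )

    def test_zero_variance_matrix_rejected(self):
        table = make_table({"A": [[(1, 1)], [(1, 1)], [(1, 1)]]})
        with pytest.raises(ValueError, match="zero-variance"):
            encode_and_pca(table)


class TestDAPC:
    def test_separable_groups_fully_assigned(self, structured):
        table, pca = structured
        model = dapc_train(pca.scores, table.pop_labels, n_pcs=4)
        assert model.overall_training_accuracy == 1.0
        assert all(v == 1.0 for v in model.training_accuracy.values())

    def test_posteriors_are_probabilities(self, structured):
        table, pca = structured
        model = dapc_train(pca.scores, table.pop_labels, n_pcs=4)
        post = model.posterior(pca.scores)
        assert np.all(post >= 0)
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_axes_capped_at_groups_minus_one(self, structured):
        table, pca = structured
        model = dapc_train(pca.scores, table.pop_labels, n_pcs=6, n_axes=5)
        assert model.n_axes == 2

    def test_tiny_group_rejected(self, structured):
        table, pca = structured
        groups = np.asarray(table.pop_labels).copy()
        groups[:] = "X"
        groups[0] = "lonely"
        with pytest.raises(ValueError, match="at least 2"):
            dapc_train(pca.scores, groups, n_pcs=3)


class TestNullAccuracy:
    def test_study_group_sizes_give_39_percent(self):
        assert round(100 * null_accuracy([24, 15, 8])) == 39

    def test_proportional_assignment_simulation_matches_analytic(self):
        """Drawing predicted labels from the empirical group proportions
        reproduces sum((n_i/N)^2) within 3 binomial SEs."""
        sizes = [24, 15, 8]
        n = sum(sizes)
        probs = np.array(sizes) / n
        truth = np.repeat(np.arange(3), sizes)
        rng = np.random.default_rng(40)
        n_rep = 300
        hits = sum(
            (rng.choice(3, size=n, p=probs) == truth).sum() for _ in range(n_rep)
        )
        total = n_rep * n
        p_exp = null_accuracy(sizes)
        se = np.sqrt(p_exp * (1 - p_exp) / total)
        assert abs(hits / total - p_exp) < 3 * se


class TestSelectNPcs:
    def test_separable_data_picks_small_plateau_value(self, structured):
        table, pca = structured
        n = select_n_pcs(pca.scores, table.pop_labels, mode="a_score", seed=1,
                         n_pcs_grid=[2, 4, 6, 8])
        assert n in (2, 4)  # plateau starts immediately; smallest tie wins

    def test_a_score_penalises_overfitting_on_noise(self, structured, unstructured):
        """The permutation-corrected reassignment score is large for real
        structure and hovers near zero for noise, however many PCs are
        retained — the property that stops n_pcs inflation."""
        from thermotrout.clustering import _a_score

        rng = np.random.default_rng(2)
        table_s, pca_s = structured
        table_n, pca_n = unstructured
        structured_score = _a_score(pca_s.scores, np.asarray(table_s.pop_labels), 4, 15, rng)
        noise_scores = [
            _a_score(pca_n.scores, np.asarray(table_n.pop_labels), k, 15, rng)
            for k in (10, 30)
        ]
        assert structured_score > 0.4
        assert all(s < structured_score - 0.2 for s in noise_scores)

    def test_reproducible_under_fixed_seed(self, structured):
        table, pca = structured
        a = select_n_pcs(pca.scores, table.pop_labels, seed=3, n_pcs_grid=[2, 4, 6])
        b = select_n_pcs(pca.scores, table.pop_labels, seed=3, n_pcs_grid=[2, 4, 6])
        assert a == b


class TestCrossValidation:
    def test_separable_data_near_perfect_holdout(self, structured):
        table, pca = structured
        res = dapc_crossvalidate(
            pca.scores, table.pop_labels, n_pcs=4, n_repeats=40, seed=4
        )
        assert res.overall_accuracy > 0.95

    def test_per_group_and_overall_consistent(self, structured):
        table, pca = structured
        res = dapc_crossvalidate(
            pca.scores, table.pop_labels, n_pcs=4, n_repeats=20, seed=5
        )
        assert set(res.per_group_accuracy) == set(np.unique(table.pop_labels))
        assert 0 <= res.overall_accuracy <= 1


def brute_force_min_wss(X, k):
    """Exhaustive minimum within-cluster sum of squares over all partitions."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        wss = sum(
            ((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
        best = min(best, wss)
    return best


class TestKMeansBIC:
    def test_wss_and_bic_match_brute_force_on_toy(self):
        """Best-of-repeats k-means attains the exhaustive-minimum WSS on a
        10-point toy, and BIC equals its defining formula."""
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(0, 0.5, (5, 8)), rng.normal(6, 0.5, (5, 8))]
        )
        sols = kmeans_bic(X, k_range=[2], n_repeats=10, seed=7)
        k2 = sols[0]
        assert k2.wss == pytest.approx(brute_force_min_wss(X, 2), rel=1e-9)
        n = len(X)
        assert k2.bic == pytest.approx(n * np.log(k2.wss / n) + 2 * np.log(n))

    def test_two_diverged_populations_select_k2(self):
        """On genotype-scale data (many PC dimensions, tens of fish) the
        BIC minimum sits at the true number of populations."""
        ks = []
        for rep in range(5):
            cfg = synth.GeneratorConfig(
                seed=400 + rep, target_fst=0.35,
                genotype_n_per_stream={"A": 24, "B": 23},
            )
            table = synth.generate_genotypes(cfg)
            _, pca = encode_and_pca(table)
            sols = kmeans_bic(pca.scores, k_range=range(1, 5), n_repeats=10, seed=rep)
            ks.append(best_k(sols).k)
        assert sum(k == 2 for k in ks) >= 4

    def test_undifferentiated_genotypes_prefer_k1(self):
        wins = 0
        for rep in range(5):
            cfg = synth.GeneratorConfig(
                seed=500 + rep, target_fst=0.0,
                genotype_n_per_stream={"A": 24, "B": 23},
            )
            table = synth.generate_genotypes(cfg)
            _, pca = encode_and_pca(table)
            sols = kmeans_bic(pca.scores, k_range=range(1, 5), n_repeats=10, seed=rep)
            if best_k(sols).k == 1:
                wins += 1
        assert wins >= 4

    def test_stability_one_when_repeats_agree(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(9, 0.1, (6, 2))])
        sols = kmeans_bic(X, k_range=[2], n_repeats=15, seed=9)
        assert sols[0].repeat_stability == 1.0

    def test_best_of_repeats_never_worse_than_single(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (40, 4))
        many = kmeans_bic(X, k_range=[4], n_repeats=15, seed=11)[0]
        one = kmeans_bic(X, k_range=[4], n_repeats=1, seed=12)[0]
        assert many.wss <= one.wss + 1e-9
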