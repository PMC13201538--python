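"""Differentiation statistics against independent oracles and known limits."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_table
from thermotrout import popgen, synth


# ---------------------------------------------------------------------------
# independent theta oracle: nested random-effects ANOVA on allele indicators


def theta_anova_oracle(table, pop_pair):
    """Brute-force variance components from sums of squares on the 0/1
    allele-indicator array (populations / individuals / gene copies), the
    moment estimators the frequency-based formulas must reproduce."""
    num = den = 0.0
    for li in range(len(table.loci)):
        pops_g = []
        for pop in pop_pair:
            g = table.genotypes[table.pop_labels == pop, li]
            pops_g.append(g[g[:, 0] != popgen.MISSING])
        alleles = sorted(set(np.concatenate(pops_g).ravel().tolist()))
        if len(alleles) < 2:
            continue
        n = np.array([len(g) for g in pops_g], dtype=float)
        r = len(n)
        N = n.sum()
        nc = (N - (n**2).sum() / N) / (r - 1)
        for a in alleles:
            x = [(g == a).astype(float) for g in pops_g]  # (n_i, 2) indicators
            p_i = np.array([xi.mean() for xi in x])
            pbar = sum(xi.sum() for xi in x) / (2 * N)
            ssp = float(sum(2 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_i)))
            ssi = float(
                sum(2 * ((xi.mean(axis=1) - xi.mean()) ** 2).sum() for xi in x)
            )
            ssg = float(
                sum(((xi - xi.mean(axis=1, keepdims=True)) ** 2).sum() for xi in x)
            )
            msp = ssp / (r - 1)
            msi = ssi / (N - r)
            msg = ssg / N
            sig_g = msg
            sig_i = (msi - msg) / 2
            sig_p = (msp - msi) / (2 * nc)
            num += sig_p
            den += sig_p + sig_i + sig_g
    return num / den


def random_table(seed, n_pops=2, n_ind=12, n_loci=3, n_alleles=4, missing=0.0):
    rng = np.random.default_rng(seed)
    geno = rng.integers(1, n_alleles + 1, size=(n_pops * n_ind, n_loci, 2))
    if missing:
        drop = rng.random((n_pops * n_ind, n_loci)) < missing
        geno[drop] = popgen.MISSING
    labels = np.repeat([f"P{i}" for i in range(n_pops)], n_ind).astype(object)
    inds = [f"I{i}" for i in range(n_pops * n_ind)]
    return popgen.GenotypeTable(inds, [f"L{j}" for j in range(n_loci)], geno, labels)


class TestAlleleStats:
    def test_hand_counted_frequencies(self):
        table = make_table({"A": [[(1, 1)], [(1, 2)]]})
        (st,) = popgen.allele_stats(table)
        assert st.freqs == {1: 0.75, 2: 0.25}
        assert st.ho == 0.5
        assert st.he == pytest.approx(1 - 0.75**2 - 0.25**2)  # 0.375

    def test_monomorphic_locus_has_zero_diversity(self):
        table = make_table({"A": [[(1, 1)], [(1, 1)]]})
        (st,) = popgen.allele_stats(table)
        assert st.ho == 0.0 and st.he == 0.0

    def test_missing_reduces_n_not_normalisation(self):
        table = make_table({"A": [[(1, 1)], [(-1, -1)], [(1, 2)]]})
        (st,) = popgen.allele_stats(table)
        assert st.n == 2
        assert sum(st.freqs.values()) == pytest.approx(1.0)


class TestWeirCockerhamTheta:
    def test_fixed_different_alleles_gives_one(self, diverged_table):
        res = popgen.weir_cockerham_theta(diverged_table, ("A", "B"))
        assert res.estimate == pytest.approx(1.0)

    def test_identical_hwe_populations_near_zero(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(1, 5, size=(400, 5, 2))
        labels = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        table = popgen.GenotypeTable(
            [f"I{i}" for i in range(400)], [f"L{j}" for j in range(5)], geno, labels
        )
        res = popgen.weir_cockerham_theta(table, ("A", "B"))
        assert abs(res.estimate) < 0.01

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_anova_oracle_on_random_toys(self, seed):
        table = random_table(seed, n_ind=6 + seed, n_loci=3, missing=0.1 if seed % 2 else 0.0)
        res = popgen.weir_cockerham_theta(table, ("P0", "P1"))
        assert res.estimate == pytest.approx(
            theta_anova_oracle(table, ("P0", "P1")), abs=1e-12
        )

    def test_fixed_same_allele_locus_excluded(self):
        table = make_table(
            {
                "A": [[(1, 1), (1, 2)], [(1, 1), (2, 2)]],
                "B": [[(1, 1), (1, 1)], [(1, 1), (1, 2)]],
            },
            loci=["Fixed", "Poly"],
        )
        res = popgen.weir_cockerham_theta(table, ("A", "B"))
        assert res.loci_excluded == ["Fixed"]
        assert res.loci_used == ["Poly"]

    def test_invariant_to_allele_relabelling_and_order(self):
        table = random_table(3, n_ind=10)
        res = popgen.weir_cockerham_theta(table, ("P0", "P1"))
        # relabel alleles 1..4 -> 11..14 and shuffle individuals
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.n_individuals)
        relabelled = popgen.GenotypeTable(
            [table.individuals[i] for i in perm],
            list(table.loci),
            table.genotypes[perm] + 10,
            table.pop_labels[perm],
        )
        res2 = popgen.weir_cockerham_theta(relabelled, ("P0", "P1"))
        assert res2.estimate == pytest.approx(res.estimate, abs=1e-14)


class TestJostDest:
    def test_identical_frequencies_near_zero(self):
        table = make_table(
            {
                "A": [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]] * 5,
                "B": [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]] * 5,
            }
        )
        res = popgen.jost_dest(table, ("A", "B"))
        assert abs(res.estimate) < 0.05

    def test_non_overlapping_alleles_approach_one(self):
        table = make_table(
            {
                "A": [[(1, 2)]] * 10,
                "B": [[(3, 4)]] * 10,
            }
        )
        res = popgen.jost_dest(table, ("A", "B"))
        assert res.estimate > 0.95

    def test_matches_hand_computed_nei_chesser_chain(self):
        # pop A: 1/1, 1/2, 2/2 ; pop B: 1/1, 1/1, 1/2  (one locus)
        table = make_table(
            {"A": [[(1, 1)], [(1, 2)], [(2, 2)]], "B": [[(1, 1)], [(1, 1)], [(1, 2)]]}
        )
        # spreadsheet chain
        nA = nB = 3
        pA, pB = np.array([0.5, 0.5]), np.array([5 / 6, 1 / 6])
        hoA, hoB = 1 / 3, 1 / 3
        n_harm = 2 / (1 / nA + 1 / nB)
        ho_bar = (hoA + hoB) / 2
        hs_raw = ((1 - (pA**2).sum()) + (1 - (pB**2).sum())) / 2
        hs = n_harm / (n_harm - 1) * (hs_raw - ho_bar / (2 * n_harm))
        pbar = (pA + pB) / 2
        ht = (1 - (pbar**2).sum()) + hs / (2 * n_harm) - ho_bar / (4 * n_harm)
        d_hand = (ht - hs) / (1 - hs) * 2
        res = popgen.jost_dest(table, ("A", "B"))
        assert res.estimate == pytest.approx(d_hand, abs=1e-12)


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, diverged_table):
        ci1 = popgen.bootstrap_ci(diverged_table, ("A", "B"), "theta", 120, seed=5)
        ci2 = popgen.bootstrap_ci(diverged_table, ("A", "B"), "theta", 120, seed=5)
        assert ci1 == ci2

    def test_diverged_populations_ci_excludes_zero(self):
        cfg = synth.GeneratorConfig(seed=9, target_fst=0.25,
                                    genotype_n_per_stream={"A": 20, "B": 20})
        table = synth.generate_genotypes(cfg)
        lo, hi = popgen.bootstrap_ci(table, ("A", "B"), "theta", 200, seed=1)
        assert lo > 0

    def test_same_pool_split_straddles_zero(self):
        """Halves of one panmictic pool: CI covers 0 and the lower bound
        dips slightly negative — the unbiased estimator's signature."""
        rng = np.random.default_rng(4)
        geno = rng.integers(1, 7, size=(60, 20, 2))
        labels = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        table = popgen.GenotypeTable(
            [f"I{i}" for i in range(60)], [f"L{j}" for j in range(20)], geno, labels
        )
        lo, hi = popgen.bootstrap_ci(table, ("A", "B"), "theta", 300, seed=2)
        assert lo < 0 < hi

    def test_locus_resampling_mode_runs(self, diverged_table):
        lo, hi = popgen.bootstrap_ci(
            diverged_table, ("A", "B"), "theta", 120, seed=3, resample="loci"
        )
        assert lo <= hi


def enumerate_2x2_p(tab):
    """Full-enumeration exact probability test for a 2x2 table."""
    r1, r2 = tab.sum(axis=1)
    c1 = tab[:, 0].sum()
    n = tab.sum()
    obs = stats.hypergeom.pmf(tab[0, 0], n, r1, c1)
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pm = stats.hypergeom.pmf(xs, n, r1, c1)
    return float(pm[pm <= obs * (1 + 1e-9)].sum())


class TestExactGenicTest:
    @pytest.mark.parametrize(
        "tab",
        [
            np.array([[12, 8], [5, 15]]),
            np.array([[30, 10], [22, 18]]),
            np.array([[4, 16], [14, 6]]),
        ],
    )
    def test_mcmc_matches_enumeration_on_2x2(self, tab):
        p_true = enumerate_2x2_p(tab)
        p_mc, se = popgen.exact_test_mcmc(
            tab, dememorisation=2000, batches=20, iter_per_batch=2000,
            rng=np.random.default_rng(8),
        )
        assert abs(p_mc - p_true) < max(4 * se, 0.02)

    def test_longer_chains_reduce_error(self):
        tab = np.array([[12, 8], [5, 15]])
        p_true = enumerate_2x2_p(tab)
        errs = []
        for iters in (200, 5000):
            reps = [
                abs(
                    popgen.exact_test_mcmc(
                        tab, 500, 10, iters, rng=np.random.default_rng(100 + k)
                    )[0]
                    - p_true
                )
                for k in range(5)
            ]
            errs.append(np.mean(reps))
        assert errs[1] < errs[0]

    def test_identical_populations_give_large_p(self):
        rng = np.random.default_rng(11)
        geno = rng.integers(1, 4, size=(60, 4, 2))
        labels = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        table = popgen.GenotypeTable(
            [f"I{i}" for i in range(60)], [f"L{j}" for j in range(4)], geno, labels
        )
        res = popgen.exact_genic_test(
            table, ("A", "B"), dememorisation=500, batches=10, iter_per_batch=500,
            seed=12,
        )
        assert res.p_combined > 0.05

    def test_df_shrinks_when_locus_monomorphic(self):
        cfg = synth.GeneratorConfig(
            seed=13, genotype_n_per_stream={"A": 10, "B": 10}, n_loci=17,
            force_monomorphic_locus=4,
        )
        table = synth.generate_genotypes(cfg)
        res = popgen.exact_genic_test(
            table, ("A", "B"), dememorisation=100, batches=5, iter_per_batch=100,
            seed=14,
        )
        assert res.df == 32
        assert res.loci_skipped == ["Loc05"]


class TestPooling:
    def test_merge_two_warm_streams(self):
        cfg = synth.GeneratorConfig(seed=15)
        table = synth.generate_genotypes(cfg)
        pooled = popgen.pool_populations(table, {"IS1": "warm", "IS5": "warm"})
        assert set(pooled.populations) == {"IS12", "warm"}
        assert int((pooled.pop_labels == "warm").sum()) == 15 + 8

    def test_identity_map_changes_nothing(self):
        table = random_table(16)
        out = popgen.pool_populations(table, {})
        assert out.populations == table.populations
        np.testing.assert_array_equal(out.genotypes, table.genotypes)

    def test_merging_everything_breaks_pairwise_stats(self):
        table = random_table(17)
        merged = popgen.pool_populations(table, {"P0": "all", "P1": "all"})
        with pytest.raises(Exception):
            popgen.weir_cockerham_theta(merged, ("all", "missing"))

    def test_unknown_label_rejected(self):
        table = random_table(18)
        with pytest.raises(ValueError, match="not present"):
            popgen.pool_populations(table, {"nope": "x"})
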