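"""Genetic differentiation among populations from microsatellite genotypes.

Implements the estimators used to compare allele frequencies among stream
populations:

* Weir & Cockerham's theta, the variance-component estimator of Wright's
  F_ST, from components among populations (a), among individuals within
  populations (b) and within individuals (c), combined across alleles and
  loci as a ratio of sums;
* Jost's D_EST from Nei-Chesser bias-corrected heterozygosities,
  D = (H_T - H_S) / (1 - H_S) * r / (r - 1) for r populations;
* bias-corrected bootstrap confidence intervals, resampling individuals
  within populations (optionally loci);
* the exact conditional contingency-table ("genic") test of allele-
  frequency homogeneity, evaluated by a Markov chain over allele-count
  tables with fixed margins and combined across loci by Fisher's method.

Loci fixed for the same allele in both populations of a pairwise
comparison carry no information and are excluded (and reported).
Missing genotypes are dropped locus-wise, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MISSING = -1


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes with population labels.

    ``genotypes`` has shape (n_individuals, n_loci, 2) of integer allele
    labels, with both entries ``-1`` for a missing genotype.
    """

    individuals: list[str]
    loci: list[str]
    genotypes: np.ndarray
    pop_labels: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        n, L, two = self.genotypes.shape
        if two != 2 or n != len(self.individuals) or L != len(self.loci):
            raise ValueError("genotype array shape mismatch")
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("genotypes must have 0 or 2 alleles recorded")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def subset_pops(self, pops: list[str]) -> "GenotypeTable":
        mask = np.isin(self.pop_labels, pops)
        return GenotypeTable(
            [ind for ind, m in zip(self.individuals, mask) if m],
            list(self.loci),
            self.genotypes[mask],
            self.pop_labels[mask],
        )

    def allele_counts(self, locus_idx: int, pop: str) -> dict[int, int]:
        """Allele label -> count among non-missing genotypes of one pop."""
        g = self.genotypes[self.pop_labels == pop, locus_idx]
        g = g[g[:, 0] != MISSING]
        labels, counts = np.unique(g.ravel(), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def pool_populations(table: GenotypeTable, merge_map: dict[str, str]) -> GenotypeTable:
    """Relabel populations, e.g. {'IS1': 'warm', 'IS5': 'warm'}.

    Labels absent from the map are kept. Every merged label must exist.
    """
    missing = set(merge_map) - set(table.populations)
    if missing:
        raise ValueError(f"labels not present in table: {sorted(missing)}")
    new_labels = np.array(
        [merge_map.get(p, p) for p in table.pop_labels], dtype=object
    )
    return GenotypeTable(
        list(table.individuals), list(table.loci), table.genotypes.copy(), new_labels
    )


# ---------------------------------------------------------------------------
# descriptive statistics


@dataclass
class LocusStats:
    locus: str
    pop: str
    n: int  # individuals with a genotype
    freqs: dict[int, float]
    ho: float
    he: float


def allele_stats(table: GenotypeTable, pops: list[str] | None = None) -> list[LocusStats]:
    """Per locus x population allele frequencies, Ho, He and sample sizes.

    He is the unbiased-free Nei gene diversity 1 - sum p^2; Ho the observed
    heterozygote fraction. Loci with no data in a population are skipped.
    """
    pops = pops if pops is not None else table.populations
    out: list[LocusStats] = []
    for li, locus in enumerate(table.loci):
        for pop in pops:
            g = table.genotypes[table.pop_labels == pop, li]
            g = g[g[:, 0] != MISSING]
            if len(g) == 0:
                continue
            counts = np.unique(g.ravel(), return_counts=True)
            total = counts[1].sum()
            freqs = {int(a): c / total for a, c in zip(*counts)}
            ho = float(np.mean(g[:, 0] != g[:, 1]))
            he = 1.0 - sum(p * p for p in freqs.values())
            out.append(LocusStats(locus, pop, len(g), freqs, ho, he))
    return out


@dataclass
class DiffResult:
    statistic: str
    estimate: float
    per_locus: dict[str, float] = field(default_factory=dict)
    loci_used: list[str] = field(default_factory=list)
    loci_excluded: list[str] = field(default_factory=list)
    ci_low_5pct: float | None = None
    ci_high_95pct: float | None = None


def _pair_locus_data(table: GenotypeTable, pop_pair: tuple[str, str], locus_idx: int):
    """Per-pop (n, allele freqs, het freqs per allele) for one locus, or None."""
    alleles = sorted(
        set(table.allele_counts(locus_idx, pop_pair[0]))
        | set(table.allele_counts(locus_idx, pop_pair[1]))
    )
    data = []
    for pop in pop_pair:
        g = table.genotypes[table.pop_labels == pop, locus_idx]
        g = g[g[:, 0] != MISSING]
        if len(g) == 0:
            return None
        n = len(g)
        p = np.array([np.mean(g == a) for a in alleles])  # mean over 2n slots
        het = np.array(
            [np.mean((g[:, 0] == a) ^ (g[:, 1] == a)) for a in alleles]
        )
        data.append((n, p, het))
    if len(alleles) < 2:
        return None  # fixed for the same allele in both populations
    return alleles, data


def _wc_components(n: np.ndarray, p: np.ndarray, het: np.ndarray):
    """Weir-Cockerham variance components (a, b, c) for one allele.

    ``n``: per-population sample sizes (individuals); ``p``: allele
    frequencies; ``het``: observed frequency of heterozygotes carrying the
    allele. Returns the among-population, among-individual and
    within-individual components of allelic variance.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * het).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def weir_cockerham_theta(table: GenotypeTable, pop_pair: tuple[str, str]) -> DiffResult:
    """Multi-locus Weir-Cockerham theta for one pair of populations.

    Per-locus theta is sum(a) / sum(a+b+c) over alleles; the multi-locus
    estimate is the ratio of sums over loci (not the mean of ratios).
    Negative estimates are retained — they signal sampling noise around
    zero differentiation, not an error.
    """
    for pop in pop_pair:
        if int((table.pop_labels == pop).sum()) < 2:
            raise ValueError(f"population {pop!r} needs at least 2 individuals")
    per_locus, used, excluded = {}, [], []
    num_total = den_total = 0.0
    for li, locus in enumerate(table.loci):
        pair = _pair_locus_data(table, pop_pair, li)
        if pair is None:
            excluded.append(locus)
            continue
        _, data = pair
        n = np.array([d[0] for d in data], dtype=float)
        num = den = 0.0
        for ai in range(len(pair[0])):
            p = np.array([d[1][ai] for d in data])
            het = np.array([d[2][ai] for d in data])
            a, b, c = _wc_components(n, p, het)
            num += a
            den += a + b + c
        if den == 0:
            excluded.append(locus)
            continue
        per_locus[locus] = num / den
        used.append(locus)
        num_total += num
        den_total += den
    if den_total == 0:
        raise ValueError("no usable (polymorphic) loci for this pair")
    return DiffResult(
        statistic="theta",
        estimate=num_total / den_total,
        per_locus=per_locus,
        loci_used=used,
        loci_excluded=excluded,
    )


def _nei_chesser(n: np.ndarray, freqs: np.ndarray, ho: np.ndarray):
    """Bias-corrected H_S and H_T (Nei-Chesser) for one locus.

    ``freqs``: (r, n_alleles) frequencies; ``ho``: per-pop observed
    heterozygosity; ``n``: individuals per pop. Uses the harmonic mean
    sample size and unweighted frequency averages, the convention for
    unbalanced samples.
    """
    r = len(n)
    n_harm = r / (1.0 / n).sum()
    ho_bar = ho.mean()
    hs_raw = (1 - (freqs**2).sum(axis=1)).mean()
    hs = n_harm / (n_harm - 1) * (hs_raw - ho_bar / (2 * n_harm))
    pbar = freqs.mean(axis=0)
    ht_raw = 1 - (pbar**2).sum()
    ht = ht_raw + hs / (n_harm * r) - ho_bar / (2 * n_harm * r)
    return hs, ht


def jost_dest(table: GenotypeTable, pop_pair: tuple[str, str]) -> DiffResult:
    """Jost's D_EST for one pair of populations.

    Per-locus D = (H_T - H_S)/(1 - H_S) * r/(r-1) with Nei-Chesser
    bias-corrected heterozygosities. The multi-locus estimate applies the
    same formula to the across-locus means of H_T and H_S — robust to the
    negative per-locus values that weak differentiation produces.
    """
    per_locus, used, excluded = {}, [], []
    hs_list, ht_list = [], []
    r = len(pop_pair)
    for li, locus in enumerate(table.loci):
        pair = _pair_locus_data(table, pop_pair, li)
        if pair is None:
            excluded.append(locus)
            continue
        alleles, data = pair
        n = np.array([d[0] for d in data], dtype=float)
        freqs = np.array([d[1] for d in data])
        ho = np.array([d[2].sum() for d in data])  # het fraction = sum over alleles / 2... see below
        # each heterozygote contributes to exactly 2 allele-specific het freqs
        ho = ho / 2.0
        hs, ht = _nei_chesser(n, freqs, ho)
        if hs >= 1.0:
            excluded.append(locus)
            continue
        per_locus[locus] = (ht - hs) / (1 - hs) * r / (r - 1)
        used.append(locus)
        hs_list.append(hs)
        ht_list.append(ht)
    if not used:
        raise ValueError("no usable (polymorphic) loci for this pair")
    hs_bar, ht_bar = float(np.mean(hs_list)), float(np.mean(ht_list))
    overall = (ht_bar - hs_bar) / (1 - hs_bar) * r / (r - 1)
    return DiffResult(
        statistic="d_est",
        estimate=overall,
        per_locus=per_locus,
        loci_used=used,
        loci_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# bootstrap confidence intervals

_STATISTICS = {"theta": weir_cockerham_theta, "d_est": jost_dest}


def bootstrap_ci(
    table: GenotypeTable,
    pop_pair: tuple[str, str],
    statistic: str = "theta",
    n_boot: int = 10_000,
    seed: int | None = None,
    resample: str = "individuals",
) -> tuple[float, float]:
    """Bias-corrected bootstrap 5%/95% bounds on theta or D_EST.

    Resamples individuals with replacement within each population
    (``resample='loci'`` resamples loci instead). Resampling individuals
    inflates apparent between-population differences, so the bootstrap
    distribution sits above the point estimate near zero differentiation;
    the interval is therefore the percentile bounds shifted down by the
    bootstrap bias (mean of replicates minus the estimate). Degenerate
    replicates (no polymorphic locus) are skipped and counted.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    stat_fn = _STATISTICS[statistic]
    rng = np.random.default_rng(seed)
    observed = stat_fn(table, pop_pair).estimate

    sub = table.subset_pops(list(pop_pair))
    values = []
    n_degenerate = 0
    pop_indices = {p: np.flatnonzero(sub.pop_labels == p) for p in pop_pair}
    for _ in range(n_boot):
        if resample == "individuals":
            idx = np.concatenate(
                [rng.choice(pop_indices[p], size=len(pop_indices[p])) for p in pop_pair]
            )
            boot = GenotypeTable(
                [sub.individuals[i] for i in idx],
                list(sub.loci),
                sub.genotypes[idx],
                sub.pop_labels[idx],
            )
        elif resample == "loci":
            lidx = rng.integers(0, len(sub.loci), size=len(sub.loci))
            boot = GenotypeTable(
                list(sub.individuals),
                [f"{sub.loci[j]}_{k}" for k, j in enumerate(lidx)],
                sub.genotypes[:, lidx],
                sub.pop_labels,
            )
        else:
            raise ValueError("resample must be 'individuals' or 'loci'")
        try:
            values.append(stat_fn(boot, pop_pair).estimate)
        except ValueError:
            n_degenerate += 1
    values = np.asarray(values)
    if len(values) == 0:
        raise ValueError("all bootstrap replicates degenerate")
    bias = float(values.mean()) - observed
    return (
        float(np.quantile(values, 0.05)) - bias,
        float(np.quantile(values, 0.95)) - bias,
    )


def differentiation_with_ci(
    table: GenotypeTable,
    pop_pair: tuple[str, str],
    statistic: str = "theta",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DiffResult:
    """Point estimate plus bias-corrected bootstrap interval."""
    res = _STATISTICS[statistic](table, pop_pair)
    lo, hi = bootstrap_ci(table, pop_pair, statistic, n_boot=n_boot, seed=seed)
    res.ci_low_5pct, res.ci_high_95pct = lo, hi
    return res


# ---------------------------------------------------------------------------
# exact genic differentiation test


@dataclass
class ExactTestResult:
    per_locus_p: dict[str, float]
    chi2: float
    df: int
    p_combined: float
    loci_skipped: list[str] = field(default_factory=list)


def _table_logprob(tab: np.ndarray) -> float:
    """Log multiple-hypergeometric probability of a table, up to the
    margin-dependent constant: -sum(lgamma(n_ij + 1))."""
    return -float(sum(math.lgamma(v + 1) for v in tab.ravel()))


def exact_test_mcmc(
    observed: np.ndarray,
    dememorisation: int = 10_000,
    batches: int = 100,
    iter_per_batch: int = 5_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Exact probability test on one contingency table by Markov chain.

    Runs a Metropolis walk over non-negative integer tables with the
    observed margins, whose stationary law is the multiple hypergeometric
    (the null of allele-frequency homogeneity). The p-value is the chain
    frequency of tables no more probable than the observed one; the
    standard error comes from the variance of per-batch estimates.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tab = np.array(observed, dtype=int)
    r, c = tab.shape
    if r < 2 or c < 2:
        raise ValueError("table must be at least 2x2")
    log_obs = _table_logprob(tab) + 1e-9  # tolerance for float ties
    lgam = [math.lgamma(v + 1) for v in range(int(tab.sum()) + 2)]

    current = _table_logprob(tab)
    cells = tab.copy()
    # pre-draw proposals in blocks for speed
    total_steps = dememorisation + batches * iter_per_batch
    batch_hits = np.zeros(batches)
    step = 0
    block = 65536
    while step < total_steps:
        m = min(block, total_steps - step)
        rows = rng.integers(0, r, size=(m, 2))
        cols = rng.integers(0, c, size=(m, 2))
        us = rng.random(m)
        for i in range(m):
            i1, i2 = rows[i]
            j1, j2 = cols[i]
            if i1 != i2 and j1 != j2 and cells[i1, j2] > 0 and cells[i2, j1] > 0:
                a, b_, cc, d = (
                    cells[i1, j1],
                    cells[i1, j2],
                    cells[i2, j1],
                    cells[i2, j2],
                )
                delta = (
                    lgam[a] + lgam[b_] + lgam[cc] + lgam[d]
                    - lgam[a + 1] - lgam[b_ - 1] - lgam[cc - 1] - lgam[d + 1]
                )
                if delta >= 0 or us[i] < math.exp(delta):
                    cells[i1, j1] = a + 1
                    cells[i1, j2] = b_ - 1
                    cells[i2, j1] = cc - 1
                    cells[i2, j2] = d + 1
                    current += delta
            k = step + i
            if k >= dememorisation:
                b_idx = (k - dememorisation) // iter_per_batch
                if current <= log_obs:
                    batch_hits[b_idx] += 1
        step += m
    batch_p = batch_hits / iter_per_batch
    p = float(batch_p.mean())
    se = float(batch_p.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return p, se


def exact_genic_test(
    table: GenotypeTable,
    pop_pair: tuple[str, str],
    dememorisation: int = 10_000,
    batches: int = 100,
    iter_per_batch: int = 5_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Per-locus exact genic tests combined across loci by Fisher's method.

    Each usable locus contributes a populations x alleles table of allele
    counts; monomorphic loci are skipped and the combined chi-square
    degrees of freedom (2 per usable locus) shrink accordingly.
    """
    rng = np.random.default_rng(seed)
    per_locus_p, skipped = {}, []
    for li, locus in enumerate(table.loci):
        counts = [table.allele_counts(li, pop) for pop in pop_pair]
        alleles = sorted(set().union(*counts))
        if len(alleles) < 2 or any(not c for c in counts):
            skipped.append(locus)
            continue
        tab = np.array([[c.get(a, 0) for a in alleles] for c in counts])
        p, _ = exact_test_mcmc(
            tab, dememorisation, batches, iter_per_batch, rng=rng
        )
        per_locus_p[locus] = p
    if not per_locus_p:
        raise ValueError("no polymorphic locus to test")
    # Fisher's combination; p=0 from a finite chain is floored at 1/n_iter
    floor = 1.0 / (batches * iter_per_batch)
    chi2 = -2.0 * sum(math.log(max(p, floor)) for p in per_locus_p.values())
    df = 2 * len(per_locus_p)
    return ExactTestResult(
        per_locus_p=per_locus_p,
        chi2=chi2,
        df=df,
        p_combined=float(stats.chi2.sf(chi2, df)),
        loci_skipped=skipped,
    )
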