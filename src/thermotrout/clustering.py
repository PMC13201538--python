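"""Genotype-based clustering and population assignment.

Genotypes are encoded as per-allele dosages (0/1/2 copies per
locus:allele column), mean-imputed where missing, centred but not scaled,
and decomposed by PCA. On the retained principal components:

* DAPC — linear discriminant axes that maximise between-group relative to
  within-group variance, with posterior group membership under the
  Gaussian equal-covariance rule. The number of PCs to retain is chosen by
  the a-score (reassignment success minus its permutation expectation,
  which penalises overfitting) and/or repeated hold-out cross-validation,
  keeping the larger of the two optima.
* blind k-means over a range of k with repeated random starts, scored by
  BIC = n*ln(WSS/n) + k*ln(n), with repeat stability tracked as the
  fraction of repeats reproducing the best partition.

With no real structure, the expected assignment accuracy of proportional
guessing is sum((n_i/N)^2) — the null baseline every accuracy should be
read against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .popgen import MISSING, GenotypeTable


@dataclass
class AlleleCountMatrix:
    """Individuals x allele-columns dosage matrix with its centring vector."""

    matrix: np.ndarray
    column_labels: list[str]
    centre: np.ndarray
    imputed_fraction: float


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray

    def n_pcs_for_variance(self, target: float = 0.95) -> int:
        """Smallest PC count whose cumulative variance fraction reaches target."""
        cum = np.cumsum(self.variance_fractions)
        return int(np.searchsorted(cum, target - 1e-12) + 1)


def encode_alleles(table: GenotypeTable) -> AlleleCountMatrix:
    """Per-allele dosage encoding with mean imputation of missing genotypes."""
    cols, labels = [], []
    n_missing = 0
    for li, locus in enumerate(table.loci):
        g = table.genotypes[:, li]
        present = g[:, 0] != MISSING
        n_missing += int((~present).sum())
        alleles = np.unique(g[present])
        for a in alleles:
            dosage = (g == a).sum(axis=1).astype(float)
            if (~present).any():
                dosage[~present] = dosage[present].mean()
            cols.append(dosage)
            labels.append(f"{locus}:{int(a)}")
    X = np.column_stack(cols)
    centre = X.mean(axis=0)
    frac = n_missing / (table.n_individuals * len(table.loci))
    return AlleleCountMatrix(X, labels, centre, frac)


def encode_and_pca(table: GenotypeTable) -> tuple[AlleleCountMatrix, PCAResult]:
    """Centred, unscaled PCA of the allele-dosage matrix.

    Deterministic up to sign; the convention fixed here makes the largest-
    magnitude loading of each axis positive. Variance fractions sum to 1
    over all non-trivial axes.
    """
    acm = encode_alleles(table)
    Xc = acm.matrix - acm.centre
    if not np.any(Xc):
        raise ValueError("zero-variance genotype matrix; nothing to decompose")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-10
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # sign convention
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2
    return acm, PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_fractions=var / var.sum(),
    )


def null_accuracy(group_sizes) -> float:
    """Expected accuracy of proportional random assignment, sum((n_i/N)^2)."""
    n = np.asarray(group_sizes, dtype=float)
    return float(((n / n.sum()) ** 2).sum())


def simulate_null_accuracy(group_sizes, n_repeats: int = 300, seed: int | None = None):
    """Monte-Carlo check of the proportional-assignment null.

    Each repeat assigns every individual a predicted group drawn from the
    empirical group proportions and scores it against the true membership.
    Returns (mean accuracy, total predictions made).
    """
    sizes = np.asarray(group_sizes, dtype=int)
    n = int(sizes.sum())
    probs = sizes / n
    truth = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    hits = sum(
        int((rng.choice(len(sizes), size=n, p=probs) == truth).sum())
        for _ in range(n_repeats)
    )
    return hits / (n_repeats * n), n_repeats * n


def pooled_accuracy(per_group: dict) -> float:
    """Overall accuracy from per-group (n_correct, n_total) pairs."""
    correct = sum(c for c, _ in per_group.values())
    total = sum(t for _, t in per_group.values())
    return correct / total


@dataclass
class DAPCModel:
    retained_pcs: int
    lda: LinearDiscriminantAnalysis
    groups: np.ndarray
    training_accuracy: dict[str, float]
    overall_training_accuracy: float

    @property
    def n_axes(self) -> int:
        return self.lda.scalings_.shape[1]

    def discriminant_scores(self, scores: np.ndarray) -> np.ndarray:
        return self.lda.transform(scores[:, : self.retained_pcs])

    def posterior(self, scores: np.ndarray) -> np.ndarray:
        """Posterior group membership probabilities (rows sum to 1)."""
        return self.lda.predict_proba(scores[:, : self.retained_pcs])

    def assign(self, scores: np.ndarray) -> np.ndarray:
        return self.lda.predict(scores[:, : self.retained_pcs])


def dapc_train(
    scores: np.ndarray,
    groups,
    n_pcs: int,
    n_axes: int = 2,
) -> DAPCModel:
    """Fit discriminant axes on the first ``n_pcs`` PC scores.

    ``n_axes`` is capped at groups - 1. Posteriors follow the Gaussian
    equal-covariance (LDA) rule. A singular within-group covariance —
    typically from retaining too many PCs for the sample size — is
    reported with that advice.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    if n_pcs < len(labels) - 1:
        raise ValueError("retain at least groups-1 PCs")
    n_axes = min(n_axes, len(labels) - 1)
    X = scores[:, :n_pcs]
    lda = LinearDiscriminantAnalysis(
        solver="svd", n_components=n_axes, tol=1e-8
    )
    try:
        lda.fit(X, groups)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(
            "singular within-group covariance; retain fewer PCs"
        ) from err
    pred = lda.predict(X)
    per_group = {
        str(lab): float(np.mean(pred[groups == lab] == lab)) for lab in labels
    }
    return DAPCModel(
        retained_pcs=n_pcs,
        lda=lda,
        groups=groups,
        training_accuracy=per_group,
        overall_training_accuracy=float(np.mean(pred == groups)),
    )


def _a_score(scores, groups, n_pcs, n_perm, rng) -> float:
    """Reassignment success minus its expectation under permuted labels."""
    model = dapc_train(scores, groups, n_pcs)
    observed = model.overall_training_accuracy
    null = []
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        null.append(
            dapc_train(scores, perm, n_pcs).overall_training_accuracy
        )
    return observed - float(np.mean(null))


def _xval_accuracy(scores, groups, n_pcs, n_repeats, holdout_fraction, rng) -> float:
    accs = []
    for _ in range(n_repeats):
        train_idx, test_idx = _holdout_split(groups, holdout_fraction, rng)
        model = dapc_train(scores[train_idx], groups[train_idx], n_pcs)
        accs.append(float(np.mean(model.assign(scores[test_idx]) == groups[test_idx])))
    return float(np.mean(accs))


def _holdout_split(groups, holdout_fraction, rng):
    """Remove ceil(fraction * n_g) (>=1) members of each group at random."""
    test = []
    for lab in np.unique(groups):
        idx = np.flatnonzero(groups == lab)
        k = max(1, int(round(holdout_fraction * len(idx))))
        k = min(k, len(idx) - 2)  # keep the group trainable
        test.extend(rng.choice(idx, size=k, replace=False))
    test = np.array(sorted(test))
    train = np.setdiff1d(np.arange(len(groups)), test)
    return train, test


def select_n_pcs(
    scores: np.ndarray,
    groups,
    mode: str = "max_of_both",
    seed: int | None = None,
    n_pcs_grid=None,
    n_perm: int = 10,
    n_xval_repeats: int = 30,
    holdout_fraction: float = 1 / 8,
) -> int:
    """Choose how many PCs to retain before the discriminant step.

    ``a_score`` maximises reassignment success corrected by its permutation
    expectation; ``xval`` maximises held-out assignment accuracy over the
    grid; ``max_of_both`` runs both and returns the larger optimum. Within
    a criterion, ties go to the smallest n_pcs (the least-overfit model).
    """
    groups = np.asarray(groups)
    g = len(np.unique(groups))
    max_pcs = min(scores.shape[1], len(groups) - g - 1)
    grid = (
        list(n_pcs_grid)
        if n_pcs_grid is not None
        else list(range(max(1, g - 1), max_pcs + 1))
    )
    rng = np.random.default_rng(seed)

    def best(values):
        values = np.round(values, 12)
        return grid[int(np.argmax(values))]  # argmax takes first = smallest n_pcs

    choices = {}
    if mode in ("a_score", "max_of_both"):
        choices["a_score"] = best(
            [_a_score(scores, groups, k, n_perm, rng) for k in grid]
        )
    if mode in ("xval", "max_of_both"):
        choices["xval"] = best(
            [
                _xval_accuracy(scores, groups, k, n_xval_repeats, holdout_fraction, rng)
                for k in grid
            ]
        )
    if not choices:
        raise ValueError(f"unknown mode {mode!r}")
    return max(choices.values())


@dataclass
class CrossValidationResult:
    overall_accuracy: float
    per_group_accuracy: dict[str, float]
    n_repeats: int


def dapc_crossvalidate(
    scores: np.ndarray,
    groups,
    n_pcs: int,
    holdout_fraction: float = 1 / 8,
    n_repeats: int = 200,
    seed: int | None = None,
) -> CrossValidationResult:
    """Repeated hold-out validation of DAPC assignment.

    Each repeat removes a random ``holdout_fraction`` of every prior group
    (at least one member), trains on the remainder and predicts the
    removed fish; accuracies are averaged over repeats.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    labels = np.unique(groups)
    correct = {str(l): 0 for l in labels}
    total = {str(l): 0 for l in labels}
    for _ in range(n_repeats):
        train_idx, test_idx = _holdout_split(groups, holdout_fraction, rng)
        model = dapc_train(scores[train_idx], groups[train_idx], n_pcs)
        pred = model.assign(scores[test_idx])
        for lab in labels:
            m = groups[test_idx] == lab
            correct[str(lab)] += int((pred[m] == lab).sum())
            total[str(lab)] += int(m.sum())
    per_group = {l: correct[l] / total[l] for l in correct}
    return CrossValidationResult(
        overall_accuracy=sum(correct.values()) / sum(total.values()),
        per_group_accuracy=per_group,
        n_repeats=n_repeats,
    )


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    bic: float
    wss: float
    repeat_stability: float


def _partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition (up to relabeling)."""
    pa = {tuple(np.flatnonzero(a == l)) for l in np.unique(a)}
    pb = {tuple(np.flatnonzero(b == l)) for l in np.unique(b)}
    return pa == pb


def kmeans_bic(
    scores: np.ndarray,
    n_pcs: int | None = None,
    k_range=range(1, 8),
    n_repeats: int = 20,
    seed: int | None = None,
) -> list[ClusterSolution]:
    """Blind k-means over a k range, scored by BIC, with repeat stability.

    For each k, ``n_repeats`` random starts are run; the best (lowest-WSS)
    partition is kept, BIC = n*ln(WSS/n) + k*ln(n) computed from it, and
    stability is the fraction of repeats that reproduce that partition
    exactly. The best k has the minimum BIC.
    """
    X = scores[:, :n_pcs] if n_pcs else scores
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    out = []
    for k in k_range:
        if k >= n:
            raise ValueError(f"k={k} must be below n={n}")
        runs = []
        for _ in range(n_repeats):
            km = KMeans(
                n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1))
            ).fit(X)
            runs.append((km.inertia_, km.labels_))
        best_wss, best_labels = min(runs, key=lambda t: t[0])
        stability = float(
            np.mean([_partitions_equal(lab, best_labels) for _, lab in runs])
        )
        wss = max(best_wss, 1e-300)
        out.append(
            ClusterSolution(
                k=k,
                assignments=best_labels,
                bic=n * np.log(wss / n) + k * np.log(n),
                wss=float(best_wss),
                repeat_stability=stability,
            )
        )
    return out


def best_k(solutions: list[ClusterSolution]) -> ClusterSolution:
    return min(solutions, key=lambda s: s.bic)
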