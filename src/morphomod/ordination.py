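"""Ordination and group classification of shape data.

PCA of aligned (symmetric) shape coordinates, cross-validated selection of the
number of PC dimensions under unbalanced group sizes, permutation Procrustes
ANOVA, leave-one-out discriminant classification with resampled confidence
intervals, Mahalanobis distances between group means, and predictive
assignment of specimens excluded from training.

Classification uses linear discriminant analysis with equal priors (the
balanced-design logic of the resampling), backed by scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "ShapeSpace",
    "DimensionSelection",
    "AnovaResult",
    "ClassificationReport",
    "DistanceMatrix",
    "pca",
    "select_dimensions",
    "procrustes_anova",
    "cva_classify",
    "predict_excluded",
]


@dataclass
class ShapeSpace:
    """PC scores, eigenvalues and variance fractions of shape data."""

    scores: np.ndarray  # n x q
    eigenvalues: np.ndarray  # q, non-increasing
    variance_fractions: np.ndarray  # q, sums to 1
    loadings: np.ndarray  # p x q basis vectors
    mean: np.ndarray  # p flattened mean shape

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Project new (aligned) configurations into this PC space."""
        flat = np.asarray(coords, float).reshape(coords.shape[0], -1)
        return (flat - self.mean) @ self.loadings


@dataclass
class DimensionSelection:
    chosen_N: int
    accuracy_by_N: pd.DataFrame  # columns: N, accuracy


@dataclass
class AnovaResult:
    F: float
    p: float
    permutations: int
    PCs_used: int


@dataclass
class ClassificationReport:
    overall_accuracy: float  # percent
    ci_low: float
    ci_high: float
    per_group_accuracy: dict[str, float]
    confusion: pd.DataFrame  # true group x predicted group counts
    posterior_probs: pd.DataFrame  # per specimen, one column per group
    PCs_used: int


@dataclass
class DistanceMatrix:
    """Squared Mahalanobis distances between group means.

    ``distances`` (D = sqrt(D²)) is what comparison tables conventionally
    print.
    """

    groups: list[str]
    D2: np.ndarray

    @property
    def distances(self) -> np.ndarray:
        return np.sqrt(self.D2)

    def frame(self, squared: bool = False) -> pd.DataFrame:
        vals = self.D2 if squared else self.distances
        return pd.DataFrame(vals, index=self.groups, columns=self.groups)


def pca(coords: np.ndarray) -> ShapeSpace:
    """Principal component analysis of flattened shape coordinates.

    Accepts an n x k x m array of aligned coordinates (or an already-flat
    n x p matrix).  Eigen-decomposition of the specimen covariance via SVD of
    the centred data; components with numerically zero variance are dropped.
    """
    coords = np.asarray(coords, float)
    flat = coords.reshape(coords.shape[0], -1)
    n = flat.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    mean = flat.mean(axis=0)
    centred = flat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    if total == 0:
        # all specimens identical: a single zero component
        q = min(n - 1, flat.shape[1])
        return ShapeSpace(
            scores=np.zeros((n, q)),
            eigenvalues=np.zeros(q),
            variance_fractions=np.zeros(q),
            loadings=vt[:q].T,
            mean=mean,
        )
    keep = eigenvalues > eigenvalues[0] * 1e-12
    scores = u[:, keep] * s[keep]
    return ShapeSpace(
        scores=scores,
        eigenvalues=eigenvalues[keep],
        variance_fractions=eigenvalues[keep] / total,
        loadings=vt[keep].T,
        mean=mean,
    )


def _lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    labels = np.unique(y)
    clf = LinearDiscriminantAnalysis(
        priors=np.full(len(labels), 1 / len(labels)), solver="svd"
    )
    clf.fit(X, y)
    return clf


def _loo_predict(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out LDA predictions (deterministic)."""
    preds = np.empty(len(y), dtype=y.dtype)
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        clf = _lda(X[mask], y[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
    return preds


def _balanced_subsample(
    y: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a without-replacement subsample of `size` per group."""
    picks = []
    for g in np.unique(y):
        members = np.flatnonzero(y == g)
        picks.append(rng.choice(members, size=size, replace=False))
    return np.concatenate(picks)


def select_dimensions(
    scores: np.ndarray,
    groups: np.ndarray,
    max_N: int = 20,
    resamples: int = 1000,
    seed: int | None = None,
    min_N: int = 2,
) -> DimensionSelection:
    """Choose the number of leading PCs maximising cross-validated accuracy.

    For each candidate N, leave-one-out LDA accuracy is averaged over repeated
    balanced subsamples (smallest group size per group), which guards the
    cross-validation against unbalanced designs.  Ties break toward the
    smallest N (parsimony).
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise ValueError("need at least 2 groups with at least 2 members each")
    n = len(groups)
    cap = min(scores.shape[1], n - len(labels) - 1)
    if max_N > cap:
        warnings.warn(
            f"max_N={max_N} too large for n={n} with {len(labels)} groups; "
            f"capped at {cap}",
            stacklevel=2,
        )
        max_N = cap
    size = int(counts.min())
    rng = np.random.default_rng(seed)
    subsamples = [_balanced_subsample(groups, size, rng) for _ in range(resamples)]
    rows = []
    for N in range(min_N, max_N + 1):
        accs = []
        for sub in subsamples:
            preds = _loo_predict(scores[sub, :N], groups[sub])
            accs.append(np.mean(preds == groups[sub]))
        rows.append((N, float(np.mean(accs))))
    table = pd.DataFrame(rows, columns=["N", "accuracy"])
    chosen = int(table.loc[table["accuracy"].idxmax(), "N"])  # idxmax -> first max
    return DimensionSelection(chosen_N=chosen, accuracy_by_N=table)


def _anova_f(X: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> float:
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for g in labels:
        sub = X[groups == g]
        m = sub.mean(axis=0)
        ssb += len(sub) * np.sum((m - grand) ** 2)
        ssw += np.sum((sub - m) ** 2)
    df_b = len(labels) - 1
    df_w = len(X) - len(labels)
    return float((ssb / df_b) / (ssw / df_w))


def procrustes_anova(
    scores: np.ndarray,
    groups: np.ndarray,
    N: int,
    permutations: int = 999,
    seed: int | None = None,
) -> AnovaResult:
    """Permutation one-way ANOVA of shape (first N PC scores) on group.

    F is the ratio of between- to within-group mean squared deviation summed
    over the N dimensions; the p-value is the proportion of label
    permutations (observed statistic included) with F at least as large.
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    if N > scores.shape[1]:
        raise ValueError(f"N={N} exceeds available PCs ({scores.shape[1]})")
    labels, counts = np.unique(groups, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    X = scores[:, :N]
    f_obs = _anova_f(X, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 1  # observed statistic counted in the null set
    for _ in range(permutations):
        perm = rng.permutation(groups)
        if _anova_f(X, perm, labels) >= f_obs:
            hits += 1
    return AnovaResult(
        F=f_obs, p=hits / (permutations + 1), permutations=permutations, PCs_used=N
    )


def mahalanobis_matrix(X: np.ndarray, groups: np.ndarray) -> DistanceMatrix:
    """Squared Mahalanobis distances between group means (pooled covariance)."""
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    n, p = X.shape
    pooled = np.zeros((p, p))
    means = {}
    for g in labels:
        sub = X[groups == g]
        means[g] = sub.mean(axis=0)
        pooled += (sub - means[g]).T @ (sub - means[g])
    pooled /= n - len(labels)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-group covariance is singular; use fewer PCs"
        ) from exc
    d2 = np.zeros((len(labels), len(labels)))
    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels):
            if j <= i:
                continue
            diff = means[gi] - means[gj]
            d2[i, j] = d2[j, i] = diff @ inv @ diff
    return DistanceMatrix(groups=[str(g) for g in labels], D2=d2)


def cva_classify(
    scores: np.ndarray,
    groups: np.ndarray,
    N: int,
    resamples: int = 1000,
    seed: int | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[ClassificationReport, DistanceMatrix]:
    """Leave-one-out discriminant classification on the first N PCs.

    The point accuracy and confusion matrix come from deterministic LOO over
    the full sample; the confidence interval is the percentile range of LOO
    accuracies over balanced resampled designs (smallest group size per
    group).  Mahalanobis distances between group means are computed in the
    same N-dimensional space with the pooled within-group covariance.
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    if N > scores.shape[1]:
        raise ValueError(f"N={N} exceeds available PCs ({scores.shape[1]})")
    X = scores[:, :N]
    labels, counts = np.unique(groups, return_counts=True)
    preds = _loo_predict(X, groups)
    overall = 100.0 * np.mean(preds == groups)
    per_group = {
        str(g): 100.0 * np.mean(preds[groups == g] == g) for g in labels
    }
    confusion = pd.crosstab(
        pd.Series(groups, name="true"), pd.Series(preds, name="predicted")
    ).reindex(index=labels, columns=labels, fill_value=0)

    clf = _lda(X, groups)
    posteriors = pd.DataFrame(clf.predict_proba(X), columns=clf.classes_)

    rng = np.random.default_rng(seed)
    size = int(counts.min())
    accs = []
    for _ in range(resamples):
        sub = _balanced_subsample(groups, size, rng)
        sub_preds = _loo_predict(X[sub], groups[sub])
        accs.append(100.0 * np.mean(sub_preds == groups[sub]))
    lo, hi = np.percentile(accs, ci)
    report = ClassificationReport(
        overall_accuracy=float(overall),
        ci_low=float(lo),
        ci_high=float(hi),
        per_group_accuracy=per_group,
        confusion=confusion,
        posterior_probs=posteriors,
        PCs_used=N,
    )
    return report, mahalanobis_matrix(X, groups)


def predict_excluded(
    scores: np.ndarray,
    train_groups: np.ndarray,
    excluded_scores: np.ndarray,
    N: int,
    resamples: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Identification probabilities for specimens excluded from training.

    Per excluded specimen, the probability of belonging to each training
    group is the fraction of balanced resampled discriminant fits that assign
    it to that group.  Excluded specimens must already live in the training
    PC space (project them with the training loadings).
    """
    scores = np.asarray(scores, float)[:, :N]
    excluded = np.atleast_2d(np.asarray(excluded_scores, float))[:, :N]
    train_groups = np.asarray(train_groups)
    labels, counts = np.unique(train_groups, return_counts=True)
    size = int(counts.min())
    rng = np.random.default_rng(seed)
    votes = np.zeros((excluded.shape[0], len(labels)))
    col = {g: i for i, g in enumerate(labels)}
    for _ in range(resamples):
        sub = _balanced_subsample(train_groups, size, rng)
        clf = _lda(scores[sub], train_groups[sub])
        for row, pred in enumerate(clf.predict(excluded)):
            votes[row, col[pred]] += 1
    return pd.DataFrame(votes / resamples, columns=[str(g) for g in labels])
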