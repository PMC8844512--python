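"""ANOVA F-score feature ranking, incremental feature selection and PCA.

Features are ranked by the two-class ANOVA F statistic (between-class over
within-class mean square); incremental feature selection (IFS) then sweeps
rank-ordered feature prefixes and picks the prefix size with the best
cross-validated accuracy.  Degenerate features are ordered deterministically:
a feature that separates the classes with zero within-class variance gets
F = +inf (ranked first), a constant feature gets F = 0; ties break by
ascending feature index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .encoder import FeatureMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ClassifierSpec


@dataclass
class FeatureRanking:
    """Per-feature F-scores and the induced descending order (0-based)."""

    f_scores: np.ndarray
    order: np.ndarray

    def to_tsv(self, path: str | Path, feature_names: Sequence[str]) -> None:
        with Path(path).open("w") as fh:
            fh.write("rank\tfeature_index\tfeature_name\tf_score\n")
            for rank, j in enumerate(self.order, start=1):
                fh.write(f"{rank}\t{j + 1}\t{feature_names[j]}\t{self.f_scores[j]:.6g}\n")


def anova_f(matrix: FeatureMatrix) -> FeatureRanking:
    """Rank every feature by the two-class ANOVA F statistic.

    F = MSB / MSW with MSB = sum_g n_g (xbar_g - xbar)^2 / (k - 1) and
    MSW = sum_g sum_i (x_gi - xbar_g)^2 / (N - k), k = 2 classes.
    Requires >= 2 samples in each class.
    """
    y = np.asarray(matrix.labels, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"ANOVA ranking needs binary 0/1 labels; got {classes}")
    X = matrix.X
    n0 = int(np.sum(y == 0))
    n1 = int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples for within-class variance")
    N = n0 + n1
    m0 = X[y == 0].mean(axis=0)
    m1 = X[y == 1].mean(axis=0)
    grand = X.mean(axis=0)
    ssb = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2  # k - 1 = 1
    ssw = ((X[y == 0] - m0) ** 2).sum(axis=0) + ((X[y == 1] - m1) ** 2).sum(axis=0)
    msw = ssw / (N - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / msw
    # zero within-class variance: perfectly separating -> +inf, constant -> 0
    f = np.where(msw == 0, np.where(ssb > 0, np.inf, 0.0), f)
    order = np.argsort(-f, kind="stable")  # stable sort: ties by ascending index
    return FeatureRanking(f_scores=f, order=order)


def select_top(matrix: FeatureMatrix, ranking: FeatureRanking, d: int) -> FeatureMatrix:
    """Keep the d best-ranked features, columns in rank order; labels unchanged."""
    if not 1 <= d <= matrix.n_features:
        raise ValueError(f"d must be in 1..{matrix.n_features}, got {d}")
    cols = ranking.order[:d]
    return FeatureMatrix(
        matrix.X[:, cols],
        [matrix.feature_names[j] for j in cols],
        matrix.labels,
        list(matrix.ids),
    )


@dataclass
class IFSResult:
    """Accuracy (percent) of each tried prefix size, and the chosen optimum."""

    accuracy_by_d: dict[int, float]
    optimal_d: int
    optimal_accuracy: float

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("d\taccuracy\n")
            for d in sorted(self.accuracy_by_d):
                fh.write(f"{d}\t{self.accuracy_by_d[d]:.4f}\n")


def ifs_search(
    matrix: FeatureMatrix,
    ranking: FeatureRanking,
    spec: "ClassifierSpec",
    k: int = 10,
    cv_seed: int = 0,
    d_grid: Sequence[int] | None = None,
    objective: str = "acc",
) -> IFSResult:
    """Incremental feature selection over rank-ordered prefixes.

    For each prefix size d in ``d_grid`` (default: every size 1..n_features)
    the classifier is cross-validated on the top-d features; the optimum is
    the smallest d attaining the maximum objective (mean CV accuracy by
    default, MCC with ``objective='mcc'``).  Deterministic given the seeds.
    """
    from .evaluation import stratified_kfold

    if d_grid is None:
        d_grid = range(1, matrix.n_features + 1)
    d_grid = sorted(set(int(d) for d in d_grid))
    if not d_grid:
        raise ValueError("d_grid must be non-empty")
    if d_grid[0] < 1 or d_grid[-1] > matrix.n_features:
        raise ValueError(f"d_grid values must lie in 1..{matrix.n_features}")
    if objective not in ("acc", "mcc"):
        raise ValueError("objective must be 'acc' or 'mcc'")
    accuracy_by_d: dict[int, float] = {}
    for d in d_grid:
        report = stratified_kfold(select_top(matrix, ranking, d), spec, k=k, seed=cv_seed)
        accuracy_by_d[d] = report.mean.acc if objective == "acc" else report.mean.mcc
    best = max(accuracy_by_d.values())
    optimal_d = min(d for d, a in accuracy_by_d.items() if a == best)
    return IFSResult(accuracy_by_d=accuracy_by_d, optimal_d=optimal_d, optimal_accuracy=best)


def pca_project(matrix: FeatureMatrix, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores for visualisation.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-magnitude loading is positive, making plots
    reproducible across runs and library versions.  Returns
    (scores[n_samples, n_components], explained_variance_ratio).
    """
    from sklearn.decomposition import PCA

    max_nc = min(matrix.n_samples, matrix.n_features)
    if not 1 <= n_components <= max_nc:
        raise ValueError(f"n_components must be in 1..{max_nc}, got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_
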