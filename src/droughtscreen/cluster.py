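"""Two-way hierarchical clustering, PCA and LDA cross-validation.

Genotypes are clustered on standardized relative trait values (drought /
control ratios of genotype means) with the Ward.D2 criterion on Euclidean
distances; traits are clustered the same way on the transposed matrix.
PCA of the trait correlation matrix and leave-one-out linear discriminant
analysis validate the resulting partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "LinkageTree",
    "PcaModel",
    "ConfusionMatrix",
    "TwoWayClustering",
    "standardize_columns",
    "ward_d2_linkage",
    "cut_tree",
    "two_way_cluster",
    "pca",
    "lda_crossvalidate",
    "cluster_summary",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history over labelled leaves.

    ``merges`` is the (n−1)×4 scipy linkage matrix: children ids, merge
    height (the Ward.D2 between-cluster distance) and merged size.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    method: str = "ward.D2"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["left", "right", "height", "size"])


@dataclass(frozen=True)
class PcaModel:
    """Eigen decomposition of the trait correlation matrix."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame      # observations × components
    loadings: pd.DataFrame    # traits × components, scaled by sqrt(eigenvalue)
    components: pd.DataFrame  # traits × components, orthonormal


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: pd.DataFrame
    accuracy: float
    n_evaluated: int
    skipped: tuple[str, ...] = ()


@dataclass(frozen=True)
class TwoWayClustering:
    row_tree: LinkageTree
    row_assignment: pd.Series
    col_tree: LinkageTree
    col_assignment: pd.Series
    ordered_matrix: pd.DataFrame = field(repr=False)


def standardize_columns(matrix: pd.DataFrame, *, clip: float | None = None) -> pd.DataFrame:
    """Column z-scores (mean 0, SD 1, ddof=1).

    Zero-variance columns are dropped with a warning.  ``clip`` bounds the
    output symmetrically (display convention for heatmaps, e.g. ±2); leave
    ``None`` for analysis — distances are always computed on unclipped
    scores.
    """
    sd = matrix.std(ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        warnings.warn("dropping zero-variance columns: "
                      + ", ".join(map(str, matrix.columns[bad])), stacklevel=2)
        matrix = matrix.loc[:, ~bad]
        sd = sd[~bad]
    z = (matrix - matrix.mean()) / sd
    if clip is not None:
        z = z.clip(-abs(clip), abs(clip))
    return z


def ward_d2_linkage(matrix: pd.DataFrame) -> LinkageTree:
    """Ward.D2 agglomeration on Euclidean distances between rows.

    The criterion squares the distances internally (the R ``ward.D2``
    convention); merge heights are monotone non-decreasing.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    X = np.ascontiguousarray(matrix.to_numpy(float))
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return LinkageTree(Z, tuple(matrix.index))


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Partition into exactly k groups by removing the k−1 highest merges.

    Labels are 1..k, numbered by first appearance in the input row order
    (deterministic).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return pd.Series(out, index=list(tree.labels), name="cluster")


def two_way_cluster(matrix: pd.DataFrame, k_rows: int = 3,
                    k_cols: int = 2) -> TwoWayClustering:
    """Cluster rows (genotypes) and columns (traits) independently.

    Returns both trees and assignments plus the input matrix reordered by
    the two dendrograms (the heatmap layout).
    """
    row_tree = ward_d2_linkage(matrix)
    col_tree = ward_d2_linkage(matrix.T)
    row_assign = cut_tree(row_tree, k_rows)
    col_assign = cut_tree(col_tree, k_cols)
    ordered = matrix.loc[row_tree.leaf_order(), col_tree.leaf_order()]
    return TwoWayClustering(row_tree, row_assign, col_tree, col_assign, ordered)


def pca(matrix: pd.DataFrame) -> PcaModel:
    """PCA via eigen decomposition of the column correlation matrix."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    z = standardize_columns(matrix)
    R = np.corrcoef(z.to_numpy(float), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("degenerate matrix: correlation undefined")
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # deterministic sign: largest-magnitude coordinate positive
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    vec = vec * flip
    comp_names = [f"PC{i + 1}" for i in range(len(lam))]
    scores = pd.DataFrame(z.to_numpy(float) @ vec, index=matrix.index,
                          columns=comp_names)
    loadings = pd.DataFrame(vec * np.sqrt(lam), index=z.columns,
                            columns=comp_names)
    components = pd.DataFrame(vec, index=z.columns, columns=comp_names)
    return PcaModel(lam, lam / lam.sum() * 100.0, scores, loadings, components)


def _reduce_for_lda(X: np.ndarray, var_target: float) -> np.ndarray:
    """Project onto the leading PCs capturing ``var_target`` of the variance
    (needed whenever traits outnumber genotypes and the pooled covariance
    would be singular)."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    ncomp = int(np.searchsorted(frac, var_target) + 1)
    ncomp = min(ncomp, np.sum(s > 1e-10 * s[0]))
    return U[:, :ncomp] * s[:ncomp]


def lda_crossvalidate(matrix: pd.DataFrame, labels: pd.Series, *,
                      variance_target: float = 0.90,
                      uniform_priors: bool = True) -> ConfusionMatrix:
    """Leave-one-out LDA validation of a cluster assignment.

    The classifier is a linear discriminant with pooled within-class
    covariance.  When features are at least as numerous as observations the
    matrix is first projected onto the leading principal components
    capturing ``variance_target`` of the variance.  Folds whose left-out
    observation belongs to a class with fewer than 2 members are skipped
    with a warning (the class cannot appear in the training set).
    """
    labels = labels.loc[matrix.index]
    X = matrix.to_numpy(float)
    if X.shape[1] >= X.shape[0]:
        X = _reduce_for_lda(X, variance_target)
    y = labels.to_numpy()
    classes = np.unique(y)
    counts = pd.Series(y).value_counts()
    skipped = []
    results: list[tuple[object, object]] = []
    for i in range(len(y)):
        if counts[y[i]] < 2:
            skipped.append(str(matrix.index[i]))
            continue
        mask = np.ones(len(y), bool)
        mask[i] = False
        train_classes = np.unique(y[mask])
        priors = (np.full(len(train_classes), 1.0 / len(train_classes))
                  if uniform_priors else None)
        clf = LinearDiscriminantAnalysis(solver="lsqr", priors=priors)
        try:
            clf.fit(X[mask], y[mask])
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular pooled covariance with {X.shape[1]} feature(s); "
                "reduce dimensionality further") from err
        results.append((y[i], clf.predict(X[i][None, :])[0]))
    if skipped:
        warnings.warn("skipped LOO folds for singleton classes: "
                      + ", ".join(skipped), stacklevel=2)
    counts_mat = pd.DataFrame(0, index=classes, columns=classes)
    for true, pred in results:
        counts_mat.loc[true, pred] += 1
    n_eval = len(results)
    acc = float(np.trace(counts_mat.to_numpy())) / n_eval if n_eval else float("nan")
    return ConfusionMatrix(counts_mat, acc, n_eval, tuple(skipped))


def cluster_summary(percent_changes: pd.DataFrame,
                    assignment: pd.Series) -> pd.DataFrame:
    """Mean percent change per (cluster, trait).

    ``percent_changes`` is a genotype × trait matrix of drought-vs-control
    percent changes; rows are averaged within each cluster.
    """
    missing = set(percent_changes.index) - set(assignment.index)
    if missing:
        raise ValueError(f"assignment does not cover genotypes: {sorted(missing)}")
    grouped = percent_changes.groupby(assignment.loc[percent_changes.index]).mean()
    grouped.index.name = "cluster"
    return grouped


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Chance-corrected partition agreement (test/diagnostic metric)."""
    from sklearn.metrics import adjusted_rand_score

    a, b = pd.Series(labels_a).align(pd.Series(labels_b), join="inner")
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
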