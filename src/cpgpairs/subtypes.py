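"""Subtype discovery on the binary pair matrix and cross-platform transfer.

Samples are clustered by complete-linkage agglomeration on Hamming distances
between their 0/1 pair-score columns; the tree is cut at k clusters. An
optional resampled consensus wrapper repeats the clustering on sample subsets
and clusters the co-assignment matrix. Subtypes are transferred to new
samples (e.g. a second array platform) with an RBF-kernel SVM tuned by
stratified cross-validated grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC


def canonicalize_labels(labels: pd.Series) -> pd.Series:
    """Renumber clusters 1..k by decreasing size; ties broken by the smallest
    member sample ID. Makes partitions comparable across runs."""
    groups = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), min(map(str, kv[1]))),
    )
    mapping = {old: new for new, (old, _) in enumerate(groups, start=1)}
    out = labels.map(mapping).astype(int)
    out.name = "cluster"
    return out


def hierarchical_cluster(
    scores: pd.DataFrame,
    k: int = 3,
    consensus: bool = False,
    n_resamples: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Cluster samples on the binary pair matrix.

    Pairwise sample distances are Hamming distances over pairs; agglomeration
    uses complete linkage and the dendrogram is cut at ``k``. Samples are
    sorted by ID before linkage so the partition does not depend on input
    order. With ``consensus=True`` the clustering is repeated on
    ``n_resamples`` random subsets of ``subsample`` of the samples and the
    same linkage/cut is applied to 1 - (co-assignment frequency).
    """
    n = scores.shape[1]
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    ordered = scores.reindex(columns=sorted(scores.columns, key=str))
    x = ordered.to_numpy(dtype=float).T  # samples x pairs
    if consensus:
        rng = np.random.default_rng(seed)
        m = max(2, int(round(subsample * n)))
        together = np.zeros((n, n))
        drawn = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            sub = x[idx]
            lab = fcluster(
                linkage(pdist(sub, metric="hamming"), method="complete"),
                t=min(k, m),
                criterion="maxclust",
            )
            same = lab[:, None] == lab[None, :]
            together[np.ix_(idx, idx)] += same
            drawn[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore"):
            consensus_d = 1.0 - np.where(drawn > 0, together / drawn, 0.0)
        np.fill_diagonal(consensus_d, 0.0)
        dist = squareform(consensus_d, checks=False)
    else:
        dist = pdist(x, metric="hamming")
    raw = fcluster(linkage(dist, method="complete"), t=k, criterion="maxclust")
    labels = pd.Series(raw, index=ordered.columns, name="cluster")
    labels = canonicalize_labels(labels)
    return labels.reindex(scores.columns)


def pca_embed(scores: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Principal-component coordinates of the samples.

    Pair features are mean-centered; components are ordered by decreasing
    explained variance, with the sign fixed so that each component's
    largest-magnitude loading is positive.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = scores.to_numpy(dtype=float).T
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("constant score matrix: no variance to embed")
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    for i in range(n_components):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, i] = -coords[:, i]
    return pd.DataFrame(
        coords,
        index=scores.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def explained_variance(scores: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    x = scores.to_numpy(dtype=float).T
    pca = PCA(n_components=min(n_components, min(x.shape)), svd_solver="full")
    pca.fit(x)
    return pca.explained_variance_


def split_train(
    labels: pd.Series, test_fraction: float = 0.25, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified random split of labeled samples into a training (A) and
    hold-out (B) group, 3:1 by default. Deterministic under the seed."""
    counts = labels.value_counts()
    if (counts < 4).any():
        small = counts[counts < 4].index.tolist()
        raise ValueError(f"clusters too small to stratify 3:1: {small}")
    a, b = train_test_split(
        labels.index.to_numpy(),
        test_size=test_fraction,
        stratify=labels.to_numpy(),
        random_state=seed,
    )
    return sorted(a.tolist(), key=str), sorted(b.tolist(), key=str)


@dataclass
class SvmModel:
    """Tuned RBF-kernel SVM together with its selection-time CV accuracy."""

    kernel: str
    C: float
    gamma: float | str
    cv_accuracy: float
    estimator: SVC
    pairs: list[str] = field(default_factory=list)


DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float | str, ...] = ("scale", 0.01, 0.1, 1.0)


def fit_svm_grid(
    scores_a: pd.DataFrame,
    labels_a: pd.Series,
    folds: int = 5,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float | str] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> SvmModel:
    """Grid-search an RBF SVM by stratified k-fold CV accuracy.

    Ties are broken toward smaller C, then toward the earlier gamma in the
    grid. The winning parameters are refit on all of group A.
    """
    y = labels_a.reindex(scores_a.columns)
    if y.isna().any():
        raise ValueError("unlabeled samples in the training matrix")
    y = y.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit the classifier")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {folds} for "
            f"{folds}-fold stratified CV"
        )
    x = scores_a.to_numpy(dtype=float).T
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(x, y))
    best: tuple[float, float, float | str] | None = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in gamma_grid:
            accs = []
            for train_idx, test_idx in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(x[train_idx], y[train_idx])
                accs.append(float(np.mean(clf.predict(x[test_idx]) == y[test_idx])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, C, gamma)
    assert best is not None
    acc, C, gamma = best
    final = SVC(kernel="rbf", C=C, gamma=gamma)
    final.fit(x, y)
    return SvmModel(
        kernel="rbf",
        C=C,
        gamma=gamma,
        cv_accuracy=acc,
        estimator=final,
        pairs=scores_a.index.tolist(),
    )


def predict_subtype(model: SvmModel, scores: pd.DataFrame) -> pd.Series:
    """Assign subtype labels to new samples scored on the model's pair universe."""
    if set(scores.index) != set(model.pairs):
        extra = sorted(set(scores.index) - set(model.pairs))
        missing = sorted(set(model.pairs) - set(scores.index))
        raise ValueError(
            f"pair universe mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
        )
    x = scores.reindex(model.pairs).to_numpy(dtype=float).T
    pred = model.estimator.predict(x)
    return pd.Series(pred.astype(int), index=scores.columns, name="cluster")
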