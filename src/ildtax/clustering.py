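"""Hierarchical agglomerative clustering with cophenetic model selection.

The pipeline clusters cells by their principal-component scores.  Because no
single distance metric / linkage rule is canonical for tuning-curve data, all
24 combinations of six pairwise-distance metrics (euclidean, seuclidean,
minkowski, mahalanobis, cityblock, cosine) and four linkage rules (single,
average, complete, ward) are ranked by the cophenetic correlation coefficient
(CCC): the Pearson correlation between the original pairwise dissimilarities
and the dendrogram-implied (cophenetic) distances.  The winning dendrogram is
cut either at a fixed cluster count or wherever the inconsistency coefficient
-- a per-merge z-score of link height against the link heights within a fixed
depth window below it -- exceeds a threshold.

The merge bookkeeping follows the classic statistics-toolbox conventions
(Lance-Williams updates, depth-windowed inconsistency), as implemented by
:mod:`scipy.cluster.hierarchy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "METRICS",
    "LINKAGES",
    "DistanceMatrix",
    "LinkageTree",
    "CCCGrid",
    "InconsistencyTable",
    "ClusterSolution",
    "pairwise_distances",
    "linkage",
    "cophenetic",
    "ccc_grid",
    "inconsistency",
    "cut",
]

# row / column order of the CCC grid; also the tie-break order
METRICS = ("euclidean", "seuclidean", "minkowski", "mahalanobis", "cityblock", "cosine")
LINKAGES = ("single", "average", "complete", "ward")


@dataclass
class DistanceMatrix:
    """Condensed vector of the N*(N-1)/2 pairwise dissimilarities."""

    condensed: np.ndarray
    metric: str
    n: int
    p: float = 2.0

    def __post_init__(self) -> None:
        self.condensed = np.asarray(self.condensed, dtype=float)
        if self.condensed.size != self.n * (self.n - 1) // 2:
            raise ValueError("condensed length inconsistent with n")
        if np.any(self.condensed < -1e-12):
            raise ValueError("negative dissimilarity")

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


def pairwise_distances(matrix: np.ndarray, metric: str, p: float = 2.0) -> DistanceMatrix:
    """Condensed pairwise distances between the rows of ``matrix``.

    seuclidean standardizes each dimension by its unbiased variance;
    cosine is 1 - u.v/(|u||v|); mahalanobis uses the sample covariance of
    the rows, falling back to a pseudo-inverse (with a warning) when that
    covariance is singular.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two observations")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    kwargs: dict = {}
    if metric == "minkowski":
        kwargs["p"] = p
    elif metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"cosine distance undefined for zero-norm row {bad[0]}")
    elif metric == "mahalanobis":
        cov = np.cov(x.T)
        cov = np.atleast_2d(cov)
        try:
            vi = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular covariance; using pseudo-inverse for mahalanobis",
                stacklevel=2,
            )
            vi = np.linalg.pinv(cov)
        kwargs["VI"] = vi
    d = pdist(x, metric=metric, **kwargs)
    # cosine can dip epsilon-negative for near-parallel vectors
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(d, metric, n=x.shape[0], p=p)


@dataclass
class LinkageTree:
    """The N-1 agglomerative merges: (left id, right id, height, size)."""

    merges: np.ndarray
    method: str
    n: int
    metric: str = ""

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n - 1, 4):
            raise ValueError(f"expected {self.n - 1} merge records")
        if int(self.merges[-1, 3]) != self.n:
            raise ValueError("root size does not equal n")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def linkage(dm: DistanceMatrix, method: str) -> LinkageTree:
    """Agglomerate a condensed distance matrix into a dendrogram.

    Ward is applied to whatever dissimilarity is supplied via its
    Lance-Williams coefficients, including non-Euclidean ones such as
    cosine — a deliberate faithful-reproduction choice for this pipeline.
    """
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    if dm.n < 2:
        raise ValueError("need at least two items to cluster")
    z = hierarchy.linkage(dm.condensed, method=method)
    return LinkageTree(z, method=method, n=dm.n, metric=dm.metric)


def cophenetic(tree: LinkageTree, dm: DistanceMatrix) -> tuple[float, np.ndarray]:
    """Cophenetic correlation coefficient and cophenetic distances.

    The cophenetic distance of a pair of cells is the height of the lowest
    merge that joins them; the CCC is the Pearson correlation between these
    and the original dissimilarities.
    """
    if dm.n != tree.n:
        raise ValueError("tree and distance matrix disagree on N")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ccc, coph = hierarchy.cophenet(tree.merges, dm.condensed)
    if not np.isfinite(ccc):
        raise ValueError("CCC undefined: zero variance in distances")
    return float(ccc), coph


@dataclass
class CCCGrid:
    """CCC for every metric x linkage combination, plus the argmax pair."""

    values: np.ndarray  # len(metrics) x len(linkages), NaN where failed
    metrics: tuple[str, ...]
    linkages: tuple[str, ...]
    best: tuple[str, str]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def value(self, metric: str, link: str) -> float:
        return float(self.values[self.metrics.index(metric), self.linkages.index(link)])


def ccc_grid(
    matrix: np.ndarray,
    metrics: tuple[str, ...] = METRICS,
    linkages: tuple[str, ...] = LINKAGES,
    p: float = 2.0,
) -> CCCGrid:
    """Evaluate the CCC over every metric x linkage pair on ``matrix`` rows.

    Ties at the maximum are broken by the listed metric order, then linkage
    order.  Combinations that fail (e.g. undefined distances) are recorded
    as NaN with the reason kept in ``failures``.
    """
    vals = np.full((len(metrics), len(linkages)), np.nan)
    failures: dict[tuple[str, str], str] = {}
    for i, metric in enumerate(metrics):
        try:
            dm = pairwise_distances(matrix, metric, p=p)
        except Exception as exc:  # metric inapplicable to this matrix
            for j, link in enumerate(linkages):
                failures[(metric, link)] = str(exc)
            continue
        for j, link in enumerate(linkages):
            try:
                tree = linkage(dm, link)
                vals[i, j], _ = cophenetic(tree, dm)
            except Exception as exc:
                failures[(metric, link)] = str(exc)
    if np.all(np.isnan(vals)):
        raise ValueError("every metric x linkage combination failed")
    # ties at the max (e.g. the structurally identical euclidean/minkowski and,
    # on decorrelated PC scores, seuclidean/mahalanobis rows) are broken by the
    # listed metric order, then linkage order, robust to rounding noise
    top = np.nanmax(vals)
    bi, bj = next(
        (i, j)
        for i in range(len(metrics))
        for j in range(len(linkages))
        if np.isfinite(vals[i, j]) and vals[i, j] >= top - 1e-9
    )
    return CCCGrid(vals, tuple(metrics), tuple(linkages), (metrics[bi], linkages[bj]), failures)


@dataclass
class InconsistencyTable:
    """Per-merge inconsistency statistics at a given depth.

    Columns: mean and SD of the link heights in the depth window, number of
    links in the window, and the inconsistency coefficient
    (height - mean)/SD, defined as 0 for windows with a single link or zero
    SD.
    """

    table: np.ndarray  # (N-1, 4): mean, sd, count, coefficient
    depth: int

    @property
    def coefficients(self) -> np.ndarray:
        return self.table[:, 3]


def inconsistency(tree: LinkageTree, depth: int = 3) -> InconsistencyTable:
    """Depth-windowed inconsistency coefficient for every merge."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = hierarchy.inconsistent(tree.merges, d=depth)
    r = np.asarray(r, dtype=float)
    # single-link windows / zero SD -> coefficient 0 by convention
    r[:, 3] = np.where((r[:, 2] <= 1) | (r[:, 1] == 0) | ~np.isfinite(r[:, 3]), 0.0, r[:, 3])
    return InconsistencyTable(r, depth=depth)


@dataclass
class ClusterSolution:
    """Flat clustering: one 1-based cluster id per cell."""

    labels: np.ndarray
    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.counts.sum() != self.labels.size:
            raise ValueError("membership counts do not sum to N")


def _solution_from_labels(labels: np.ndarray) -> ClusterSolution:
    # relabel to 1..k in order of first appearance, for determinism
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    lab = np.asarray([remap[v] for v in labels], dtype=int)
    counts = np.bincount(lab)[1:]
    return ClusterSolution(lab, k=int(lab.max()), counts=counts)


def cut(
    tree: LinkageTree,
    k: int | None = None,
    inconsistency_threshold: float | None = None,
    depth: int = 3,
) -> ClusterSolution:
    """Cut a dendrogram into a flat clustering.

    Exactly one criterion must be given: ``k`` cuts into exactly k clusters
    (undoing the last k-1 merges); ``inconsistency_threshold`` groups cells
    below every link whose inconsistency coefficient (at ``depth``) stays
    within the threshold.
    """
    if (k is None) == (inconsistency_threshold is None):
        raise ValueError("give exactly one of k or inconsistency_threshold")
    if k is not None:
        if not 1 <= k <= tree.n:
            raise ValueError(f"k must be in [1, {tree.n}]")
        labels = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    else:
        r = inconsistency(tree, depth=depth).table
        labels = hierarchy.fcluster(
            tree.merges, t=inconsistency_threshold, criterion="inconsistent", R=r
        )
    return _solution_from_labels(labels)
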