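"""PCA dimension reduction for ILD surveys and component-count selection.

The covariance matrix of the L = 13 ILD-level variables is formed across the
N cells with 1/N scaling,

    A = (1/N) * sum_k (x_k - mu)^T (x_k - mu),        A v = lambda v,

eigen-decomposed, and cells are projected onto the eigenvectors,
y = V^T (x - mu).  Each component's share of the total variance is
lambda_i * 100 / sum(lambda).  Four rules for choosing how many components
to keep are provided: the scree-plot elbow, Kaiser's eigenvalue cutoff,
Horn's parallel analysis, and a cumulative explained-variance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .normalization import NormalizedDataset

__all__ = [
    "PCAResult",
    "ComponentSelectionRule",
    "fit_pca",
    "variance_percentages",
    "select_n_components",
    "project",
    "reconstruct",
]

SELECTION_RULES = ("scree_elbow", "kaiser", "horn", "explained_variance")


@dataclass
class PCAResult:
    """Eigen-decomposition of the level-by-level covariance matrix.

    ``eigenvalues`` are sorted descending (one per ILD level);
    ``eigenvectors`` holds the matching orthonormal columns; ``scores`` is
    the full L x N projection of the centered data; ``variance_pct`` the
    percentage of total variance per component.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    variance_pct: np.ndarray
    n_samples: int
    column_variances: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    @property
    def n_levels(self) -> int:
        return self.eigenvalues.size


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, NormalizedDataset):
        return data.matrix
    x = np.asarray(data, dtype=float)
    if hasattr(data, "counts"):  # ILDDataset
        x = np.asarray(data.counts, dtype=float)
    return x


def fit_pca(data) -> PCAResult:
    """Fit covariance PCA (1/N scaling) to an N x L matrix.

    Accepts a raw array, an ``ILDDataset`` or a ``NormalizedDataset``.
    Eigenvector signs are fixed by making each column's largest-magnitude
    loading positive, so score files are reproducible.
    """
    x = _as_matrix(data)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.any(~np.isfinite(x)):
        raise ValueError("PCA input contains missing or non-finite values")
    n, L = x.shape
    mu = x.mean(axis=0)
    xc = x - mu
    a = (xc.T @ xc) / n
    evals, evecs = np.linalg.eigh(a)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-12 * max(evals.max(), 1.0), 0.0, evals)
    # deterministic sign: largest-|loading| entry positive per eigenvector
    for j in range(L):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    degenerate = evals.sum() <= 0
    if degenerate:
        warnings.warn("constant input: covariance is zero, PCA is degenerate", stacklevel=2)
        pct = np.zeros(L)
    else:
        pct = variance_percentages(evals)
    scores = evecs.T @ xc.T
    return PCAResult(
        mean=mu,
        eigenvalues=evals,
        eigenvectors=evecs,
        scores=scores,
        variance_pct=pct,
        n_samples=n,
        column_variances=xc.var(axis=0),
        degenerate=degenerate,
    )


def variance_percentages(eigenvalues) -> np.ndarray:
    """Percent of total variance per component: lambda_i * 100 / sum(lambda)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues supplied")
    if np.any(lam < -1e-9 * max(abs(lam).max(), 1.0)):
        raise ValueError("eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero")
    return lam * 100.0 / total


@dataclass(frozen=True)
class ComponentSelectionRule:
    """How many principal components to keep.

    ``name`` is one of scree_elbow / kaiser / horn / explained_variance.
    ``threshold`` is the cumulative-percentage target for explained_variance.
    ``kaiser_cutoff`` is "mean" (eigenvalues above the mean eigenvalue; the
    covariance-PCA analogue of the classical rule) or "one" (the classical
    lambda > 1, appropriate for correlation-matrix PCA).  The Horn settings
    control the parallel-analysis null: i.i.d. Gaussian matrices matched in
    shape and per-column variance.
    """

    name: str = "explained_variance"
    threshold: float = 95.0
    kaiser_cutoff: str = "mean"
    horn_replicates: int = 200
    horn_percentile: float = 95.0
    horn_seed: int | None = 0

    def __post_init__(self) -> None:
        if self.name not in SELECTION_RULES:
            raise ValueError(
                f"unknown rule {self.name!r}; choose from {SELECTION_RULES}"
            )
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100]")


def _scree_elbow(lam: np.ndarray) -> int:
    # keep the components before the flattening point: the flattening point is
    # the eigenvalue of maximum curvature (second difference), and everything
    # from it on is tail
    if lam.size < 3:
        return 1
    d2 = lam[:-2] - 2 * lam[1:-1] + lam[2:]  # curvature centered at lam[i+1]
    return int(np.argmax(d2)) + 1


def _horn(result: PCAResult, rule: ComponentSelectionRule) -> int:
    rng = np.random.default_rng(rule.horn_seed)
    n, L = result.n_samples, result.n_levels
    sd = np.sqrt(np.clip(result.column_variances, 0.0, None))
    null = np.empty((rule.horn_replicates, L))
    for r in range(rule.horn_replicates):
        z = rng.normal(size=(n, L)) * sd
        zc = z - z.mean(axis=0)
        ev = np.linalg.eigvalsh((zc.T @ zc) / n)
        null[r] = ev[::-1]
    cut = np.percentile(null, rule.horn_percentile, axis=0)
    k = 0
    for lam_i, cut_i in zip(result.eigenvalues, cut):
        if lam_i > cut_i:
            k += 1
        else:
            break
    return max(k, 1)


def select_n_components(result: PCAResult, rule: ComponentSelectionRule) -> int:
    """Apply one component-count selection rule; returns k in [1, L]."""
    lam = result.eigenvalues
    if rule.name == "explained_variance":
        cum = np.cumsum(result.variance_pct)
        hit = np.flatnonzero(cum >= rule.threshold - 1e-12)
        return int(hit[0]) + 1 if hit.size else result.n_levels
    if rule.name == "kaiser":
        cutoff = 1.0 if rule.kaiser_cutoff == "one" else float(lam.mean())
        return max(int(np.sum(lam > cutoff)), 1)
    if rule.name == "scree_elbow":
        return _scree_elbow(lam)
    if rule.name == "horn":
        return _horn(result, rule)
    raise AssertionError(rule.name)  # pragma: no cover


def project(result: PCAResult, k: int) -> np.ndarray:
    """First k principal-component scores, shape k x N."""
    if not 1 <= k <= result.n_levels:
        raise ValueError(f"k must be in [1, {result.n_levels}], got {k}")
    return result.scores[:k]


def reconstruct(result: PCAResult, k: int | None = None) -> np.ndarray:
    """Invert the projection; with k = L this recovers the data exactly."""
    k = result.n_levels if k is None else k
    return (result.eigenvectors[:, :k] @ result.scores[:k]).T + result.mean
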