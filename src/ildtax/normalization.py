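"""Seven spike-count normalization methods and the prototype test bench.

Normalization rescales each cell's 13-point ILD function before PCA and
clustering.  Which rescaling is appropriate for spike-count tuning curves is
an empirical question, answered here by a "test bench": all seven methods are
applied to a library of perturbed idealized ILD functions and scored for how
well they preserve shape while compressing the dynamic range.

With ``X_n(i,j)`` the raw count of cell n at level j, ``mu_n`` / ``sigma_n``
the mean / SD over that cell's levels, the methods are:

====  ===============  =================================================
 id   name             formula
====  ===============  =================================================
 1    mean_correction  V = X - mu_n
 2    global_max       V = X / max over the whole matrix
 3    vector_max       V = X / max over the cell's own levels
 4    vector_sd        V = X / sigma_n
 5    log2_mean        V = log2(X) - log2(mu_n)
 6    utpm             V = X * mu_n / sum_j X_n(., j)
 7    zscore           V = (X - mu_n) / sigma_n
====  ===============  =================================================

UTPM ("unit total probability mass") with per-cell mean and per-cell sum
reduces algebraically to division by the number of levels L, a uniform
rescaling of the whole matrix: mu_n = (sum_j X)/L, so V = X/L.  A variant
using the grand mean instead of the per-cell mean is available via
``utpm_mean="grand"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ILDDataset, ILDFunction

__all__ = [
    "NormalizationMethod",
    "NormalizedDataset",
    "BenchReport",
    "METHODS",
    "METHOD_NAMES",
    "get_method",
    "normalize",
    "normalize_matrix",
    "bench_evaluate",
    "select_method",
]


@dataclass(frozen=True)
class NormalizationMethod:
    id: int
    name: str
    description: str
    per_cell: bool  # computable from one cell's vector alone


METHODS: tuple[NormalizationMethod, ...] = (
    NormalizationMethod(1, "mean_correction", "subtract each vector's mean", True),
    NormalizationMethod(2, "global_max", "divide by the matrix-wide maximum", False),
    NormalizationMethod(3, "vector_max", "divide by each vector's maximum", True),
    NormalizationMethod(4, "vector_sd", "divide by each vector's SD", True),
    NormalizationMethod(5, "log2_mean", "log2 of counts minus log2 of vector mean", True),
    NormalizationMethod(6, "utpm", "unit total probability mass", True),
    NormalizationMethod(7, "zscore", "per-vector standardization", True),
)
METHOD_NAMES = tuple(m.name for m in METHODS)
_BY_NAME = {m.name: m for m in METHODS}
_BY_ID = {m.id: m for m in METHODS}


def get_method(key: int | str | NormalizationMethod) -> NormalizationMethod:
    if isinstance(key, NormalizationMethod):
        return key
    if isinstance(key, int):
        if key not in _BY_ID:
            raise KeyError(f"no normalization method with id {key}")
        return _BY_ID[key]
    if key not in _BY_NAME:
        raise KeyError(f"unknown normalization method {key!r}")
    return _BY_NAME[key]


@dataclass
class NormalizedDataset:
    """Matrix of normalized values, same shape as its source dataset."""

    matrix: np.ndarray
    method: NormalizationMethod
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(~np.isfinite(self.matrix)):
            raise ValueError("normalized matrix contains non-finite values")


def normalize_matrix(
    x: np.ndarray,
    method: int | str | NormalizationMethod,
    utpm_mean: str = "vector",
    row_names: list[str] | None = None,
) -> np.ndarray:
    """Apply one normalization method to an N x L count matrix."""
    method = get_method(method)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("input must be a non-empty 2-D matrix")
    names = row_names or [f"row {i}" for i in range(x.shape[0])]

    def _fail(i: int, why: str) -> ValueError:
        return ValueError(f"{method.name}: {why} in {names[i]}")

    mu = x.mean(axis=1, keepdims=True)
    if method.name == "mean_correction":
        return x - mu
    if method.name == "global_max":
        gmax = x.max()
        if gmax <= 0:
            raise ValueError("global_max: matrix maximum is not positive")
        return x / gmax
    if method.name == "vector_max":
        vmax = x.max(axis=1, keepdims=True)
        for i in np.flatnonzero(vmax.ravel() <= 0):
            raise _fail(i, "non-positive vector maximum")
        return x / vmax
    if method.name in ("vector_sd", "zscore"):
        sd = x.std(axis=1, ddof=1, keepdims=True)
        for i in np.flatnonzero(sd.ravel() == 0):
            raise _fail(i, "zero standard deviation")
        return (x - mu) / sd if method.name == "zscore" else x / sd
    if method.name == "log2_mean":
        for i in np.flatnonzero((x <= 0).any(axis=1)):
            raise _fail(i, "non-positive count (log undefined)")
        return np.log2(x) - np.log2(mu)
    if method.name == "utpm":
        rowsum = x.sum(axis=1, keepdims=True)
        for i in np.flatnonzero(rowsum.ravel() == 0):
            raise _fail(i, "zero row sum")
        m = x.mean() if utpm_mean == "grand" else mu
        return x * m / rowsum
    raise AssertionError(f"unhandled method {method.name}")  # pragma: no cover


def normalize(
    dataset: ILDDataset,
    method: int | str | NormalizationMethod,
    utpm_mean: str = "vector",
) -> NormalizedDataset:
    """Normalize a whole survey; see module docstring for the formulas."""
    method = get_method(method)
    out = normalize_matrix(
        dataset.counts, method, utpm_mean=utpm_mean, row_names=dataset.cell_ids
    )
    return NormalizedDataset(out, method, provenance=f"{dataset.n_cells}x{dataset.n_levels}")


# ---------------------------------------------------------------------------
# Test bench


@dataclass
class BenchReport:
    """Outcome of running every method over the perturbed prototype panels.

    ``cells[(method, panel)]`` holds min / max of the normalized panel, the
    Pearson shape score against the raw panel, and the compression ratio
    (normalized max over raw max).  ``method_summary[method]`` pools the
    panels: overall shape score, overall max, whether the method is
    per-cell computable, and any degenerate failure.
    """

    cells: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    method_summary: dict[str, dict] = field(default_factory=dict)
    selected: str | None = None

    def to_dict(self) -> dict:
        return {
            "cells": {f"{m}|{p}": v for (m, p), v in self.cells.items()},
            "method_summary": self.method_summary,
            "selected": self.selected,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bench_evaluate(
    prototypes: dict[str, list[ILDFunction]],
    methods: tuple[NormalizationMethod, ...] = METHODS,
) -> BenchReport:
    """Score each normalization method on the perturbed prototype panels.

    Each panel is treated as its own small dataset (its variants share one
    family).  The per-method pooled shape score is the Pearson correlation of
    all normalized values against all raw values across every panel; only
    methods that amount to a single uniform rescaling of the data keep this
    at exactly 1.
    """
    if not prototypes:
        raise ValueError("no prototype panels supplied")
    report = BenchReport()
    panel_raw = {
        panel: np.vstack([fn.counts for fn in fns]) for panel, fns in prototypes.items()
    }
    for method in methods:
        pooled_raw, pooled_norm = [], []
        error: str | None = None
        overall_max = -np.inf
        for panel, raw in panel_raw.items():
            try:
                norm = normalize_matrix(raw, method)
            except ValueError as exc:
                error = f"panel {panel}: {exc}"
                continue
            report.cells[(method.name, panel)] = {
                "min": float(norm.min()),
                "max": float(norm.max()),
                "shape_r": _pearson(norm, raw),
                "compression": float(norm.max() / raw.max()),
            }
            overall_max = max(overall_max, float(norm.max()))
            pooled_raw.append(raw.ravel())
            pooled_norm.append(norm.ravel())
        pooled_r = (
            _pearson(np.concatenate(pooled_norm), np.concatenate(pooled_raw))
            if pooled_norm
            else float("nan")
        )
        report.method_summary[method.name] = {
            "id": method.id,
            "shape_r": pooled_r,
            "max": overall_max if np.isfinite(overall_max) else float("nan"),
            "per_cell": method.per_cell,
            "error": error,
        }
    report.selected = select_method(report).name
    return report


def select_method(report: BenchReport, shape_tol: float = 0.999) -> NormalizationMethod:
    """Pick the preferred normalization method from a bench report.

    Lexicographic rule: (a) keep methods with no degenerate failures whose
    pooled shape score is >= ``shape_tol`` -- i.e. the normalization is a
    single uniform rescaling that leaves between-cell amplitude structure
    intact; (b) among those prefer methods computable from one cell alone
    (a matrix-global divisor makes a cell's normalized value depend on every
    other cell in the survey); (c) prefer the smallest normalized maximum
    (strongest dynamic-range compression); (d) break ties by lowest id.
    On the default bench this selects UTPM.
    """
    if not report.method_summary:
        raise ValueError("empty bench report")
    entries = [
        (name, s)
        for name, s in report.method_summary.items()
        if s["error"] is None and np.isfinite(s["shape_r"])
    ]
    if not entries:
        raise ValueError("every method failed on the bench")
    shape_ok = [(n, s) for n, s in entries if s["shape_r"] >= shape_tol]
    pool = shape_ok or entries
    per_cell = [(n, s) for n, s in pool if s["per_cell"]]
    pool = per_cell or pool
    name = min(pool, key=lambda ns: (ns[1]["max"], ns[1]["id"]))[0]
    return get_method(name)
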