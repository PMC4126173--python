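"""Cluster templates and their assignment to canonical ILD function types.

Averaging the member curves of each cluster yields one template ILD function
per cluster.  Each template is then assigned to one of the canonical types
seen across auditory brain areas:

* ``SIGMOID_EI`` — monotone sigmoid favouring the ipsilateral ear (EI =
  excitatory ipsilateral / inhibitory contralateral), i.e. response FALLS as
  ILD grows on this package's axis (positive ILD = contralateral louder);
* ``SIGMOID_IE`` — the mirror image, response rising with ILD;
* ``PEAKED`` — interior response maximum with a clear drop on both flanks;
* ``INSENSITIVE`` — negligible modulation across ILDs;
* three ``TRANSITION_*`` labels for shapes between these.

The type assignment is rule-based on scale-free shape statistics (modulation
depth, monotone step fraction, flank prominence), so it is invariant to
uniform rescaling of a curve, and mirroring a curve along the ILD axis swaps
EI and IE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .clustering import CCCGrid, ClusterSolution
from .core import ILDDataset
from .dimreduce import PCAResult

__all__ = [
    "ILDClass",
    "ClassRuleParams",
    "TemplateSet",
    "TaxonomyReport",
    "cluster_templates",
    "classify_ild_function",
    "build_report",
]


class ILDClass(str, Enum):
    SIGMOID_EI = "SIGMOID_EI"
    SIGMOID_IE = "SIGMOID_IE"
    PEAKED = "PEAKED"
    INSENSITIVE = "INSENSITIVE"
    TRANSITION_PEAK_SIGMOID = "TRANSITION_PEAK_SIGMOID"
    TRANSITION_PEAK_FLAT = "TRANSITION_PEAK_FLAT"
    TRANSITION_OTHER = "TRANSITION_OTHER"

    @property
    def canonical(self) -> bool:
        return not self.value.startswith("TRANSITION")


@dataclass(frozen=True)
class ClassRuleParams:
    """Thresholds of the shape-classification rule (all fractions in (0, 1)).

    ``insensitive_depth``: modulation depth (max-min)/max below which a curve
    counts as insensitive.  ``monotone_fraction``: fraction of axis steps
    that must move in one direction for a sigmoid call.
    ``peak_prominence``: minimum drop from an interior peak on BOTH flanks,
    as a fraction of the curve's range.  ``transition_margin``: slack used
    when separating peak/flat from peak/sigmoid transitions.
    """

    insensitive_depth: float = 0.25
    monotone_fraction: float = 0.9
    peak_prominence: float = 0.3
    transition_margin: float = 0.1

    def __post_init__(self) -> None:
        for name in ("insensitive_depth", "monotone_fraction", "peak_prominence", "transition_margin"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def classify_ild_function(
    curve: np.ndarray, params: ClassRuleParams | None = None
) -> ILDClass:
    """Assign one ILD curve to a canonical or transitional type."""
    p = params or ClassRuleParams()
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("curve must be 1-D with at least 3 levels")
    ymax, ymin = float(y.max()), float(y.min())
    if ymax <= 0:
        warnings.warn("all-zero curve classified as INSENSITIVE", stacklevel=2)
        return ILDClass.INSENSITIVE
    depth = (ymax - ymin) / ymax
    if depth < p.insensitive_depth:
        return ILDClass.INSENSITIVE

    rng = ymax - ymin
    d = np.diff(y)
    tol = 0.02 * rng  # treat near-flat steps as consistent with either direction
    frac_up = float(np.mean(d >= -tol))
    frac_dn = float(np.mean(d <= tol))
    if max(frac_up, frac_dn) >= p.monotone_fraction:
        rising = y[-1] >= y[0]
        return ILDClass.SIGMOID_IE if rising else ILDClass.SIGMOID_EI

    imax = int(np.argmax(y))
    if 0 < imax < y.size - 1:
        left_drop = ymax - float(y[: imax + 1].min())
        right_drop = ymax - float(y[imax:].min())
        ok_left = left_drop >= p.peak_prominence * rng
        ok_right = right_drop >= p.peak_prominence * rng
        if ok_left and ok_right:
            # full drop on both flanks -> clean peak; elevated flanks on both
            # sides (relative to the peak) mark a peak/flat transition
            flank = max(ymax - left_drop, ymax - right_drop)
            if ymin > 0 and (flank - ymin) <= p.transition_margin * rng and ymin / ymax >= p.insensitive_depth:
                return ILDClass.TRANSITION_PEAK_FLAT
            return ILDClass.PEAKED
        if ok_left != ok_right:
            return ILDClass.TRANSITION_PEAK_SIGMOID
        return ILDClass.TRANSITION_PEAK_FLAT
    return ILDClass.TRANSITION_OTHER


@dataclass
class TemplateSet:
    """Per-cluster mean ILD functions with counts and type labels."""

    templates: np.ndarray  # k x L
    counts: np.ndarray  # members per cluster
    classes: list[ILDClass]
    levels: np.ndarray

    def __post_init__(self) -> None:
        if self.templates.shape[0] != self.counts.size or len(self.classes) != self.counts.size:
            raise ValueError("templates, counts and classes disagree on k")

    @property
    def k(self) -> int:
        return self.counts.size

    def non_insensitive_fraction(self) -> float:
        """Fraction of cells whose cluster template is not insensitive."""
        keep = np.array([c is not ILDClass.INSENSITIVE for c in self.classes])
        return float(self.counts[keep].sum() / self.counts.sum())


def cluster_templates(
    dataset: ILDDataset,
    solution: ClusterSolution,
    params: ClassRuleParams | None = None,
) -> TemplateSet:
    """Average the member curves of each cluster and classify the means."""
    labels = solution.labels
    if labels.size != dataset.n_cells:
        raise ValueError("solution does not cover the dataset")
    k = solution.k
    templates = np.empty((k, dataset.n_levels))
    counts = np.empty(k, dtype=int)
    for c in range(1, k + 1):
        members = dataset.counts[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        templates[c - 1] = members.mean(axis=0)
        counts[c - 1] = members.shape[0]
    classes = [classify_ild_function(t, params) for t in templates]
    return TemplateSet(templates, counts, classes, dataset.axis.levels.copy())


@dataclass
class TaxonomyReport:
    """End-to-end summary of one classification run."""

    normalization: str
    variance_pct: list[float]
    n_components: int
    metric: str
    linkage: str
    ccc: float
    k: int
    counts: list[int]
    classes: list[str]
    templates: list[list[float]]
    levels: list[float]
    scores: list[list[float]] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TaxonomyReport":
        return cls(**json.loads(text))


def build_report(
    templates: TemplateSet,
    grid: CCCGrid,
    pca_result: PCAResult,
    solution: ClusterSolution,
    normalization: str = "utpm",
    n_components: int = 3,
) -> TaxonomyReport:
    """Assemble the structured run report from the pipeline components."""
    if solution.labels.size != pca_result.scores.shape[1]:
        raise ValueError("cluster solution and PCA scores disagree on N")
    if templates.counts.sum() != solution.labels.size:
        raise ValueError("template member counts do not sum to N")
    metric, link = grid.best
    return TaxonomyReport(
        normalization=normalization,
        variance_pct=[float(v) for v in pca_result.variance_pct],
        n_components=n_components,
        metric=metric,
        linkage=link,
        ccc=grid.value(metric, link),
        k=templates.k,
        counts=[int(c) for c in templates.counts],
        classes=[c.value for c in templates.classes],
        templates=[[float(v) for v in row] for row in templates.templates],
        levels=[float(v) for v in templates.levels],
        scores=[[float(v) for v in row] for row in pca_result.scores[:n_components]],
        labels=[int(v) for v in solution.labels],
    )
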