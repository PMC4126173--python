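"""Synthetic ILD sensitivity functions.

Two generators live here:

* ``make_prototypes`` builds the nine-panel library of idealized ILD functions
  (sigmoids, peaked, transitional and insensitive shapes on a 0-100
  spikes/stimulus scale) used as the normalization test bench, together with
  ``perturb`` which applies the small additive deformation that makes them
  look like recorded data.
* ``simulate_survey`` builds a whole surrogate survey of N cells with planted
  cluster structure, so the full classification pipeline can be exercised and
  scored against known ground truth.

Parametric forms: sigmoids are logistic curves ``m / (1 + exp(-(x - x0)/s))``,
peaked shapes are Gaussians ``m * exp(-(x - x0)^2 / (2 w^2))``, insensitive
shapes are constants, and transitional shapes are convex blends of these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ILDAxis, ILDDataset, ILDFunction, make_axis

__all__ = [
    "PrototypeSpec",
    "PerturbationConfig",
    "SurveyConfig",
    "PANELS",
    "make_prototypes",
    "perturb",
    "perturb_panels",
    "default_survey_templates",
    "simulate_survey",
    "STUDY_PROPORTIONS",
]

# Membership counts of the seven clusters in the original 208-cell survey.
STUDY_PROPORTIONS: tuple[int, ...] = (61, 19, 36, 25, 21, 11, 35)

PANELS = tuple("ABCDEFGHI")


def _sigmoid(x: np.ndarray, m: float, x0: float, s: float, sign: int = 1) -> np.ndarray:
    return m / (1.0 + np.exp(-sign * (x - x0) / s))

def _peak(x: np.ndarray, m: float, x0: float, w: float) -> np.ndarray:
    return m * np.exp(-((x - x0) ** 2) / (2.0 * w**2))


@dataclass(frozen=True)
class PrototypeSpec:
    """Parameters of one idealized ILD curve.

    ``family`` is the panel letter (A-I); ``kind`` one of sigmoid / peaked /
    flat / blend.  ``amplitude`` is the maximum response m in spikes/stimulus
    (0-100); ``position`` the sigmoid midpoint or peak centre in dB;
    ``width`` the sigmoid slope constant or Gaussian SD in dB; ``blend``
    the convex weight of the peaked component for transitional shapes;
    ``partner`` names what the peak blends into (sigmoid or flat).
    """

    family: str
    kind: str
    amplitude: float
    position: float = 0.0
    width: float = 5.0
    blend: float = 1.0
    sign: int = 1
    partner: str = "sigmoid"

    def realize(self, axis: ILDAxis) -> np.ndarray:
        if not 0 <= self.amplitude:
            raise ValueError("amplitude must be non-negative")
        x = axis.levels
        if self.kind == "sigmoid":
            return _sigmoid(x, self.amplitude, self.position, self.width, self.sign)
        if self.kind == "peaked":
            return _peak(x, self.amplitude, self.position, self.width)
        if self.kind == "flat":
            return np.full(x.shape, self.amplitude)
        if self.kind == "blend":
            peak = _peak(x, self.amplitude, self.position, self.width)
            if self.partner == "flat":
                other = np.full(x.shape, 0.45 * self.amplitude)
            else:
                other = _sigmoid(x, self.amplitude, self.position - 5.0, self.width, self.sign)
            return self.blend * peak + (1.0 - self.blend) * other
        raise ValueError(f"unknown prototype kind {self.kind!r}")


def prototype_specs(m_max: float = 100.0) -> dict[str, list[PrototypeSpec]]:
    """Per-panel parameter grids for the nine-panel prototype library.

    Each panel varies one feature of one of the four canonical ILD shapes:
    A/B/C sigmoids varying amplitude, cut-off position and slope; D/E/F
    peaked functions varying amplitude, position and position-plus-width;
    G peaked-to-sigmoid and H peaked-to-flat transitions; I constants of
    varying amplitude.
    """
    m = m_max
    specs: dict[str, list[PrototypeSpec]] = {
        "A": [PrototypeSpec("A", "sigmoid", a, 0.0, 5.0) for a in (0.25 * m, 0.5 * m, 0.75 * m, m)],
        "B": [PrototypeSpec("B", "sigmoid", m, x0, 5.0) for x0 in (-10.0, 0.0, 10.0)],
        "C": [PrototypeSpec("C", "sigmoid", m, 0.0, s) for s in (2.5, 5.0, 10.0)],
        "D": [PrototypeSpec("D", "peaked", a, 0.0, 8.0) for a in (0.25 * m, 0.5 * m, 0.75 * m, m)],
        "E": [PrototypeSpec("E", "peaked", m, x0, 8.0) for x0 in (-10.0, 0.0, 10.0)],
        "F": [
            PrototypeSpec("F", "peaked", m, x0, w)
            for x0, w in ((-10.0, 5.0), (0.0, 8.0), (10.0, 12.0))
        ],
        "G": [PrototypeSpec("G", "blend", m, 0.0, 8.0, lam, partner="sigmoid") for lam in (0.35, 0.65)],
        "H": [PrototypeSpec("H", "blend", m, 0.0, 8.0, lam, partner="flat") for lam in (0.35, 0.65)],
        "I": [PrototypeSpec("I", "flat", a) for a in (0.25 * m, 0.5 * m, 0.75 * m, m)],
    }
    return specs


def make_prototypes(
    axis: ILDAxis | None = None, m_max: float = 100.0
) -> dict[str, list[ILDFunction]]:
    """Realize the nine prototype panels on ``axis`` (default 13-level grid).

    Returns a dict mapping panel letter (A-I) to its variant curves.  All
    values lie in [0, m_max]; sigmoid variants are monotone, peaked variants
    have a strict interior maximum, insensitive variants are constant.
    """
    if m_max <= 0:
        raise ValueError("m_max must be positive")
    axis = axis if axis is not None else make_axis()
    out: dict[str, list[ILDFunction]] = {}
    for panel, specs in prototype_specs(m_max).items():
        out[panel] = [
            ILDFunction(f"{panel}.v{i + 1}", spec.realize(axis), axis)
            for i, spec in enumerate(specs)
        ]
    return out


@dataclass(frozen=True)
class PerturbationConfig:
    """Additive uniform deformation of an idealized curve.

    ``fraction`` is the half-range as a fraction of the curve's amplitude
    scale m (default 0.06, i.e. up to +-6 spikes on a 100-spike curve);
    ``floor`` is the minimum permitted value after perturbation -- set it
    strictly positive when a log normalization will be applied downstream.
    """

    fraction: float = 0.06
    seed: int | None = None
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")


def perturb(
    fn: ILDFunction,
    cfg: PerturbationConfig,
    m: float | None = None,
    rng: np.random.Generator | None = None,
) -> ILDFunction:
    """Perturb each of the curve's values by an independent uniform draw.

    Draws one number per ILD level, uniform in [-fraction, +fraction], scales
    it by the amplitude ``m`` (default: the curve's own maximum) and adds it,
    then clamps at ``cfg.floor`` so the result stays valid for every
    normalization method (a zero count would break the log method).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scale = float(np.max(fn.counts)) if m is None else float(m)
    u = rng.uniform(-cfg.fraction, cfg.fraction, size=fn.counts.size)
    new = np.maximum(fn.counts + u * scale, cfg.floor)
    return ILDFunction(fn.cell_id, new, fn.axis)


def perturb_panels(
    panels: dict[str, list[ILDFunction]], cfg: PerturbationConfig
) -> dict[str, list[ILDFunction]]:
    """Apply :func:`perturb` to every curve of every panel with one RNG stream."""
    rng = np.random.default_rng(cfg.seed)
    return {
        panel: [perturb(fn, cfg, rng=rng) for fn in fns] for panel, fns in panels.items()
    }


@dataclass(frozen=True)
class SurveyConfig:
    """Composition and noise model of a surrogate N-cell survey.

    Defaults reproduce the original survey's composition: 208 cells split
    into seven planted groups of 61/19/36/25/21/11/35 members.  Noise is
    additive Gaussian on spike counts truncated at zero (``noise="truncnorm"``,
    sd in spikes/stimulus) or Poisson (``noise="poisson"``); each cell's
    template is additionally scaled by a uniform amplitude jitter of
    +-``amplitude_jitter``.
    """

    n_cells: int = 208
    proportions: tuple[int, ...] = STUDY_PROPORTIONS
    amplitude_jitter: float = 0.10
    noise: str = "truncnorm"
    noise_sd: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")
        if sum(self.proportions) != self.n_cells:
            raise ValueError(
                f"proportions sum to {sum(self.proportions)}, expected {self.n_cells}"
            )
        if self.noise not in ("truncnorm", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise_sd < 0 or self.amplitude_jitter < 0:
            raise ValueError("noise_sd and amplitude_jitter must be >= 0")


def default_survey_templates(axis: ILDAxis | None = None, m: float = 100.0) -> np.ndarray:
    """Seven planted templates mirroring the shapes of the study's clusters.

    The templates trace the sigmoid -> peaked -> insensitive continuum the
    seven clusters occupy: a shallow falling (EI) sigmoid, a sigmoid/peak
    transition, a steep rising (IE) sigmoid, a broad and a narrow peak, a
    peak arising from an elevated baseline, and a flat (insensitive) curve.
    """
    axis = axis if axis is not None else make_axis()
    x = axis.levels
    t = np.vstack(
        [
            _sigmoid(x, 0.80 * m, -5.0, 8.0, sign=-1),          # 1: shallow EI sigmoid
            0.35 * _peak(x, m, 0.0, 8.0)
            + 0.65 * _sigmoid(x, m, -5.0, 5.0),                 # 2: sigmoid/peak transition
            _sigmoid(x, m, 5.0, 3.0),                           # 3: steep IE sigmoid
            _peak(x, 0.90 * m, 0.0, 12.0),                      # 4: broad peak
            _peak(x, m, 5.0, 6.0),                              # 5: narrow peak
            0.40 * m + 0.60 * _peak(x, m, -5.0, 8.0),           # 6: arisen peak
            np.full(x.shape, 0.50 * m),                         # 7: insensitive
        ]
    )
    return t


def simulate_survey(
    cfg: SurveyConfig,
    templates: np.ndarray | None = None,
    axis: ILDAxis | None = None,
) -> tuple[ILDDataset, np.ndarray]:
    """Simulate a survey of noisy realizations of planted templates.

    Returns the dataset (rows grouped by planted template, in template order)
    and the planted group label (1-based) of every row.  Bit-reproducible
    under a fixed ``cfg.seed``.
    """
    axis = axis if axis is not None else make_axis()
    if templates is None:
        templates = default_survey_templates(axis)
    templates = np.asarray(templates, dtype=float)
    if templates.shape[0] < len(cfg.proportions):
        raise ValueError(
            f"{templates.shape[0]} templates cannot cover "
            f"{len(cfg.proportions)} planted groups"
        )
    if templates.shape[1] != len(axis):
        raise ValueError("template length does not match axis")

    rng = np.random.default_rng(cfg.seed)
    rows, labels = [], []
    for g, count in enumerate(cfg.proportions):
        base = templates[g]
        for _ in range(count):
            gain = 1.0 + rng.uniform(-cfg.amplitude_jitter, cfg.amplitude_jitter)
            mean = gain * base
            if cfg.noise == "poisson":
                row = rng.poisson(mean).astype(float)
            else:
                row = mean + rng.normal(0.0, cfg.noise_sd, size=mean.size)
            rows.append(np.maximum(row, 0.0))
            labels.append(g + 1)
    counts = np.vstack(rows)
    if np.all(counts.max(axis=1) == 0):
        warnings.warn("simulated survey is entirely zero", stacklevel=2)
    ds = ILDDataset(counts, axis)
    return ds, np.asarray(labels, dtype=int)
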