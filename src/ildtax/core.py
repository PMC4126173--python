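"""Core containers: the ILD axis, single sensitivity functions and cell surveys.

An ILD (interaural level difference) sensitivity function is a neuron's spike
count per stimulus sampled at a fixed grid of level differences between the two
ears.  The convention throughout this package is that positive ILDs mean the
sound was louder in the ear contralateral to the recorded side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ILDAxis", "ILDFunction", "ILDDataset", "make_axis"]


@dataclass(frozen=True)
class ILDAxis:
    """Ordered grid of ILD values in dB.

    Positive values denote the contralateral ear being louder.  The grid must
    be strictly increasing and uniformly spaced with at least two levels.
    """

    levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if levels.ndim != 1 or levels.size < 2:
            raise ValueError("axis needs at least two ILD levels")
        diffs = np.diff(levels)
        if np.any(diffs <= 0):
            raise ValueError("ILD levels must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
            raise ValueError("ILD levels must be uniformly spaced")

    def __len__(self) -> int:
        return self.levels.size

    @property
    def step(self) -> float:
        return float(self.levels[1] - self.levels[0])


def make_axis(lo_db: float = -30.0, hi_db: float = 30.0, step_db: float = 5.0) -> ILDAxis:
    """Build a uniform ILD axis from ``lo_db`` to ``hi_db`` inclusive.

    The default is the standard 13-level grid from -30 to +30 dB in 5 dB
    steps.  The span must be an integer multiple of the step.

    >>> len(make_axis(-30, 30, 5))
    13
    """
    if not lo_db < hi_db:
        raise ValueError(f"need lo_db < hi_db, got {lo_db} >= {hi_db}")
    if step_db <= 0:
        raise ValueError(f"step_db must be positive, got {step_db}")
    n_steps = (hi_db - lo_db) / step_db
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"range {hi_db - lo_db} dB is not divisible by step {step_db} dB"
        )
    n = int(round(n_steps)) + 1
    return ILDAxis(np.linspace(lo_db, hi_db, n))


@dataclass
class ILDFunction:
    """One cell's spike counts (spikes/stimulus) along an ILD axis."""

    cell_id: str
    counts: np.ndarray
    axis: ILDAxis

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size != len(self.axis):
            raise ValueError(
                f"cell {self.cell_id}: {self.counts.size} counts for "
                f"{len(self.axis)} axis levels"
            )
        if np.any(~np.isfinite(self.counts)):
            raise ValueError(f"cell {self.cell_id}: non-finite spike count")
        if np.any(self.counts < 0):
            raise ValueError(f"cell {self.cell_id}: negative spike count")


@dataclass
class ILDDataset:
    """N cells x L ILD levels spike-count matrix tied to one axis."""

    counts: np.ndarray
    axis: ILDAxis
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (cells x levels)")
        if self.counts.shape[1] != len(self.axis):
            raise ValueError(
                f"matrix has {self.counts.shape[1]} columns for "
                f"{len(self.axis)} axis levels"
            )
        if not self.cell_ids:
            self.cell_ids = [f"cell{i + 1:03d}" for i in range(self.counts.shape[0])]
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length does not match row count")
        if np.any(~np.isfinite(self.counts)):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_levels(self) -> int:
        return self.counts.shape[1]

    def function(self, i: int) -> ILDFunction:
        return ILDFunction(self.cell_ids[i], self.counts[i], self.axis)

    def __iter__(self):
        return (self.function(i) for i in range(self.n_cells))
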