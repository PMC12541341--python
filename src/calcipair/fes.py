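"""Regular-grid free-energy surfaces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FESAxis:
    """One axis of a free-energy grid: name plus uniform bin edges (CV units)."""

    name: str
    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("axis needs at least two bin edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def linear(cls, name: str, lo: float, hi: float, nbins: int) -> "FESAxis":
        return cls(name, np.linspace(lo, hi, nbins + 1))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def nbins(self) -> int:
        return self.edges.size - 1

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class FESGrid:
    """Free energy on a regular 1D/2D/... grid.

    ``values`` holds the free energy in kJ/mol; unvisited bins are NaN (never
    silently zero).  ``counts`` optionally carries the raw per-bin sample
    counts from which the surface was estimated.  When ``min_subtracted`` is
    set, the minimum over visited bins is exactly zero.
    """

    axes: list[FESAxis]
    values: np.ndarray
    counts: np.ndarray | None = None
    min_subtracted: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        shape = tuple(ax.nbins for ax in self.axes)
        if values.shape != shape:
            raise ValueError(f"values shape {values.shape} does not match axes {shape}")
        if self.counts is not None:
            counts = np.asarray(self.counts)
            if counts.shape != shape:
                raise ValueError("counts shape must match the grid")
            self.counts = counts
        self.values = values

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.nbins for ax in self.axes)

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def bin_volume(self) -> float:
        return float(np.prod([ax.width for ax in self.axes]))

    def axis(self, name: str) -> FESAxis:
        for ax in self.axes:
            if ax.name == name:
                return ax
        raise KeyError(f"no axis named {name!r}")

    def min_subtract(self) -> "FESGrid":
        """Return a copy whose minimum over visited bins is zero."""
        if not self.visited.any():
            raise ValueError("cannot min-subtract: no visited bins")
        shifted = self.values - np.nanmin(self.values)
        return FESGrid(self.axes, shifted, counts=self.counts, min_subtracted=True)
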