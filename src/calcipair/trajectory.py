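"""Frames and trajectories of labelled point particles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .geometry import SimulationBox

#: Species labels understood by default: nuclei of the calcium carbonate /
#: water system plus Wannier-center pseudo-particles.  Subscripted variants
#: (Ow, Hw, Oc) distinguish water/carbonate atoms where needed.
DEFAULT_SPECIES = ("O", "H", "C", "Ca", "WC", "Ow", "Hw", "Oc")


def _validate_labels(labels: Sequence[str], alphabet: Sequence[str] | None) -> tuple[str, ...]:
    labels = tuple(str(s) for s in labels)
    if alphabet is not None:
        unknown = sorted(set(labels) - set(alphabet))
        if unknown:
            raise ValueError(
                f"species labels {unknown} not in declared alphabet {sorted(set(alphabet))}"
            )
    return labels


@dataclass
class Frame:
    """One time point: labelled positions in a periodic box.

    positions are in A, time in ps.  ``wrapped`` records whether coordinates
    are wrapped into the box (structure convention) or unwrapped (dynamics
    convention, required for mean squared displacements).
    """

    species: tuple[str, ...]
    positions: np.ndarray
    box: SimulationBox
    time: float = 0.0
    wrapped: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must have shape (N, 3), got {pos.shape}")
        if len(self.species) != pos.shape[0]:
            raise ValueError(
                f"{len(self.species)} species labels but {pos.shape[0]} positions"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos
        self.species = tuple(str(s) for s in self.species)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def select(self, species: str) -> np.ndarray:
        """Positions of all particles with the given label."""
        mask = np.array([s == species for s in self.species])
        return self.positions[mask]


@dataclass
class Trajectory:
    """Ordered frames with constant particle count and label order."""

    species: tuple[str, ...]
    positions: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ps
    box: SimulationBox
    wrapped: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(f"positions must have shape (F, N, 3), got {pos.shape}")
        if times.shape != (pos.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(self.species) != pos.shape[1]:
            raise ValueError("species labels must match particle count")
        if pos.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos
        self.times = times
        self.species = tuple(str(s) for s in self.species)

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise ValueError("need at least one frame")
        first = frames[0]
        for fr in frames[1:]:
            if fr.species != first.species:
                raise ValueError("all frames must share species labels and order")
            if fr.box != first.box:
                raise ValueError("all frames must share the simulation box")
        return cls(
            species=first.species,
            positions=np.stack([fr.positions for fr in frames]),
            times=np.array([fr.time for fr in frames]),
            box=first.box,
            wrapped=first.wrapped,
        )

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def __getitem__(self, i: int) -> Frame:
        return Frame(
            species=self.species,
            positions=self.positions[i],
            box=self.box,
            time=float(self.times[i]),
            wrapped=self.wrapped,
        )

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]

    def species_indices(self, species: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s == species], dtype=int)
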