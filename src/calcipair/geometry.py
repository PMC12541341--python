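"""Orthorhombic periodic boxes and minimum-image geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedGeometryError


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic cell.

    Parameters
    ----------
    edge_lengths : array-like of 3 floats
        Box edges Lx, Ly, Lz in A; strictly positive.
    periodic : tuple of 3 bools
        Periodicity flag per axis.
    """

    edge_lengths: np.ndarray
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        lengths = np.asarray(self.edge_lengths, dtype=float)
        if lengths.shape != (3,):
            raise ValueError(f"edge_lengths must have shape (3,), got {lengths.shape}")
        if not np.all(lengths > 0):
            raise ValueError(f"edge lengths must be strictly positive, got {lengths}")
        object.__setattr__(self, "edge_lengths", lengths)
        object.__setattr__(self, "periodic", tuple(bool(p) for p in self.periodic))

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "SimulationBox":
        return cls(np.full(3, float(edge)), (periodic,) * 3)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationBox):
            return NotImplemented
        return (
            np.allclose(self.edge_lengths, other.edge_lengths)
            and self.periodic == other.periodic
        )


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: SimulationBox
) -> np.ndarray:
    """Minimum-image displacement vector(s) from ``a`` to ``b``.

    Each component of the result lies in ``(-L/2, L/2]`` for periodic axes;
    non-periodic axes are returned as the plain difference.  Supports
    broadcasting over leading dimensions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    lengths = box.edge_lengths
    for axis in range(3):
        if not box.periodic[axis]:
            continue
        L = lengths[axis]
        comp = d[..., axis]
        comp = comp - L * np.round(comp / L)
        # map the -L/2 boundary onto +L/2 so components lie in (-L/2, L/2]
        comp = np.where(comp <= -L / 2, comp + L, comp)
        d[..., axis] = comp
    return d


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Euclidean norm of :func:`minimum_image_displacement`."""
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def wrap_positions(positions: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Wrap positions into ``[0, L)`` along periodic axes."""
    pos = np.array(positions, dtype=float)
    for axis in range(3):
        if box.periodic[axis]:
            L = box.edge_lengths[axis]
            pos[..., axis] = np.mod(pos[..., axis], L)
    return pos


def require_orthorhombic(lattice: np.ndarray) -> np.ndarray:
    """Validate a 3x3 lattice matrix as orthorhombic; return edge lengths.

    Raises :class:`UnsupportedGeometryError` for triclinic cells.
    """
    lattice = np.asarray(lattice, dtype=float)
    if lattice.shape != (3, 3):
        raise ValueError(f"lattice must be 3x3, got {lattice.shape}")
    off = lattice - np.diag(np.diag(lattice))
    if np.any(np.abs(off) > 1e-10):
        raise UnsupportedGeometryError(
            "non-orthorhombic (triclinic) cells are not supported; "
            f"off-diagonal lattice elements: {off[np.abs(off) > 1e-10]}"
        )
    return np.diag(lattice).copy()
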