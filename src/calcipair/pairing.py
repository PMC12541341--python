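"""From free-energy surfaces to ion-pairing thermodynamics.

The radial free energy G(r) of the pair separation contains the
configurational-entropy term -kB*T ln(4 pi r^2); removing it gives the
potential of mean force

    W(r) = G(r) + kB*T ln(4 pi r^2),

which is flat for an ideal (non-interacting) pair.  After fixing the additive
gauge so that W -> 0 as r -> infinity (either by zeroing a short-range tail
window or by matching a screened-Coulomb tail), the standard association free
energy is

    dG = -kB*T ln [ C0 * integral_0^r* 4 pi r^2 exp(-beta W(r)) dr ],

with C0 the 1 M standard concentration (one pair per ~1660 A^3) and r* the
association cutoff (Bjerrum length, 14 A by default).
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import simpson

from .errors import CalcipairError, ContractError
from .fes import FESGrid
from .units import COULOMB, ThermoState

logger = logging.getLogger(__name__)

RAW = "raw"
ZEROED_TAIL = "zeroed_tail"
COULOMB_TAIL = "coulomb_tail"


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationSpec:
    """Standard-state volume 1/C0 (A^3) and association cutoff r* (A)."""

    standard_volume: float = 1660.0
    r_star: float = 14.0

    def __post_init__(self) -> None:
        if self.standard_volume <= 0 or self.r_star <= 0:
            raise ValueError("standard volume and r* must be positive")


@dataclass(frozen=True)
class TailSpec:
    """Screened-Coulomb tail: charge product (e^2), dielectric, fit window (A)."""

    charge_product: float = -4.0
    epsilon: float = 102.0
    fit_window: tuple[float, float] = (12.0, 14.0)

    def __post_init__(self) -> None:
        if self.epsilon <= 1:
            raise ValueError("dielectric constant must exceed 1")
        if not self.fit_window[0] < self.fit_window[1]:
            raise ValueError("fit window must be increasing")


@dataclass
class RadialPMF:
    """W(r) curve with alignment state and thermodynamic context.

    ``alignment`` is one of ``raw`` (arbitrary additive gauge),
    ``zeroed_tail`` (short-range model, W = 0 on the tail window) or
    ``coulomb_tail`` (W matches the screened Coulomb tail on the window).
    Unvisited grid points are NaN.
    """

    r: np.ndarray
    w: np.ndarray
    thermo: ThermoState
    alignment: str = RAW
    tail: TailSpec | None = None
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if r.ndim != 1 or r.shape != w.shape:
            raise ValueError("r and w must be 1D arrays of equal length")
        if not np.all(r > 0) or not np.all(np.diff(r) > 0):
            raise ValueError("r grid must be positive and strictly increasing")
        if self.alignment not in (RAW, ZEROED_TAIL, COULOMB_TAIL):
            raise ValueError(f"unknown alignment state {self.alignment!r}")
        self.r = r
        self.w = w

    @property
    def aligned(self) -> bool:
        return self.alignment in (ZEROED_TAIL, COULOMB_TAIL)

    def window_mask(self, lo: float, hi: float, visited_only: bool = True) -> np.ndarray:
        mask = (self.r >= lo) & (self.r <= hi)
        if visited_only:
            mask &= np.isfinite(self.w)
        return mask


# ---------------------------------------------------------------------------
# entropy correction and tail alignment
# ---------------------------------------------------------------------------


def entropy_correct(fes: FESGrid | tuple[np.ndarray, np.ndarray], thermo: ThermoState) -> RadialPMF:
    """Remove the radial configurational entropy: W(r) = G(r) + kB*T ln(4 pi r^2).

    Accepts a 1D FESGrid over the separation r (bin centers are used) or a
    plain ``(r, G)`` pair.  The additive gauge of G is preserved; the result
    is a ``raw`` (unaligned) PMF.
    """
    counts = None
    if isinstance(fes, FESGrid):
        if fes.ndim != 1:
            raise ValueError("entropy_correct needs a 1D radial FES")
        r = fes.axes[0].centers
        g = fes.values
        counts = fes.counts
    else:
        r, g = np.asarray(fes[0], dtype=float), np.asarray(fes[1], dtype=float)
    if np.any(r <= 0):
        raise CalcipairError("entropy correction requires r > 0 everywhere")
    w = g + thermo.kbt * np.log(4.0 * np.pi * r**2)
    return RadialPMF(r=r, w=w, thermo=thermo, alignment=RAW, counts=counts)


def coulomb_tail(r: np.ndarray | float, tail: TailSpec, thermo: ThermoState | None = None) -> np.ndarray | float:
    """Screened Coulomb interaction E(r) = q1 q2 k_e / (eps r) in kJ/mol."""
    r_arr = np.asarray(r, dtype=float)
    e = tail.charge_product * COULOMB / (tail.epsilon * r_arr)
    return e if r_arr.ndim else float(e)


def align_tail_zero(
    pmf: RadialPMF, model_cutoff: float = 6.0, window_end: float | None = None
) -> RadialPMF:
    """Zero the short-range tail: subtract the mean of W over [2*rc, window_end].

    A short-ranged model's PMF reaches its plateau at about twice the model's
    interaction cutoff rc; after the shift the mean of W over the window is
    exactly zero.
    """
    lo = 2.0 * model_cutoff
    hi = window_end if window_end is not None else float(pmf.r[-1])
    mask = pmf.window_mask(lo, hi)
    if not mask.any():
        raise CalcipairError(f"empty alignment window [{lo}, {hi}] on the PMF grid")
    shift = float(np.mean(pmf.w[mask]))
    return replace(pmf, w=pmf.w - shift, alignment=ZEROED_TAIL, tail=None)


def align_tail_coulomb(pmf: RadialPMF, tail: TailSpec, thermo: ThermoState | None = None) -> RadialPMF:
    """Match the long-range tail to the screened Coulomb interaction.

    Subtracts the mean of [W(r) - E(r)] over the tail's fit window, so the
    aligned curve satisfies W -> E at long range (mean of W - E over the
    window is exactly zero).
    """
    lo, hi = tail.fit_window
    mask = pmf.window_mask(lo, hi)
    if not mask.any():
        raise CalcipairError(f"fit window [{lo}, {hi}] lies outside the PMF grid")
    e = coulomb_tail(pmf.r[mask], tail)
    shift = float(np.mean(pmf.w[mask] - e))
    return replace(pmf, w=pmf.w - shift, alignment=COULOMB_TAIL, tail=tail)


# ---------------------------------------------------------------------------
# association free energy
# ---------------------------------------------------------------------------


def _association_integral(pmf: RadialPMF, r_star: float) -> float:
    """Simpson quadrature of 4 pi r^2 exp(-beta W) from the first grid point
    to r*; the hard-core region below the grid contributes zero."""
    finite = np.isfinite(pmf.w)
    r = pmf.r[finite]
    w = pmf.w[finite]
    if r.size < 3:
        raise CalcipairError("too few visited PMF points for quadrature")
    if r_star > r[-1] + 1e-9:
        raise CalcipairError(
            f"r* = {r_star} lies beyond the PMF grid (max r = {r[-1]:.3f})"
        )
    sel = r <= r_star
    r_int = r[sel]
    w_int = w[sel]
    if abs(r_int[-1] - r_star) > 1e-12:
        w_star = float(np.interp(r_star, r, w))
        r_int = np.append(r_int, r_star)
        w_int = np.append(w_int, w_star)
    if r_int[0] > 1.0:
        logger.info(
            "association integral starts at r = %.3f A; the hard-core region "
            "below the first grid point contributes zero",
            r_int[0],
        )
    integrand = 4.0 * np.pi * r_int**2 * np.exp(-pmf.thermo.beta * w_int)
    return float(simpson(integrand, x=r_int))


def association_delta_g(
    pmf: RadialPMF, spec: AssociationSpec = AssociationSpec(), thermo: ThermoState | None = None
) -> float:
    """Standard ion-association free energy from an aligned PMF, kJ/mol.

    dG = -kB*T ln [ C0 * int_0^r* 4 pi r^2 e^{-beta W} dr ].  Requires the
    PMF alignment that establishes W -> 0 at infinity.
    """
    if not pmf.aligned:
        raise ContractError(
            "association_delta_g requires a tail-aligned PMF "
            "(zeroed_tail or coulomb_tail); call align_tail_zero / align_tail_coulomb first"
        )
    th = thermo if thermo is not None else pmf.thermo
    integral = _association_integral(pmf, spec.r_star)
    return float(-th.kbt * math.log(integral / spec.standard_volume))


def dielectric_rescale(
    pmf: RadialPMF,
    new_epsilon: float,
    spec: AssociationSpec = AssociationSpec(),
) -> float:
    """Change in dG from replacing the tail dielectric beyond the fit window.

    Replaces E(r; eps_old) by E(r; eps_new) for r beyond the fit-window start
    (W <- W - E_old + E_new there), recomputes the association free energy and
    returns ddG = dG_new - dG_old.
    """
    if pmf.alignment != COULOMB_TAIL or pmf.tail is None:
        raise ContractError("dielectric_rescale requires a coulomb_tail-aligned PMF")
    old = association_delta_g(pmf, spec)
    tail_new = replace(pmf.tail, epsilon=new_epsilon)
    beyond = pmf.r >= pmf.tail.fit_window[0]
    w_new = pmf.w.copy()
    w_new[beyond] += coulomb_tail(pmf.r[beyond], tail_new) - coulomb_tail(
        pmf.r[beyond], pmf.tail
    )
    rescaled = replace(pmf, w=w_new, tail=tail_new)
    return association_delta_g(rescaled, spec) - old


# ---------------------------------------------------------------------------
# basins and barriers on FES grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasinLocation:
    """A local FES minimum: grid index, CV position, free energy, plateau flag."""

    index: tuple[int, ...]
    position: tuple[float, ...]
    depth: float
    plateau: bool = False


def locate_basins(fes: FESGrid, search_radius: int = 2) -> list[BasinLocation]:
    """Local minima of the FES over the visited region, sorted by depth.

    A bin is a basin if it attains the minimum over its (2*radius+1)^d
    neighbourhood; plateau ties are resolved to the lowest flat index and
    flagged.  A constant surface has no basins (a warning is logged).
    """
    from scipy.ndimage import minimum_filter

    values = np.where(fes.visited, fes.values, np.inf)
    if not np.isfinite(values).any():
        logger.warning("locate_basins: no visited bins")
        return []
    if np.nanmax(fes.values) - np.nanmin(fes.values) < 1e-12:
        logger.warning("locate_basins: constant surface, no basins")
        return []
    size = 2 * search_radius + 1
    local_min = minimum_filter(values, size=size, mode="nearest")
    is_min = (values == local_min) & np.isfinite(values)
    basins: list[BasinLocation] = []
    seen_plateaus: set[tuple[int, ...]] = set()
    for index in np.argwhere(is_min):
        index = tuple(int(i) for i in index)
        # plateau: another flat minimum within the neighbourhood
        neighbours = []
        for dim, i in enumerate(index):
            for off in (-1, 1):
                j = i + off
                if 0 <= j < fes.shape[dim]:
                    neighbours.append(index[:dim] + (j,) + index[dim + 1 :])
        plateau = any(
            np.isfinite(values[nb]) and values[nb] == values[index] for nb in neighbours
        )
        if plateau:
            flat_key = (round(float(values[index]), 12),)
            if flat_key in seen_plateaus:
                continue  # keep only the lowest-index bin of a flat run
            seen_plateaus.add(flat_key)
        position = tuple(float(ax.centers[i]) for ax, i in zip(fes.axes, index))
        basins.append(BasinLocation(index, position, float(values[index]), plateau))
    basins.sort(key=lambda b: (b.depth, b.index))
    return basins


def _as_index_set(fes: FESGrid, region) -> list[tuple[int, ...]]:
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return [tuple(int(i) for i in idx) for idx in np.argwhere(region)]
    out = []
    for idx in region:
        if np.isscalar(idx):
            idx = (idx,)
        out.append(tuple(int(i) for i in idx))
    return out


def minimax_barrier(
    fes: FESGrid, region_a, region_b
) -> tuple[float, float, list[tuple[int, ...]]]:
    """Minimax transition barrier between two bin sets on the grid.

    Over all 4-connected paths through visited bins from A to B, the minimum
    over paths of the maximum free energy en route (the exact discrete pass
    value, found by priority flooding), minus the minimum free energy over A.
    Returns ``(barrier, pass_value, path)``.  Disconnected regions give an
    infinite barrier (flagged by the +inf return).
    """
    a_set = _as_index_set(fes, region_a)
    b_set = _as_index_set(fes, region_b)
    if not a_set or not b_set:
        raise ValueError("regions A and B must be nonempty")
    values = fes.values
    for idx in a_set + b_set:
        if not np.isfinite(values[idx]):
            raise ValueError(f"region bin {idx} is unvisited")
    f_a_min = min(values[idx] for idx in a_set)
    b_lookup = set(b_set)
    overlap = b_lookup & set(a_set)
    if overlap:
        # already in B: the trivial path has no barrier
        start = min(overlap, key=lambda idx: values[idx])
        return 0.0, f_a_min, [start]

    # Dijkstra-style flood where the path cost is the running maximum of F.
    best: dict[tuple[int, ...], float] = {}
    parent: dict[tuple[int, ...], tuple[int, ...] | None] = {}
    heap: list[tuple[float, tuple[int, ...]]] = []
    for idx in a_set:
        cost = float(values[idx])
        if cost < best.get(idx, math.inf):
            best[idx] = cost
            parent[idx] = None
            heapq.heappush(heap, (cost, idx))
    shape = fes.shape
    target: tuple[int, ...] | None = None
    while heap:
        cost, idx = heapq.heappop(heap)
        if cost > best.get(idx, math.inf):
            continue
        if idx in b_lookup:
            target = idx
            break
        for dim in range(len(shape)):
            for off in (-1, 1):
                j = idx[dim] + off
                if not 0 <= j < shape[dim]:
                    continue
                nb = idx[:dim] + (j,) + idx[dim + 1 :]
                if not np.isfinite(values[nb]):
                    continue
                new_cost = max(cost, float(values[nb]))
                if new_cost < best.get(nb, math.inf):
                    best[nb] = new_cost
                    parent[nb] = idx
                    heapq.heappush(heap, (new_cost, nb))
    if target is None:
        logger.warning("minimax_barrier: regions are disconnected in the visited region")
        return math.inf, math.inf, []
    path = []
    node: tuple[int, ...] | None = target
    while node is not None:
        path.append(node)
        node = parent[node]
    path.reverse()
    pass_value = best[target]
    return pass_value - f_a_min, pass_value, path


def state_free_energy_difference(
    fes: FESGrid, region_a, region_b, thermo: ThermoState
) -> float:
    """Free-energy difference between integrated grid regions:
    dF = -kB*T ln [ sum_B e^{-beta F} / sum_A e^{-beta F} ] (equal bin volumes
    cancel; unvisited bins carry zero weight)."""
    a_set = _as_index_set(fes, region_a)
    b_set = _as_index_set(fes, region_b)
    if not a_set or not b_set:
        raise ValueError("regions A and B must be nonempty")

    def _weight(idx_set):
        total = 0.0
        for idx in idx_set:
            v = fes.values[idx]
            if np.isfinite(v):
                total += math.exp(-thermo.beta * v) * fes.bin_volume
        return total

    za, zb = _weight(a_set), _weight(b_set)
    if za == 0 or zb == 0:
        raise CalcipairError("a region has zero Boltzmann weight (all bins unvisited)")
    return float(-thermo.kbt * math.log(zb / za))
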