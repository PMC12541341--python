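"""Synthetic-data generators with the statistical structure the analysis
pipeline assumes.

These generators replace production molecular dynamics at desk scale:

* overdamped (Euler--Maruyama) Langevin dynamics on model potentials,
* a single-relative-coordinate emulation of the ion pair whose 4*pi*r^2
  entropic factor arises naturally from 3D dynamics,
* Brownian trajectories with known diffusion coefficient,
* two-state residence kinetics with exponential dwell times,
* layered interfacial atom distributions,
* committee force predictions with controlled disagreement,
* an analytic two-valley proton-transfer free-energy surface.

Every generator is a pure function of its seed: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np

from .cvtable import CVRecordTable
from .geometry import SimulationBox
from .switching import SwitchSpec, switch_cubic, switch_cubic_derivative
from .trajectory import Trajectory
from .units import COULOMB, ThermoState

logger = logging.getLogger(__name__)

#: 1 cm^2/s expressed in A^2/ps (1e-5 cm^2/s = 0.1 A^2/ps)
CM2_PER_S_TO_A2_PER_PS = 1e4


# ---------------------------------------------------------------------------
# model pair potential
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Basin:
    """Gaussian well (depth > 0) or bump (depth < 0) at ``center`` (A)."""

    center: float
    depth: float  # kJ/mol; positive depths are attractive wells
    width: float  # A

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"basin width must be positive, got {self.width}")


@dataclass(frozen=True)
class ModelPairPotential:
    """Radial model potential: Gaussian basins + screened-Coulomb tail + r^-12 core.

    The tail is ``charge_product * COULOMB / (epsilon * r)``; in ``truncated``
    mode it is switched off smoothly between ``cutoff`` and ``2 * cutoff``
    (mimicking a short-ranged model whose PMF reaches zero at about twice its
    interaction cutoff).  The inner core ``(r_in / r)^12`` keeps the potential
    monotonically repulsive below the first basin; ``inner_wall_radius`` is the
    radius at which the core reaches 1 kJ/mol.
    """

    basins: tuple[Basin, ...]
    charge_product: float = 0.0  # units of e^2
    epsilon: float = 1e30  # dielectric; huge value = no tail
    tail_mode: str = "none"  # none | full | truncated
    cutoff: float = 6.0  # A, truncation switch D0 (Dmax = 2 * cutoff)
    inner_wall_radius: float = 2.77  # A

    def __post_init__(self) -> None:
        if self.tail_mode not in ("none", "full", "truncated"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.inner_wall_radius <= 0:
            raise ValueError("inner_wall_radius must be positive")

    @property
    def _tail_switch(self) -> SwitchSpec:
        return SwitchSpec(self.cutoff, 2.0 * self.cutoff)

    def tail_energy(self, r: np.ndarray | float) -> np.ndarray | float:
        """Screened-Coulomb tail E(r) = q1 q2 * k_e / (eps * r), kJ/mol."""
        r_arr = np.asarray(r, dtype=float)
        e = self.charge_product * COULOMB / (self.epsilon * r_arr)
        if self.tail_mode == "none":
            e = np.zeros_like(r_arr)
        elif self.tail_mode == "truncated":
            e = e * switch_cubic(r_arr, self._tail_switch)
        return e if r_arr.ndim else float(e)

    def energy(self, r: np.ndarray | float) -> np.ndarray | float:
        r_arr = np.asarray(r, dtype=float)
        u = (self.inner_wall_radius / r_arr) ** 12
        for b in self.basins:
            u = u - b.depth * np.exp(-((r_arr - b.center) ** 2) / (2.0 * b.width**2))
        u = u + self.tail_energy(r_arr)
        return u if r_arr.ndim else float(u)

    def force(self, r: np.ndarray | float) -> np.ndarray | float:
        """Radial force -dU/dr, kJ/mol/A."""
        r_arr = np.asarray(r, dtype=float)
        du = -12.0 * self.inner_wall_radius**12 / r_arr**13
        for b in self.basins:
            gauss = np.exp(-((r_arr - b.center) ** 2) / (2.0 * b.width**2))
            du = du + b.depth * (r_arr - b.center) / b.width**2 * gauss
        if self.tail_mode != "none":
            coef = self.charge_product * COULOMB / self.epsilon
            if self.tail_mode == "full":
                du = du - coef / r_arr**2
            else:
                sw = switch_cubic(r_arr, self._tail_switch)
                dsw = switch_cubic_derivative(r_arr, self._tail_switch)
                du = du - coef / r_arr**2 * sw + coef / r_arr * dsw
        f = -du
        return f if r_arr.ndim else float(f)

    def truncated(self) -> "ModelPairPotential":
        """Tail-truncated counterpart (short-ranged model of the same basins)."""
        return replace(self, tail_mode="truncated")


def load_preset(name: str) -> ModelPairPotential:
    """Load a named model potential from the versioned preset file."""
    text = resources.files("calcipair").joinpath("presets.json").read_text()
    data = json.loads(text)
    try:
        p = data["presets"][name]
    except KeyError as exc:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(data['presets'])}"
        ) from exc
    return ModelPairPotential(
        basins=tuple(Basin(*b) for b in p["basins"]),
        charge_product=p["charge_product"],
        epsilon=p["epsilon"],
        tail_mode=p["tail_mode"],
        cutoff=p["cutoff"],
        inner_wall_radius=p["inner_wall_radius"],
    )


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped-dynamics parameters.

    The diffusion coefficient is ``D = kB*T / friction`` (A^2/ps); the friction
    is an inverse mobility in these units.  Only the stationary distribution
    matters downstream, and it is independent of D.
    """

    temperature: float = 330.0
    friction: float = 1.0  # 1/ps
    timestep: float = 0.002  # ps
    n_steps: int = 100_000
    seed: int = 0
    dims: int = 3

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.dims not in (1, 2, 3):
            raise ValueError("dims must be 1, 2 or 3")

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(temperature=self.temperature)

    @property
    def diffusion(self) -> float:
        """D = kB*T / friction in A^2/ps (zero-temperature limit gives 0 noise)."""
        return self.thermo.kbt / self.friction

    @property
    def mobility(self) -> float:
        """beta * D = 1 / friction (step response to a force, A^2 ps / kJ mol^-1)."""
        return 1.0 / self.friction


def langevin_sample(
    potential: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    spec: LangevinSpec,
    initial: Sequence[float] | float,
    bias: Callable[[np.ndarray], float] | None = None,
    bias_gradient: Callable[[np.ndarray], np.ndarray] | None = None,
    stride: int = 10,
) -> CVRecordTable:
    """Overdamped Langevin sampling of an arbitrary scalar potential.

    Update rule: ``x <- x - beta*D*grad(U)*dt + sqrt(2*D*dt)*eta`` with
    standard-normal ``eta``.  Records positions every ``stride`` steps
    (columns ``x``[, ``y``, ``z``] plus ``d`` = |x| for dims > 1).  A static
    ``bias`` (with gradient) is added to the dynamics and recorded in the
    bias column.
    """
    x = np.atleast_1d(np.asarray(initial, dtype=float)).copy()
    if x.shape != (spec.dims,):
        raise ValueError(f"initial must have {spec.dims} components")
    g0 = np.asarray(gradient(x), dtype=float)
    if not np.all(np.isfinite(g0)):
        raise ValueError("gradient not finite at the initial point")
    if (bias is None) != (bias_gradient is None):
        raise ValueError("bias and bias_gradient must be supplied together")
    logger.info("langevin_sample: seed=%d steps=%d dims=%d", spec.seed, spec.n_steps, spec.dims)

    rng = np.random.default_rng(spec.seed)
    dt = spec.timestep
    drift = spec.mobility * dt
    noise_scale = math.sqrt(2.0 * spec.diffusion * dt)

    n_rec = spec.n_steps // stride
    rec = np.empty((n_rec, spec.dims))
    rec_t = np.empty(n_rec)
    rec_bias = np.zeros(n_rec)
    k = 0
    for step in range(1, spec.n_steps + 1):
        g = np.asarray(gradient(x), dtype=float)
        if bias_gradient is not None:
            g = g + np.asarray(bias_gradient(x), dtype=float)
        x = x - drift * g + noise_scale * rng.standard_normal(spec.dims)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e8):
            raise RuntimeError(
                f"langevin_sample diverged at step {step}: x={x}; "
                "reduce the timestep or check the gradient"
            )
        if step % stride == 0:
            rec[k] = x
            rec_t[k] = step * dt
            rec_bias[k] = 0.0 if bias is None else float(bias(x))
            k += 1
    u_final = potential(x)
    if not np.isfinite(u_final) or abs(u_final) > 1e8:
        raise RuntimeError(f"potential diverged: U={u_final}")

    cvs = {name: rec[:, i] for i, name in enumerate(["x", "y", "z"][: spec.dims])}
    if spec.dims > 1:
        cvs["d"] = np.linalg.norm(rec, axis=1)
    return CVRecordTable.from_arrays(rec_t, cvs, bias=rec_bias)


def _tabulated_radial_run(
    r_grid: np.ndarray,
    force_table: np.ndarray,
    energy_table: np.ndarray,
    spec: LangevinSpec,
    r0: float,
    stride: int,
    reflect_at: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis-adjusted overdamped dynamics (MALA) of a radial potential.

    Euler-Maruyama proposals are accepted against the tabulated total energy
    (potential + static bias + walls), so the sampled stationary distribution
    is exact for any step size; the step size only affects mixing speed.
    Returns (times, radii) recorded every ``stride`` steps.  An optional
    confining sphere at ``reflect_at`` rejects proposals beyond that radius
    (a hard boundary, exact under Metropolis).
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.timestep
    drift = spec.mobility * dt
    two_d_dt = 2.0 * spec.diffusion * dt
    noise_scale = math.sqrt(two_d_dt)
    inv_var4 = 1.0 / (2.0 * two_d_dt) if two_d_dt > 0 else 0.0
    beta = spec.thermo.beta
    r_lo = float(r_grid[0])
    inv_dr = 1.0 / float(r_grid[1] - r_grid[0])
    n_grid = r_grid.size
    ftab = force_table
    etab = energy_table

    def lookup(r: float) -> tuple[float, float]:
        u = (r - r_lo) * inv_dr
        j = int(u)
        if j < 0:
            return ftab[0], etab[0]
        if j >= n_grid - 1:
            return ftab[n_grid - 1], etab[n_grid - 1]
        w = u - j
        return (
            ftab[j] * (1.0 - w) + ftab[j + 1] * w,
            etab[j] * (1.0 - w) + etab[j + 1] * w,
        )

    x, y, z = r0, 0.0, 0.0
    s_cur = math.sqrt(x * x + y * y + z * z)
    f_cur, u_cur = lookup(s_cur)
    n_rec = spec.n_steps // stride
    rec_t = np.empty(n_rec)
    rec_r = np.empty(n_rec)
    k = 0
    n_acc = 0
    chunk = 8192
    n_done = 0
    while n_done < spec.n_steps:
        n_now = min(chunk, spec.n_steps - n_done)
        noise = rng.standard_normal((n_now, 3)) * noise_scale
        logu = np.log(rng.random(n_now))
        for i in range(n_now):
            scale = drift * f_cur / s_cur
            mx = x + scale * x
            my = y + scale * y
            mz = z + scale * z
            px = mx + noise[i, 0]
            py = my + noise[i, 1]
            pz = mz + noise[i, 2]
            s_new = math.sqrt(px * px + py * py + pz * pz)
            if reflect_at is None or s_new <= reflect_at:
                f_new, u_new = lookup(s_new)
                scale_b = drift * f_new / s_new
                bx = px + scale_b * px - x
                by = py + scale_b * py - y
                bz = pz + scale_b * pz - z
                fwd = (px - mx) ** 2 + (py - my) ** 2 + (pz - mz) ** 2
                back = bx * bx + by * by + bz * bz
                log_acc = -beta * (u_new - u_cur) - (back - fwd) * inv_var4
                if logu[i] < log_acc:
                    x, y, z = px, py, pz
                    s_cur, f_cur, u_cur = s_new, f_new, u_new
                    n_acc += 1
            step = n_done + i + 1
            if step % stride == 0:
                rec_t[k] = step * dt
                rec_r[k] = s_cur
                k += 1
        n_done += n_now
        if not math.isfinite(s_cur) or s_cur > 1e8:
            raise RuntimeError(
                f"radial dynamics diverged near step {n_done}: r={s_cur}; "
                "reduce the timestep"
            )
    logger.info(
        "radial MALA: %d/%d proposals accepted (%.1f%%)",
        n_acc, spec.n_steps, 100.0 * n_acc / max(1, spec.n_steps),
    )
    return rec_t, rec_r


def sample_radial_pair(
    potential: ModelPairPotential,
    spec: LangevinSpec,
    bias: Callable[[np.ndarray], np.ndarray] | None = None,
    r0: float | None = None,
    stride: int = 10,
    r_max: float = 18.0,
    reflect_at: float | None = None,
    walls: Sequence = (),
) -> CVRecordTable:
    """3D overdamped dynamics of the ion-pair relative coordinate.

    The pair separation d evolves under ``U(r) + bias(r)`` (bias is a static,
    vectorised function of r) plus optional harmonic walls; the 4*pi*r^2
    entropic factor arises naturally from the 3D dynamics.  Emits columns
    ``time``, ``d``, ``bias``, ``wall``.
    """
    from .sampling import harmonic_wall_energy  # deferred: avoids module cycle

    r_lo = max(0.3, 0.5 * potential.inner_wall_radius)
    r_grid = np.arange(r_lo, r_max + 0.01, 0.01)
    energy_table = np.asarray(potential.energy(r_grid), dtype=float)
    force_table = np.asarray(potential.force(r_grid), dtype=float)
    bias_table = np.zeros_like(r_grid)
    if bias is not None:
        bias_table = np.asarray(bias(r_grid), dtype=float)
        force_table = force_table - np.gradient(bias_table, r_grid)
    wall_table = np.zeros_like(r_grid)
    for wall in walls:
        wall_table = wall_table + harmonic_wall_energy(r_grid, wall)
    if walls:
        force_table = force_table - np.gradient(wall_table, r_grid)

    if r0 is None:
        r0 = float(np.clip(5.0, r_lo + 0.5, r_max - 0.5))
    if r0 <= potential.inner_wall_radius * 0.8:
        raise ValueError(
            f"initial separation {r0} is inside the repulsive core "
            f"(inner wall radius {potential.inner_wall_radius})"
        )
    logger.info("sample_radial_pair: seed=%d steps=%d", spec.seed, spec.n_steps)
    total_energy = energy_table + bias_table + wall_table
    times, radii = _tabulated_radial_run(
        r_grid, force_table, total_energy, spec, r0, stride, reflect_at
    )
    rec_bias = np.interp(radii, r_grid, bias_table)
    rec_wall = np.interp(radii, r_grid, wall_table)
    return CVRecordTable.from_arrays(times, {"d": radii}, bias=rec_bias, wall=rec_wall)


# ---------------------------------------------------------------------------
# Brownian trajectories, residence kinetics, layered interfaces
# ---------------------------------------------------------------------------


def brownian_trajectory(
    d_true: float,
    n_particles: int,
    n_steps: int,
    timestep: float,
    seed: int,
    box: SimulationBox,
    species: str = "O",
) -> Trajectory:
    """Unwrapped Brownian motion with known diffusion coefficient.

    ``d_true`` is in cm^2/s (e.g. 2.4e-5 for water oxygen); increments per
    axis are Gaussian with variance ``2 * D * dt`` where D is converted to
    A^2/ps (1e-5 cm^2/s = 0.1 A^2/ps).
    """
    if d_true < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    if n_particles < 1 or n_steps < 1:
        raise ValueError("need at least one particle and one step")
    logger.info("brownian_trajectory: seed=%d D=%g cm^2/s", seed, d_true)
    rng = np.random.default_rng(seed)
    d_a2ps = d_true * CM2_PER_S_TO_A2_PER_PS
    std = math.sqrt(2.0 * d_a2ps * timestep)
    start = rng.uniform(0.0, box.edge_lengths, size=(n_particles, 3))
    increments = rng.standard_normal((n_steps, n_particles, 3)) * std
    positions = np.concatenate(
        [start[None], start[None] + np.cumsum(increments, axis=0)], axis=0
    )
    times = np.arange(n_steps + 1) * timestep
    return Trajectory(
        species=(species,) * n_particles,
        positions=positions,
        times=times,
        box=box,
        wrapped=False,
    )


@dataclass(frozen=True)
class ResidenceSeries:
    """Bound/unbound indicator on a uniform time grid of spacing ``dt`` (ps)."""

    indicator: np.ndarray  # bool, (n_times,)
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.indicator.size) * self.dt


def two_state_residence_series(
    tau_bound: float,
    tau_free: float,
    n_events: int,
    seed: int,
    dt: float = 0.5,
) -> ResidenceSeries:
    """Alternating exponential dwells, starting bound, sampled on a dt grid.

    Contains exactly ``n_events`` bound intervals; the mean bound dwell tends
    to ``tau_bound`` as n_events grows.
    """
    if tau_bound <= 0 or tau_free <= 0:
        raise ValueError("dwell times must be positive")
    if n_events < 1:
        raise ValueError("need at least one bound interval")
    logger.info("two_state_residence_series: seed=%d", seed)
    rng = np.random.default_rng(seed)
    bound_dwells = rng.exponential(tau_bound, size=n_events)
    free_dwells = rng.exponential(tau_free, size=n_events)
    chunks = []
    for b, f in zip(bound_dwells, free_dwells):
        nb = max(1, int(round(b / dt)))
        nf = max(1, int(round(f / dt)))
        chunks.append(np.ones(nb, dtype=bool))
        chunks.append(np.zeros(nf, dtype=bool))
    return ResidenceSeries(np.concatenate(chunks), dt)


def layered_interface_frames(
    layers: Sequence[tuple[float, str, int, float]],
    lateral_box: tuple[float, float],
    n_frames: int,
    seed: int,
    z_extent: float = 30.0,
) -> Trajectory:
    """Frames of a layered interface: per layer (z_position, species, count,
    z_width) particles are Gaussian-distributed in z about the layer position
    and uniform laterally."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    logger.info("layered_interface_frames: seed=%d layers=%d", seed, len(layers))
    rng = np.random.default_rng(seed)
    lx, ly = lateral_box
    box = SimulationBox(np.array([lx, ly, z_extent]), periodic=(True, True, False))
    species: list[str] = []
    for _, sp, count, _ in layers:
        species.extend([sp] * count)
    n_atoms = len(species)
    positions = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        i = 0
        for z0, _, count, width in layers:
            positions[f, i : i + count, 0] = rng.uniform(0, lx, count)
            positions[f, i : i + count, 1] = rng.uniform(0, ly, count)
            if width > 0:
                positions[f, i : i + count, 2] = rng.normal(z0, width, count)
            else:
                positions[f, i : i + count, 2] = z0
            i += count
    return Trajectory(
        species=tuple(species),
        positions=positions,
        times=np.arange(n_frames, dtype=float),
        box=box,
        wrapped=True,
    )


# ---------------------------------------------------------------------------
# committee forces
# ---------------------------------------------------------------------------


def committee_force_sets(
    true_forces: np.ndarray,
    disagreement_scale: np.ndarray | float,
    n_models: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Per-model force predictions: truth + Gaussian noise per configuration.

    ``true_forces`` has shape (n_configs, n_atoms, 3); ``disagreement_scale``
    is the per-configuration noise standard deviation (broadcastable to
    n_configs).  Returns shape (n_models, n_configs, n_atoms, 3).
    """
    true_forces = np.asarray(true_forces, dtype=float)
    if true_forces.ndim == 2:
        true_forces = true_forces[None]
    if true_forces.ndim != 3 or true_forces.shape[-1] != 3:
        raise ValueError("true_forces must have shape (n_configs, n_atoms, 3)")
    n_cfg = true_forces.shape[0]
    scale = np.broadcast_to(np.asarray(disagreement_scale, dtype=float), (n_cfg,))
    if np.any(scale < 0):
        raise ValueError("disagreement scales must be nonnegative")
    logger.info("committee_force_sets: seed=%d models=%d configs=%d", seed, n_models, n_cfg)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_models,) + true_forces.shape)
    return true_forces[None] + noise * scale[None, :, None, None]


# ---------------------------------------------------------------------------
# proton-transfer surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtonTransferSurface:
    """Analytic model landscape over (d, n) = (cation-carbon distance,
    carbonate-oxygen protonation coordinate).

    Two valleys at n = 0 (carbonate) and n = 1 (bicarbonate) for every d; the
    interconversion saddle at n = 1/2 has height ``saddle(d)`` that is lowest
    for the tightly associated pair (d ~ 3 A) and rises past the
    solvent-separated distance (d > 6 A), plus a mild harmonic confinement
    along d.  Differentiable everywhere.
    """

    saddle_low: float = 26.0  # kJ/mol, saddle height at short d
    saddle_high: float = 46.0  # kJ/mol, saddle height at large d
    saddle_midpoint: float = 4.5  # A, where the height crosses over
    saddle_steepness: float = 0.8  # A
    d_center: float = 3.2  # A, minimum of the confinement along d
    d_curvature: float = 1.2  # kJ/mol/A^2

    def saddle(self, d: np.ndarray | float) -> np.ndarray | float:
        s = 1.0 / (1.0 + np.exp(-(np.asarray(d, dtype=float) - self.saddle_midpoint)
                                / self.saddle_steepness))
        return self.saddle_low + (self.saddle_high - self.saddle_low) * s

    def energy(self, d: np.ndarray | float, n: np.ndarray | float) -> np.ndarray | float:
        d_arr = np.asarray(d, dtype=float)
        n_arr = np.asarray(n, dtype=float)
        barrier = self.saddle(d_arr) * 16.0 * n_arr**2 * (1.0 - n_arr) ** 2
        conf = 0.5 * self.d_curvature * (d_arr - self.d_center) ** 2
        out = barrier + conf
        return out if (d_arr.ndim or n_arr.ndim) else float(out)

    def gradient(
        self, d: np.ndarray | float, n: np.ndarray | float
    ) -> tuple[np.ndarray | float, np.ndarray | float]:
        d_arr = np.asarray(d, dtype=float)
        n_arr = np.asarray(n, dtype=float)
        shape = 16.0 * n_arr**2 * (1.0 - n_arr) ** 2
        sig = 1.0 / (1.0 + np.exp(-(d_arr - self.saddle_midpoint) / self.saddle_steepness))
        dsaddle = (self.saddle_high - self.saddle_low) * sig * (1.0 - sig) / self.saddle_steepness
        dd = dsaddle * shape + self.d_curvature * (d_arr - self.d_center)
        dn = self.saddle(d_arr) * 16.0 * (2.0 * n_arr * (1.0 - n_arr) ** 2
                                          - 2.0 * n_arr**2 * (1.0 - n_arr))
        if d_arr.ndim or n_arr.ndim:
            return dd, dn
        return float(dd), float(dn)

    def as_grid(
        self,
        d_range: tuple[float, float] = (2.5, 8.0),
        n_range: tuple[float, float] = (-0.2, 1.2),
        shape: tuple[int, int] = (110, 70),
    ):
        """Evaluate on a regular grid, returned as a FESGrid."""
        from .fes import FESAxis, FESGrid

        ax_d = FESAxis.linear("d", *d_range, shape[0])
        ax_n = FESAxis.linear("n", *n_range, shape[1])
        dd, nn = np.meshgrid(ax_d.centers, ax_n.centers, indexing="ij")
        return FESGrid([ax_d, ax_n], np.asarray(self.energy(dd, nn)))


def proton_transfer_surface(**params) -> ProtonTransferSurface:
    """Construct the analytic proton-transfer landscape (see
    :class:`ProtonTransferSurface` for the tunable parameters)."""
    return ProtonTransferSurface(**params)
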