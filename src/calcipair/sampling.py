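"""OPES-style adaptive bias, harmonic walls, reweighting and run averaging.

The on-the-fly probability enhanced sampling (OPES) bias is built from a
running kernel-density estimate of the biased CV distribution,

    P(s) = sum_i w_i G(s; s_i, sigma) / sum_i w_i,   w_i = exp(beta V(s_i)),

updated every ``update_pace`` steps, with

    V(s) = (1 - 1/gamma) * kB*T * ln(P(s)/Z + eps),

``gamma = dE / kB*T`` unless overridden, and the regularisation
``eps = exp[-beta dE / (1 - 1/gamma)]`` set by the barrier parameter dE.
Fixed-bandwidth Gaussian kernels on a grid, no kernel compression.  The bias
is reported in a nonnegative gauge and its range is capped at
``(1 - 1/gamma) * dE``, so the deposited bias never exceeds the barrier
parameter.

Free-energy surfaces are recovered by umbrella-sampling-type reweighting of
the recorded bias:  F(s) = -kB*T ln < delta(s - s(R)) e^{beta V} > + const.
The reweighting CVs may differ from the biased CV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cvtable import CVRecordTable
from .errors import CalcipairError
from .fes import FESAxis, FESGrid
from .toysim import LangevinSpec, ModelPairPotential
from .units import ThermoState

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters and walls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OPESParams:
    """OPES settings: exploration barrier dE (kJ/mol), update pace (steps),
    kernel bandwidth (CV units), bias factor gamma and regularisation eps
    (both derived from dE unless overridden)."""

    barrier: float = 30.0
    update_pace: int = 500
    bandwidth: float = 0.1
    bias_factor: float | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.barrier <= 0:
            raise ValueError("barrier must be positive")
        if self.update_pace < 1:
            raise ValueError("update_pace must be >= 1")
        if self.bandwidth <= 0:
            raise ValueError("kernel bandwidth must be positive")

    def gamma(self, thermo: ThermoState) -> float:
        g = self.bias_factor if self.bias_factor is not None else self.barrier / thermo.kbt
        if g <= 1:
            raise ValueError(f"bias factor must exceed 1, got {g}")
        return g

    def eps(self, thermo: ThermoState) -> float:
        if self.epsilon is not None:
            if not 0 < self.epsilon < 1:
                raise ValueError("epsilon must lie in (0, 1)")
            return self.epsilon
        g = self.gamma(thermo)
        return math.exp(-thermo.beta * self.barrier / (1.0 - 1.0 / g))


@dataclass(frozen=True)
class WallSpec:
    """One-sided harmonic wall on a CV: zero on the allowed side,
    ``kappa * excess^2`` beyond (kappa in kJ/mol per CV-unit^2)."""

    cv: str
    location: float
    kappa: float = 20.0
    side: str = "upper"

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("wall force constant must be nonnegative")
        if self.side not in ("upper", "lower"):
            raise ValueError("side must be 'upper' or 'lower'")


def harmonic_wall_energy(value: np.ndarray | float, wall: WallSpec) -> np.ndarray | float:
    """Wall energy kappa*(excess)^2; C1-continuous at the wall location."""
    v = np.asarray(value, dtype=float)
    excess = v - wall.location if wall.side == "upper" else wall.location - v
    e = wall.kappa * np.square(np.maximum(excess, 0.0))
    return e if v.ndim else float(e)


def harmonic_wall_force(value: np.ndarray | float, wall: WallSpec) -> np.ndarray | float:
    """-dE/dvalue of the harmonic wall."""
    v = np.asarray(value, dtype=float)
    if wall.side == "upper":
        f = -2.0 * wall.kappa * np.maximum(v - wall.location, 0.0)
    else:
        f = 2.0 * wall.kappa * np.maximum(wall.location - v, 0.0)
    return f if v.ndim else float(f)


# ---------------------------------------------------------------------------
# bias state
# ---------------------------------------------------------------------------


@dataclass
class BiasState:
    """Deposited-kernel record plus the final bias on its grid."""

    grid: np.ndarray  # CV grid (bin centers) on which the bias lives
    bias: np.ndarray  # applied bias V(s) on the grid, kJ/mol, >= 0
    kernel_centers: np.ndarray
    kernel_weights: np.ndarray
    bandwidth: float
    gamma: float
    eps: float
    barrier: float
    z_norm: float
    converged: bool

    @property
    def max_bias(self) -> float:
        """Range of the deposited bias potential (its depth above the floor)."""
        if self.bias.size == 0:
            return 0.0
        return float(self.bias.max() - self.bias.min())

    def bias_at(self, s: np.ndarray | float) -> np.ndarray | float:
        out = np.interp(np.asarray(s, dtype=float), self.grid, self.bias)
        return out if np.ndim(s) else float(out)


class _OPESBias:
    """Incremental kernel-density bias on a uniform grid."""

    def __init__(self, params: OPESParams, thermo: ThermoState, lo: float, hi: float, n: int = 512):
        self.params = params
        self.beta = thermo.beta
        self.kbt = thermo.kbt
        self.gamma = params.gamma(thermo)
        self.eps = params.eps(thermo)
        self.cap = (1.0 - 1.0 / self.gamma) * params.barrier
        self.grid = np.linspace(lo, hi, n)
        self.dx = self.grid[1] - self.grid[0]
        self.prob = np.zeros(n)
        self.sum_w = 0.0
        self.s_lo = math.inf
        self.s_hi = -math.inf
        self.v = np.zeros(n)
        self.f = np.zeros(n)
        self.z = 1.0
        self.centers: list[float] = []
        self.weights: list[float] = []
        self.last_change = math.inf

    def bias_at(self, s: float) -> float:
        return float(np.interp(s, self.grid, self.v))

    def deposit(self, s: float) -> None:
        w = math.exp(min(self.beta * self.bias_at(s), 500.0))
        sigma = self.params.bandwidth
        self.prob += w * np.exp(-((self.grid - s) ** 2) / (2.0 * sigma**2))
        self.sum_w += w
        self.s_lo = min(self.s_lo, s)
        self.s_hi = max(self.s_hi, s)
        self.centers.append(s)
        self.weights.append(w)
        self._rebuild()

    def _rebuild(self) -> None:
        p = self.prob / self.sum_w
        explored = (self.grid >= self.s_lo - self.params.bandwidth) & (
            self.grid <= self.s_hi + self.params.bandwidth
        )
        if not explored.any():
            return
        self.z = float(p[explored].mean())
        v = (1.0 - 1.0 / self.gamma) * self.kbt * np.log(p / self.z + self.eps)
        # keep the natural OPES gauge (weights stay consistent across updates)
        # but floor the bias so its deposited range never exceeds the cap
        np.maximum(v, v.max() - self.cap, out=v)
        self.last_change = float(np.abs(v - self.v).max())
        self.v = v
        self.f = -np.gradient(v, self.dx)

    def force_at(self, s: float) -> float:
        return float(np.interp(s, self.grid, self.f))


# ---------------------------------------------------------------------------
# OPES dynamics
# ---------------------------------------------------------------------------


def opes_run(
    potential: ModelPairPotential | object,
    params: OPESParams,
    walls: Sequence[WallSpec],
    spec: LangevinSpec,
    cv_range: tuple[float, float],
    stride: int = 10,
    r0: float | None = None,
    bias_grid_size: int = 512,
) -> tuple[CVRecordTable, BiasState]:
    """Overdamped dynamics under an adaptive OPES bias on one CV.

    ``spec.dims == 3`` runs the radial pair system (CV ``d`` = |x|, the
    potential must expose vectorised ``energy(r)``/``force(r)``);
    ``spec.dims == 1`` runs on a line (CV ``x``).  The bias is updated every
    ``params.update_pace`` steps; the recorded bias column holds the applied
    bias at sampling time, wall energies are recorded separately.
    """
    if spec.dims not in (1, 3):
        raise ValueError("opes_run supports dims 1 (line) or 3 (radial pair)")
    thermo = spec.thermo
    lo, hi = cv_range
    if not lo < hi:
        raise ValueError("cv_range must be increasing")
    logger.info(
        "opes_run: seed=%d steps=%d pace=%d barrier=%g gamma=%.3f",
        spec.seed, spec.n_steps, params.update_pace, params.barrier, params.gamma(thermo),
    )

    # dense tabulation of the conservative force and energy (potential + walls)
    n_tab = 4096
    tab_lo = max(lo - 1.0, 0.05) if spec.dims == 3 else lo - 1.0
    grid = np.linspace(tab_lo, hi + 2.0, n_tab)
    f_pot = np.asarray(potential.force(grid), dtype=float)
    e_pot = np.asarray(potential.energy(grid), dtype=float)
    wall_tab = np.zeros_like(grid)
    for wall in walls:
        f_pot = f_pot + harmonic_wall_force(grid, wall)
        wall_tab = wall_tab + harmonic_wall_energy(grid, wall)
    e_pot = e_pot + wall_tab

    opes = _OPESBias(params, thermo, lo, hi, n=bias_grid_size)

    rng = np.random.default_rng(spec.seed)
    dt = spec.timestep
    drift = spec.mobility * dt
    two_d_dt = 2.0 * spec.diffusion * dt
    noise_scale = math.sqrt(two_d_dt)
    inv_var4 = 1.0 / (2.0 * two_d_dt) if two_d_dt > 0 else 0.0
    beta = thermo.beta
    inv_d = 1.0 / (grid[1] - grid[0])
    g_lo = float(grid[0])
    n_grid = grid.size
    ftab = f_pot
    etab = e_pot

    def lookup(s: float) -> tuple[float, float]:
        """Total force and energy: tabulated potential+walls plus the
        current OPES bias (piecewise-constant between updates, so the
        Metropolis adjustment below stays exact within each epoch)."""
        u = (s - g_lo) * inv_d
        j = int(u)
        if j < 0:
            f, e = ftab[0], etab[0]
        elif j >= n_grid - 1:
            f, e = ftab[n_grid - 1], etab[n_grid - 1]
        else:
            w = u - j
            f = ftab[j] * (1.0 - w) + ftab[j + 1] * w
            e = etab[j] * (1.0 - w) + etab[j + 1] * w
        return f + opes.force_at(s), e + opes.bias_at(s)

    if spec.dims == 3:
        x, y, z = (r0 if r0 is not None else 0.5 * (lo + hi)), 0.0, 0.0
        s_cur = math.sqrt(x * x + y * y + z * z)
    else:
        x = r0 if r0 is not None else 0.5 * (lo + hi)
        s_cur = x
    f_cur, u_cur = lookup(s_cur)

    pace = params.update_pace
    n_rec = spec.n_steps // stride
    rec_t = np.empty(n_rec)
    rec_s = np.empty(n_rec)
    rec_v = np.empty(n_rec)
    rec_w = np.empty(n_rec)
    k = 0
    n_acc = 0
    change_history: list[float] = []
    chunk = 8192
    done = 0
    # Metropolis-adjusted (MALA) updates: Euler-Maruyama proposals accepted
    # against the total energy, so the sampled density is exact at any step
    # size and the step size only sets the mixing speed
    while done < spec.n_steps:
        n_now = min(chunk, spec.n_steps - done)
        if spec.dims == 3:
            noise = rng.standard_normal((n_now, 3)) * noise_scale
        else:
            noise = rng.standard_normal(n_now) * noise_scale
        logu = np.log(rng.random(n_now))
        for i in range(n_now):
            if spec.dims == 3:
                scale = drift * f_cur / s_cur
                mx = x + scale * x
                my = y + scale * y
                mz = z + scale * z
                px = mx + noise[i, 0]
                py = my + noise[i, 1]
                pz = mz + noise[i, 2]
                s_new = math.sqrt(px * px + py * py + pz * pz)
                f_new, u_new = lookup(s_new)
                scale_b = drift * f_new / s_new
                fwd = (px - mx) ** 2 + (py - my) ** 2 + (pz - mz) ** 2
                bx = px + scale_b * px - x
                by = py + scale_b * py - y
                bz = pz + scale_b * pz - z
                back = bx * bx + by * by + bz * bz
                log_acc = -beta * (u_new - u_cur) - (back - fwd) * inv_var4
                if logu[i] < log_acc:
                    x, y, z = px, py, pz
                    s_cur, f_cur, u_cur = s_new, f_new, u_new
                    n_acc += 1
            else:
                m = x + drift * f_cur
                p = m + noise[i]
                f_new, u_new = lookup(p)
                back = (p + drift * f_new - x) ** 2
                fwd = (p - m) ** 2
                log_acc = -beta * (u_new - u_cur) - (back - fwd) * inv_var4
                if logu[i] < log_acc:
                    x = p
                    s_cur, f_cur, u_cur = p, f_new, u_new
                    n_acc += 1
            step = done + i + 1
            if step % pace == 0:
                opes.deposit(min(max(s_cur, lo), hi))
                change_history.append(opes.last_change)
                f_cur, u_cur = lookup(s_cur)  # bias changed under our feet
            if step % stride == 0:
                rec_t[k] = step * dt
                rec_s[k] = s_cur
                rec_v[k] = opes.bias_at(s_cur)
                rec_w[k] = float(np.interp(s_cur, grid, wall_tab))
                k += 1
        done += n_now
        if not math.isfinite(s_cur) or abs(s_cur) > 1e8:
            raise RuntimeError(f"OPES dynamics diverged near step {done}")
    logger.info(
        "opes_run: %d/%d proposals accepted (%.1f%%)",
        n_acc, spec.n_steps, 100.0 * n_acc / max(1, spec.n_steps),
    )

    # quasi-static convergence: relative bias change over the last 10% of updates
    n_tail_updates = max(1, len(change_history) // 10)
    max_v = max(opes.v.max(), 1e-12)
    converged = bool(
        change_history
        and max(change_history[-n_tail_updates:]) / max_v < 1e-3
    )

    cv_name = "d" if spec.dims == 3 else "x"
    table = CVRecordTable.from_arrays(rec_t, {cv_name: rec_s}, bias=rec_v, wall=rec_w)
    state = BiasState(
        grid=opes.grid.copy(),
        bias=opes.v.copy(),
        kernel_centers=np.array(opes.centers),
        kernel_weights=np.array(opes.weights),
        bandwidth=params.bandwidth,
        gamma=opes.gamma,
        eps=opes.eps,
        barrier=params.barrier,
        z_norm=opes.z,
        converged=converged,
    )
    return table, state


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------


def reweight_fes(
    table: CVRecordTable,
    cv_names: Sequence[str],
    grid_spec: Sequence[FESAxis | tuple[float, float, int]],
    thermo: ThermoState,
    include_wall: bool = True,
) -> FESGrid:
    """Umbrella-sampling-type reweighting of a biased CV table onto a grid.

    Per-bin weighted histogram with weights ``exp(beta V)`` (V = recorded bias
    plus, by default, the wall energy), normalised and min-subtracted.
    Unvisited bins are NaN; raw counts are attached to the grid.  The
    reweighting axes need not be the biased CV.
    """
    axes = [
        ax if isinstance(ax, FESAxis) else FESAxis.linear(name, *ax)
        for name, ax in zip(cv_names, grid_spec)
    ]
    samples = np.column_stack([table.cv(name) for name in cv_names])
    v = table.bias + (table.wall if include_wall else 0.0)
    weights = np.exp(thermo.beta * (v - v.max()))
    edges = [ax.edges for ax in axes]
    hist, _ = np.histogramdd(samples, bins=edges, weights=weights)
    counts, _ = np.histogramdd(samples, bins=edges)
    if (counts > 0).sum() == 1:
        logger.warning("reweight_fes: degenerate grid, all samples fall in one bin")
    values = np.full(hist.shape, np.nan)
    visited = counts > 0
    with np.errstate(divide="ignore"):
        values[visited] = -thermo.kbt * np.log(hist[visited])
    values[visited] -= values[visited].min()
    return FESGrid(axes, values, counts=counts, min_subtracted=True)


@dataclass
class MultiRunFES:
    """Bin-wise mean FES over runs with per-bin standard error."""

    mean: FESGrid
    spread: np.ndarray | None  # standard error per bin; None if < 2 runs
    per_run: list[FESGrid]


def multi_run_fes(
    tables: Sequence[CVRecordTable],
    cv_names: Sequence[str],
    grid_spec: Sequence[FESAxis | tuple[float, float, int]],
    thermo: ThermoState,
    average: str = "free_energy",
) -> MultiRunFES:
    """Average independent-run FES estimates on a common additive gauge.

    Each run is reweighted separately; runs are aligned by subtracting each
    run's Boltzmann-weighted mean free energy over the globally deepest
    basin's bins (the bins within 2 kB*T of the pooled minimum), then averaged
    bin-wise.  The spread is the standard error over runs.

    ``average`` selects the bin-wise combination: ``"free_energy"``
    (arithmetic mean of F, the convention for plotting mean surfaces with
    error bars) or ``"density"`` (log of the mean Boltzmann density
    e^{-beta F}; unbiased for downstream Boltzmann integrals, because
    averaging log-densities keeps the single-run Jensen bias).
    """
    if average not in ("free_energy", "density"):
        raise ValueError("average must be 'free_energy' or 'density'")
    if not tables:
        raise ValueError("need at least one run")
    import warnings as _warnings

    per_run = [reweight_fes(t, cv_names, grid_spec, thermo) for t in tables]
    stack = np.stack([f.values for f in per_run])
    with _warnings.catch_warnings():
        # bins unvisited by every run produce expected all-NaN reductions
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled = np.nanmean(stack, axis=0)
        basin = pooled <= (np.nanmin(pooled) + 2.0 * thermo.kbt)
        aligned = []
        for f_vals in stack:
            sel = basin & np.isfinite(f_vals)
            if not sel.any():
                sel = np.isfinite(f_vals)
            w = np.exp(-thermo.beta * (f_vals[sel] - np.nanmin(f_vals[sel])))
            shift = float(np.sum(f_vals[sel] * w) / np.sum(w))
            aligned.append(f_vals - shift)
        aligned = np.stack(aligned)
        if average == "density":
            ref = np.nanmin(aligned)
            mean_vals = ref - thermo.kbt * np.log(
                np.nanmean(np.exp(-thermo.beta * (aligned - ref)), axis=0)
            )
        else:
            mean_vals = np.nanmean(aligned, axis=0)
        n_valid = np.sum(np.isfinite(aligned), axis=0)
        if len(tables) >= 2:
            std = np.nanstd(aligned, axis=0, ddof=1)
            spread = np.where(n_valid >= 2, std / np.sqrt(n_valid), np.nan)
        else:
            logger.warning("multi_run_fes: fewer than 2 runs, spread undefined")
            spread = None
    counts = np.sum(
        np.stack([f.counts for f in per_run]), axis=0
    )
    mean = FESGrid(per_run[0].axes, mean_vals, counts=counts, min_subtracted=False)
    return MultiRunFES(mean=mean, spread=spread, per_run=per_run)


def format_uncertainty(mean: float, err: float) -> str:
    """Uncertainty-in-last-digit notation, e.g. (-8.53, 0.05) -> '-8.53(5)'.

    The error is rounded to one significant digit and quoted in parentheses
    at the matching decimal place; a zero error yields '(0)'.
    """
    if err < 0 or not math.isfinite(mean):
        raise ValueError("need finite mean and nonnegative error")
    if err == 0:
        text = f"{mean:.6f}".rstrip("0")
        if text.endswith("."):
            text += "0"
        return f"{text}(0)"
    exponent = math.floor(math.log10(err))
    digit = round(err / 10**exponent)
    if digit == 10:
        digit = 1
        exponent += 1
    decimals = max(0, -exponent)
    return f"{mean:.{decimals}f}({digit})"


# ---------------------------------------------------------------------------
# committee deviation and active-learning selection
# ---------------------------------------------------------------------------


def committee_deviation(force_sets: np.ndarray) -> np.ndarray | float:
    """Per-configuration force disagreement across committee models.

    ``force_sets`` has shape (n_models, n_atoms, 3) for a single
    configuration or (n_models, n_configs, n_atoms, 3).  The score is the
    maximum over atoms of the root-mean-square (over models) norm of the
    deviation of the force vector from the model mean — invariant under
    adding any model-independent force field and under global rotations.
    """
    forces = np.asarray(force_sets, dtype=float)
    single = forces.ndim == 3
    if single:
        forces = forces[:, None]
    if forces.ndim != 4 or forces.shape[0] < 2:
        raise CalcipairError(
            "committee_deviation needs >= 2 models with shape (n_models[, n_configs], n_atoms, 3)"
        )
    dev = forces - forces.mean(axis=0, keepdims=True)
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=-1), axis=0))  # (n_configs, n_atoms)
    score = per_atom.max(axis=-1)
    return float(score[0]) if single else score


def select_configs(
    scores: Sequence[float], lower: float, upper: float
) -> list[int]:
    """Active-learning window: indices with ``lower <= score < upper``,
    order-preserving.  Scores above ``upper`` are treated as unphysical and
    discarded; scores below ``lower`` carry no new information."""
    return [i for i, s in enumerate(scores) if lower <= s < upper]
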