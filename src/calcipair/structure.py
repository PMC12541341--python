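"""Structural and dynamical observables: radial distribution functions,
coordination numbers, interfacial electron-density profiles, Einstein
diffusion with finite-size extrapolation, residence times and lattice
constants."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalcipairError
from .geometry import minimum_image_displacement
from .switching import SwitchSpec, switch_cubic, switch_cubic_derivative  # noqa: F401  (re-exported)
from .toysim import CM2_PER_S_TO_A2_PER_PS, ResidenceSeries
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

#: electrons per nucleus for the weighted nuclei-density profile
ELECTRON_COUNTS = {"O": 8, "H": 1, "C": 6, "Ca": 20, "Ow": 8, "Hw": 1, "Oc": 8}


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------


@dataclass
class RadialDistribution:
    """g(r) on uniform bins with the pair labels and frame count used."""

    bin_centers: np.ndarray
    g: np.ndarray
    pair: tuple[str, str]
    n_frames: int
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")


def rdf(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    r_max: float,
    dr: float = 0.05,
) -> RadialDistribution:
    """Radial distribution function between two species.

    Standard pair-count normalisation by the ideal-gas shell density; for
    identical species the self-pair is excluded.  ``r_max`` must not exceed
    half the smallest box edge (minimum-image validity).
    """
    half_min_edge = float(traj.box.edge_lengths.min()) / 2.0
    if r_max > half_min_edge + 1e-9:
        raise CalcipairError(
            f"r_max = {r_max} exceeds half the smallest box edge ({half_min_edge:.3f} A)"
        )
    idx_a = traj.species_indices(species_a)
    idx_b = traj.species_indices(species_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise CalcipairError(f"no particles of species {species_a!r} or {species_b!r}")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(edges.size - 1)
    same = species_a == species_b
    for f in range(len(traj)):
        pos_a = traj.positions[f, idx_a]
        pos_b = traj.positions[f, idx_b]
        disp = minimum_image_displacement(pos_a[:, None, :], pos_b[None, :, :], traj.box)
        dist = np.linalg.norm(disp, axis=-1)
        if same:
            iu = np.triu_indices(idx_a.size, k=1)
            dist = dist[iu]
        else:
            dist = dist.ravel()
        h, _ = np.histogram(dist, bins=edges)
        counts += h
    volume = traj.box.volume
    if same:
        n_pairs = idx_a.size * (idx_a.size - 1) / 2.0
        pair_density = n_pairs / volume
    else:
        pair_density = idx_a.size * idx_b.size / volume
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = pair_density * shell_volumes * len(traj)
    g = counts / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialDistribution(centers, g, (species_a, species_b), len(traj), dr)


@dataclass
class DeltaCurve:
    """Signed difference between two g(r) curves on their common grid."""

    bin_centers: np.ndarray
    values: np.ndarray
    labels: tuple[str, str]
    bin_width: float


def delta_rdf(g1: RadialDistribution, g2: RadialDistribution) -> DeltaCurve:
    """Difference curve g1 - g2 on the overlapping grid.

    Requires identical bin widths; a half-bin grid offset is handled by
    linear interpolation of g2 onto g1's centers.  Non-overlapping parts are
    trimmed with a warning; disjoint ranges give an empty curve.
    """
    if abs(g1.bin_width - g2.bin_width) > 1e-9:
        raise CalcipairError("delta_rdf requires identical bin widths")
    labels = ("-".join(g1.pair), "-".join(g2.pair))
    lo = max(g1.bin_centers[0], g2.bin_centers[0])
    hi = min(g1.bin_centers[-1], g2.bin_centers[-1])
    if lo > hi:
        logger.warning("delta_rdf: grids have disjoint ranges, empty result")
        empty = np.array([])
        return DeltaCurve(empty, empty, labels, g1.bin_width)
    if lo > g1.bin_centers[0] + 1e-9 or hi < g1.bin_centers[-1] - 1e-9:
        logger.warning("delta_rdf: trimming non-overlapping range to [%.3f, %.3f]", lo, hi)
    mask = (g1.bin_centers >= lo - 1e-9) & (g1.bin_centers <= hi + 1e-9)
    centers = g1.bin_centers[mask]
    if np.allclose(centers, g2.bin_centers[: centers.size], atol=1e-9):
        g2_interp = g2.g[: centers.size]
    else:
        from scipy.interpolate import CubicSpline

        g2_interp = CubicSpline(g2.bin_centers, g2.g)(centers)
    return DeltaCurve(centers, g1.g[mask] - g2_interp, labels, g1.bin_width)


# ---------------------------------------------------------------------------
# coordination numbers
# ---------------------------------------------------------------------------


def coordination_sharp(
    traj: Trajectory,
    center_species: str,
    neighbor_species: str,
    cutoff: float,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """Mean sharp-cutoff coordination number with a block standard error.

    Counts neighbours with minimum-image distance <= cutoff (closed boundary:
    a neighbour exactly at the cutoff is counted).  Returns (mean, stderr).
    """
    idx_c = traj.species_indices(center_species)
    idx_n = traj.species_indices(neighbor_species)
    if idx_c.size == 0 or idx_n.size == 0:
        raise CalcipairError("no particles of the requested species")
    per_frame = np.empty(len(traj))
    same = center_species == neighbor_species
    for f in range(len(traj)):
        disp = minimum_image_displacement(
            traj.positions[f, idx_c][:, None, :],
            traj.positions[f, idx_n][None, :, :],
            traj.box,
        )
        dist = np.linalg.norm(disp, axis=-1)
        within = dist <= cutoff
        if same:
            np.fill_diagonal(within, False)
        per_frame[f] = within.sum() / idx_c.size
    mean = float(per_frame.mean())
    stderr = _block_stderr(per_frame, n_blocks)
    return mean, stderr


def _block_stderr(series: np.ndarray, n_blocks: int) -> float:
    n_blocks = max(1, min(n_blocks, series.size))
    if n_blocks < 2:
        return 0.0
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# electron-density profiles
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Electron density vs height: values in e/A^3 (z bins x lateral area).

    ``origin`` is the z used as zero (mean height of the topmost Ca layer by
    default); ``lateral_area`` (A^2) and ``species_weights`` record the
    normalisation so other unit conventions (e.g. electrons per surface unit
    cell) can be emitted downstream.
    """

    z_centers: np.ndarray
    values: np.ndarray
    lateral_area: float
    bin_width: float
    origin: float
    species_weights: dict[str, int]

    @property
    def total_electrons(self) -> float:
        return float(self.values.sum() * self.bin_width * self.lateral_area)


def _topmost_ca_layer(z_values: np.ndarray, linkage: float = 1.0) -> float:
    """Mean z of the highest Ca cluster (single-linkage with a 1 A threshold)."""
    z_sorted = np.sort(z_values)
    breaks = np.where(np.diff(z_sorted) > linkage)[0]
    start = breaks[-1] + 1 if breaks.size else 0
    return float(z_sorted[start:].mean())


def electron_density_profile(
    traj: Trajectory,
    bin_width: float = 0.1,
    electron_counts: dict[str, int] | None = None,
    origin_rule: str = "top_ca_layer",
    smoothing: float = 0.0,
) -> DensityProfile:
    """Electron density as a weighted sum of per-species nuclei histograms.

    z histograms of each species are weighted by electron counts (O 8, H 1,
    C 6, Ca 20) and summed; the origin is the mean z of the topmost Ca layer
    (1 A linkage clustering).  Optional Gaussian smoothing (standard
    deviation in A) conserves the integral.  Total electrons are conserved
    exactly: integral x lateral area = sum of species counts x electrons.
    """
    from scipy.ndimage import gaussian_filter1d

    weights_table = electron_counts if electron_counts is not None else ELECTRON_COUNTS
    if origin_rule == "top_ca_layer":
        idx_ca = traj.species_indices("Ca")
        if idx_ca.size == 0:
            raise CalcipairError("origin rule 'top_ca_layer' requested but no Ca present")
        origin = _topmost_ca_layer(traj.positions[:, idx_ca, 2].ravel())
    elif origin_rule == "zero":
        origin = 0.0
    else:
        raise ValueError(f"unknown origin rule {origin_rule!r}")

    z_all = traj.positions[..., 2] - origin
    pad = bin_width + 5.0 * smoothing  # keep smoothed mass inside the range
    z_lo = math.floor(z_all.min() / bin_width) * bin_width - pad
    z_hi = math.ceil(z_all.max() / bin_width) * bin_width + pad
    edges = np.arange(z_lo, z_hi + bin_width / 2, bin_width)
    hist = np.zeros(edges.size - 1)
    used: dict[str, int] = {}
    for sp in sorted(set(traj.species)):
        if sp not in weights_table:
            raise CalcipairError(f"no electron count declared for species {sp!r}")
        idx = traj.species_indices(sp)
        h, _ = np.histogram(z_all[:, idx].ravel(), bins=edges)
        hist += weights_table[sp] * h
        used[sp] = weights_table[sp]
    lateral_area = float(traj.box.edge_lengths[0] * traj.box.edge_lengths[1])
    values = hist / (len(traj) * lateral_area * bin_width)
    if smoothing > 0:
        values = gaussian_filter1d(values, smoothing / bin_width, mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, values, lateral_area, bin_width, origin, used)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionResult:
    """Einstein-relation fit: D in 1e-5 cm^2/s, the MSD slope fit quality and
    the raw MSD curve."""

    d: float
    r_squared: float
    msd_times: np.ndarray
    msd: np.ndarray
    low_quality: bool


def einstein_diffusion(
    traj: Trajectory,
    species: str | None = None,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> DiffusionResult:
    """Diffusion coefficient from the mean squared displacement.

    MSD(t) is averaged over particles and multiple time origins (origin
    spacing at least the fit-window length, to limit correlation);
    D = slope/6 over the fit window expressed as fractions of the trajectory
    length, converted to 1e-5 cm^2/s.  Requires unwrapped coordinates.  A
    linear-fit r^2 below 0.9 sets ``low_quality`` (e.g. ballistic motion).
    """
    if traj.wrapped:
        raise CalcipairError("einstein_diffusion requires unwrapped coordinates")
    if species is None:
        idx = np.arange(traj.n_atoms)
    else:
        idx = traj.species_indices(species)
        if idx.size == 0:
            raise CalcipairError(f"no particles of species {species!r}")
    pos = traj.positions[:, idx, :]
    n_frames = pos.shape[0]
    dt = float(traj.times[1] - traj.times[0]) if n_frames > 1 else 0.0
    max_lag = max(2, int(fit_window[1] * n_frames))
    origin_spacing = max(1, max_lag)
    origins = np.arange(0, n_frames - max_lag, origin_spacing)
    if origins.size == 0:
        origins = np.array([0])
    lags = np.arange(1, max_lag)
    msd = np.zeros(lags.size)
    for i, lag in enumerate(lags):
        disp = pos[origins + lag] - pos[origins]
        msd[i] = np.mean(np.sum(disp**2, axis=-1))
    times = lags * dt
    lo = fit_window[0] * n_frames * dt
    hi = fit_window[1] * n_frames * dt
    sel = (times >= lo) & (times <= hi)
    if sel.sum() < 2:
        sel = np.ones_like(times, dtype=bool)
    slope, intercept = np.polyfit(times[sel], msd[sel], 1)
    fitted = slope * times[sel] + intercept
    ss_res = float(np.sum((msd[sel] - fitted) ** 2))
    ss_tot = float(np.sum((msd[sel] - msd[sel].mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_a2ps = max(slope, 0.0) / 6.0
    d = d_a2ps / CM2_PER_S_TO_A2_PER_PS / 1e-5  # 1e-5 cm^2/s units
    # diffusive MSDs are linear to r^2 >> 0.99; ballistic (t^2) curvature is not
    low_quality = r_squared < 0.99
    if low_quality:
        logger.warning(
            "einstein_diffusion: MSD is not linear over the fit window (r^2 = %.3f); "
            "the Einstein estimate is unreliable", r_squared,
        )
    return DiffusionResult(float(d), r_squared, times, msd, low_quality)


def finite_size_extrapolate(
    d_values: Sequence[float], box_edges: Sequence[float]
) -> tuple[float, float]:
    """Extrapolate D(L) to infinite system size by ordinary least squares of
    D against 1/L; returns (D_infinity, slope)."""
    d_values = np.asarray(d_values, dtype=float)
    box_edges = np.asarray(box_edges, dtype=float)
    if d_values.size != box_edges.size or d_values.size < 2:
        raise ValueError("need >= 2 (D, L) pairs of equal length")
    slope, intercept = np.polyfit(1.0 / box_edges, d_values, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------


@dataclass
class ResidenceResult:
    tau: float  # ps; NaN when undefined
    n_intervals: int
    survival_times: np.ndarray
    survival: np.ndarray
    defined: bool


def residence_time(
    series: ResidenceSeries | np.ndarray,
    dt: float | None = None,
    transient_tolerance: float = 2.0,
) -> ResidenceResult:
    """Residence time from the bound-interval survival function.

    Excursions to the unbound state shorter than the transient tolerance t*
    are ignored (they do not terminate a binding event).  S(t) is the
    probability that a particle continuously bound at a random origin is
    still bound after t; tau comes from a weighted exponential fit to S.
    A never-bound series yields tau = NaN with ``defined = False``.
    """
    if isinstance(series, ResidenceSeries):
        indicator = series.indicator.astype(bool)
        dt = series.dt
    else:
        if dt is None:
            raise ValueError("dt required when passing a bare indicator array")
        indicator = np.asarray(series).astype(bool)
    if not indicator.any():
        logger.warning("residence_time: series is never bound; tau undefined")
        empty = np.array([])
        return ResidenceResult(math.nan, 0, empty, empty, False)

    # close unbound excursions shorter than t*
    tol_frames = int(round(transient_tolerance / dt))
    filled = indicator.copy()
    if tol_frames > 0:
        padded = np.concatenate([[True], filled, [True]])
        changes = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(changes[::2], changes[1::2]):
            if (stop - start) < tol_frames and not padded[start + 1 : stop + 1].any():
                filled[start:stop] = True
    # collect bound interval lengths (in frames)
    padded = np.concatenate([[False], filled, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = changes[::2], changes[1::2]
    lengths = (stops - starts) * dt
    total = lengths.sum()
    t_max = lengths.max()
    t_grid = np.arange(0.0, t_max, dt)
    survival = np.array([np.sum(np.clip(lengths - t, 0.0, None)) for t in t_grid]) / total
    # exponential fit on the reliable part of the survival curve
    sel = survival > 0.02
    if sel.sum() < 2:
        sel = survival > 0
    log_s = np.log(survival[sel])
    slope = np.polyfit(t_grid[sel], log_s, 1, w=np.sqrt(survival[sel]))[0]
    tau = -1.0 / slope if slope < 0 else math.nan
    return ResidenceResult(float(tau), len(lengths), t_grid, survival, np.isfinite(tau))


# ---------------------------------------------------------------------------
# lattice constants
# ---------------------------------------------------------------------------


def lattice_constants(
    edge_series: np.ndarray,
    replications: Sequence[int],
    n_blocks: int = 10,
) -> list[tuple[float, float, str]]:
    """Per-axis lattice constants from a supercell edge time series.

    Each supercell edge is divided by its replication count; the time mean,
    a block-averaged standard error and the uncertainty-in-last-digit string
    are returned per axis.
    """
    from .sampling import format_uncertainty

    edges = np.atleast_2d(np.asarray(edge_series, dtype=float))
    if edges.ndim != 2:
        raise ValueError("edge_series must be (n_times, n_axes)")
    if edges.shape[1] != len(replications):
        raise ValueError("one replication count per axis is required")
    out = []
    for axis, rep in enumerate(replications):
        series = edges[:, axis] / rep
        mean = float(series.mean())
        err = _block_stderr(series, n_blocks)
        out.append((mean, err, format_uncertainty(mean, err)))
    return out
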