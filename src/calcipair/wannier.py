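"""Wannier-centroid construction and periodic Gaussian-charge electrostatics.

The long-range layer of the model places spherical Gaussian charges at the
nuclei (positive) and at Wannier centroids (negative): within the
pseudopotential bookkeeping O, C, H and Ca nuclei carry +6, +4, +1 and +10 e,
and each centroid — the mean of the four Wannier centers attached to an O or
Ca atom — carries -8 e (four doubly occupied Wannier functions).  In
``effective`` calcium mode, Ca instead contributes a single +2 e site and its
centroids are omitted (the short-range model is assumed to capture Ca
polarisation within its cutoff).

The Gaussian density convention is ``rho_i(x) ∝ exp(-spread^2 |x - r_i|^2)``
with the spread parameter in 1/A (default 0.1 A^-1).  The periodic energy is
evaluated in reciprocal space only (exact for these wide Gaussians at any
practical Fourier grid), with the isolated-Gaussian self energies excluded;
a real-space direct sum over periodic images serves as the independent
verification oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import erf

from .errors import CalcipairError
from .geometry import SimulationBox, minimum_image_displacement
from .trajectory import Frame
from .units import COULOMB

logger = logging.getLogger(__name__)

EXPLICIT = "explicit-centroid"
EFFECTIVE = "effective-charge"

#: nuclear charges in e under the pseudopotential bookkeeping
NUCLEAR_CHARGES = {"O": 6.0, "C": 4.0, "H": 1.0, "Ca": 10.0}
CENTROID_CHARGE = -8.0
CA_EFFECTIVE_CHARGE = 2.0
CENTROID_SPECIES = ("O", "Ca")
WC_LABEL = "WC"


@dataclass(frozen=True)
class ChargeTable:
    """Charge bookkeeping: nuclear charges, centroid charge and Ca mode."""

    nuclear: dict[str, float] = field(default_factory=lambda: dict(NUCLEAR_CHARGES))
    centroid: float = CENTROID_CHARGE
    calcium_mode: str = EFFECTIVE

    def __post_init__(self) -> None:
        if self.calcium_mode not in (EXPLICIT, EFFECTIVE):
            raise ValueError(f"unknown calcium mode {self.calcium_mode!r}")

    @property
    def centroid_hosts(self) -> tuple[str, ...]:
        """Species that own four Wannier centers each."""
        if self.calcium_mode == EXPLICIT:
            return ("O", "Ca")
        return ("O",)


@dataclass
class ChargedSiteSet:
    """Point sites with charges and a common Gaussian spread (1/A)."""

    positions: np.ndarray  # (N, 3), A
    charges: np.ndarray  # (N,), e
    box: SimulationBox
    spread: float = 0.1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        q = np.asarray(self.charges, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or q.shape != (pos.shape[0],):
            raise ValueError("positions must be (N,3) with one charge per site")
        if not np.all(np.isfinite(pos)):
            raise ValueError("site positions must be finite")
        if self.spread <= 0:
            raise ValueError("Gaussian spread must be positive")
        self.positions = pos
        self.charges = q

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class CentroidAssignment:
    """Per host atom: its 4 Wannier-center indices and centroid displacement."""

    atom_indices: np.ndarray  # (n_hosts,), indices into the frame
    center_indices: np.ndarray  # (n_hosts, 4), indices into the frame
    displacements: np.ndarray  # (n_hosts, 3), A
    flagged: np.ndarray  # (n_hosts,), True where the sanity bound was violated


def assign_centroids(frame: Frame, table: ChargeTable) -> CentroidAssignment:
    """Assign each Wannier center to a host atom (4 per O/Ca) and build centroids.

    Centers are matched to host-atom slots by minimum-image distance using an
    exact optimal assignment; the centroid displacement is the minimum-image
    mean of the four center displacements.  Displacements above 1 A are
    flagged; assignment distances above 1.5 A log a warning.
    """
    hosts = np.array(
        [i for i, s in enumerate(frame.species) if s in table.centroid_hosts], dtype=int
    )
    centers = np.array(
        [i for i, s in enumerate(frame.species) if s == WC_LABEL], dtype=int
    )
    if centers.size != 4 * hosts.size:
        raise CalcipairError(
            f"need 4 Wannier centers per host atom: {hosts.size} hosts "
            f"({'/'.join(table.centroid_hosts)}) but {centers.size} centers"
        )
    disp = minimum_image_displacement(
        frame.positions[hosts][:, None, :], frame.positions[centers][None, :, :], frame.box
    )  # (n_hosts, n_centers, 3)
    dist = np.linalg.norm(disp, axis=-1)
    # one column block of 4 slots per host atom; Hungarian on the distance cost
    cost = np.repeat(dist, 4, axis=0)  # (4*n_hosts, n_centers)
    row_ind, col_ind = linear_sum_assignment(cost)
    center_of_slot = np.empty(4 * hosts.size, dtype=int)
    center_of_slot[row_ind] = col_ind
    center_indices = centers[center_of_slot.reshape(hosts.size, 4)]
    assigned_dist = dist[np.repeat(np.arange(hosts.size), 4), center_of_slot]
    if np.any(assigned_dist > 1.5):
        logger.warning(
            "assign_centroids: %d center assignments exceed 1.5 A (max %.2f A)",
            int((assigned_dist > 1.5).sum()), float(assigned_dist.max()),
        )
    displacements = np.empty((hosts.size, 3))
    for h in range(hosts.size):
        d_h = disp[h, center_of_slot[4 * h : 4 * h + 4]]
        displacements[h] = d_h.mean(axis=0)
    flagged = np.linalg.norm(displacements, axis=-1) >= 1.0
    if flagged.any():
        logger.warning(
            "assign_centroids: %d centroid displacements exceed the 1 A sanity bound",
            int(flagged.sum()),
        )
    return CentroidAssignment(hosts, center_indices, displacements, flagged)


def build_charged_sites(
    frame: Frame,
    assignment: CentroidAssignment | None,
    table: ChargeTable,
    spread: float = 0.1,
) -> ChargedSiteSet:
    """One Gaussian site per nucleus plus one per centroid.

    Nuclei carry their pseudopotential charges; centroids carry -8 e.  In
    effective-charge mode Ca contributes a single +2 e site (no centroids).
    Wannier-center pseudo-particles themselves are never sites.
    """
    positions: list[np.ndarray] = []
    charges: list[float] = []
    host_set = set(table.centroid_hosts)
    for i, sp in enumerate(frame.species):
        if sp == WC_LABEL:
            continue
        if sp == "Ca" and table.calcium_mode == EFFECTIVE:
            positions.append(frame.positions[i])
            charges.append(CA_EFFECTIVE_CHARGE)
            continue
        if sp not in table.nuclear:
            raise CalcipairError(f"unknown species {sp!r} in charge table")
        positions.append(frame.positions[i])
        charges.append(table.nuclear[sp])
    if assignment is None:
        if any(s in host_set for s in frame.species):
            raise CalcipairError("centroid hosts present but no assignment supplied")
    else:
        for h, atom_idx in enumerate(assignment.atom_indices):
            positions.append(frame.positions[atom_idx] + assignment.displacements[h])
            charges.append(table.centroid)
    sites = ChargedSiteSet(
        np.array(positions), np.array(charges), frame.box, spread=spread
    )
    return sites


# ---------------------------------------------------------------------------
# reciprocal-space Gaussian electrostatics
# ---------------------------------------------------------------------------


def _k_vectors(box: SimulationBox, k_cut: float) -> np.ndarray:
    """All reciprocal vectors with 0 < |k| <= k_cut in one half space."""
    L = box.edge_lengths
    n_max = np.maximum(1, np.ceil(k_cut * L / (2.0 * np.pi)).astype(int))
    nx = np.arange(0, n_max[0] + 1)
    ny = np.arange(-n_max[1], n_max[1] + 1)
    nz = np.arange(-n_max[2], n_max[2] + 1)
    grid = np.array(np.meshgrid(nx, ny, nz, indexing="ij")).reshape(3, -1).T
    # half space: nx > 0, or nx == 0 and (ny > 0 or (ny == 0 and nz > 0))
    keep = (
        (grid[:, 0] > 0)
        | ((grid[:, 0] == 0) & (grid[:, 1] > 0))
        | ((grid[:, 0] == 0) & (grid[:, 1] == 0) & (grid[:, 2] > 0))
    )
    grid = grid[keep]
    k = 2.0 * np.pi * grid / L[None, :]
    k2 = np.sum(k**2, axis=1)
    return k[k2 <= k_cut**2 + 1e-12]


def gaussian_ewald_energy(
    sites: ChargedSiteSet,
    grid_spacing: float = 1.0,
    compute_forces: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Periodic interaction energy of spherical Gaussian charges, kJ/mol.

    Reciprocal-space sum with Gaussian form factors (cutoff
    ``k_cut = pi / grid_spacing``, the Fourier-grid reading of the spacing),
    isolated-Gaussian self energies excluded; returns per-site forces as the
    negative energy gradient.  Non-neutral sets receive the uniform-background
    correction (logged).  Raises when the Fourier grid is too coarse to
    resolve the Gaussians.
    """
    beta_g = sites.spread
    k_cut = math.pi / grid_spacing
    # the form factor must be negligible at the cutoff for the sum to be converged
    if math.exp(-k_cut**2 / (2.0 * beta_g**2)) > 1e-8:
        needed = math.pi / (beta_g * math.sqrt(2.0 * math.log(1e8)))
        raise CalcipairError(
            f"Fourier grid spacing {grid_spacing} A too coarse for spread "
            f"{beta_g} 1/A; use a spacing below {needed:.2f} A"
        )
    k = _k_vectors(sites.box, k_cut)
    if k.size == 0:
        raise CalcipairError("no reciprocal vectors below the cutoff; box too small")
    k2 = np.sum(k**2, axis=1)
    form = np.exp(-k2 / (2.0 * beta_g**2)) / k2  # (n_k,)
    phases = k @ sites.positions.T  # (n_k, N)
    s_re = np.cos(phases) @ sites.charges
    s_im = np.sin(phases) @ sites.charges
    volume = sites.box.volume
    prefactor = COULOMB * 4.0 * np.pi / volume  # doubled: half-space k sum
    energy = float(prefactor * np.sum(form * (s_re**2 + s_im**2)))
    # subtract isolated-Gaussian self energies
    energy -= float(COULOMB * beta_g / math.sqrt(2.0 * math.pi) * np.sum(sites.charges**2))
    q_tot = sites.net_charge
    if abs(q_tot) > 1e-12:
        logger.info(
            "gaussian_ewald_energy: net charge %.3f e, applying uniform-background correction",
            q_tot,
        )
        energy -= float(COULOMB * math.pi * q_tot**2 / (volume * beta_g**2))
    forces = None
    if compute_forces:
        # F_j = -dE/dr_j; with the half-space sum the cross terms double as well
        im_part = np.sin(phases) * s_re[:, None] - np.cos(phases) * s_im[:, None]
        coeff = 2.0 * prefactor * form  # (n_k,)
        forces = np.einsum("ka,k,kj->ja", k, coeff, im_part) * sites.charges[:, None]
    return energy, forces


def direct_sum_oracle(
    sites: ChargedSiteSet,
    shells: int = 14,
    extrapolate: bool = True,
) -> float:
    """Real-space image sum of the Gaussian pair interaction, kJ/mol.

    Pair energy ``q_i q_j erf(beta/sqrt(2) * r) / r`` summed over periodic
    images out to ``shells`` cubic shells of cells.  Two corrections make the
    shell-ordered sum comparable to the conducting-boundary reciprocal-space
    result: the cell-dipole surface term ``2 pi k_e M^2 / (3V)`` is removed
    analytically, and the remaining smooth quadrupole-tail truncation error
    is extrapolated away by a least-squares fit of ``E(S) = E_inf +
    sum_p a_p S^-p`` (p = 2..5) over the cumulative shell sums.
    O(N^2 * shells^3) — verification only.
    """
    if shells < 8 and extrapolate:
        raise ValueError("shell extrapolation needs at least 8 shells")
    L = sites.box.edge_lengths
    q = sites.charges
    pos = sites.positions
    b = sites.spread / math.sqrt(2.0)  # combined spread of two equal Gaussians
    rng = np.arange(-shells, shells + 1)
    grid = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    shell_of = np.max(np.abs(grid), axis=1)
    images = grid * L[None, :]
    diff = pos[:, None, :] - pos[None, :, :]  # (N, N, 3)
    qq = q[:, None] * q[None, :]
    per_shell = np.zeros(shells + 1)
    for start in range(0, images.shape[0], 2000):
        img = images[start : start + 2000]
        d = np.linalg.norm(diff[None] + img[:, None, None, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pair = np.where(d > 0, erf(b * d) / np.where(d > 0, d, 1.0), 0.0)
        e = qq[None] * pair
        central = np.flatnonzero(np.all(img == 0, axis=1))
        for c in central:
            e[c] = np.triu(e[c], k=1) * 2.0  # each central pair once (doubled for the 1/2)
        np.add.at(per_shell, shell_of[start : start + 2000], 0.5 * e.sum(axis=(1, 2)))
    cumulative = np.cumsum(per_shell) * COULOMB

    # shell-ordered vacuum sums converge to Ewald + 2*pi*k_e*M^2/(3V)
    dipole = np.sum(q[:, None] * pos, axis=0)
    surface = COULOMB * 2.0 * math.pi * float(dipole @ dipole) / (3.0 * sites.box.volume)
    corrected = cumulative - surface
    if not extrapolate:
        return float(corrected[shells])
    # fit only the outermost shells: for wide Gaussians the inner shells are
    # still inside the erf transition and do not follow the multipole power law
    s_fit = np.arange(max(5, shells - 5), shells + 1, dtype=float)
    y = corrected[s_fit.astype(int)]
    design = np.column_stack([np.ones_like(s_fit)] + [s_fit**-p for p in (2, 3, 4, 5)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0])


#: named molecular fragments (nuclei only; centroids are implied per host atom)
FRAGMENTS = {
    "Ca": ["Ca"],
    "water": ["O", "H", "H"],
    "hydroxide": ["O", "H"],
    "carbonate": ["C", "O", "O", "O"],
    "bicarbonate": ["C", "O", "O", "O", "H"],
}


def lr_tail_from_charges(
    table: ChargeTable,
    species_pair: tuple[str, str],
    epsilon: float,
    r: np.ndarray | float,
) -> np.ndarray | float:
    """Screened tail between net-charge groups: q_A q_B k_e / (eps r), kJ/mol.

    Group names are fragment keys ('Ca', 'carbonate', ...); for Ca/carbonate
    with the default table the charge product is -4 e^2.  Shares its Coulomb
    constant with the pairing-thermo tail.
    """
    qa = fragment_net_charge(FRAGMENTS[species_pair[0]], table)
    qb = fragment_net_charge(FRAGMENTS[species_pair[1]], table)
    r_arr = np.asarray(r, dtype=float)
    e = qa * qb * COULOMB / (epsilon * r_arr)
    return e if r_arr.ndim else float(e)


def fragment_net_charge(species: list[str], table: ChargeTable) -> float:
    """Net charge of a molecular fragment: nuclei plus one -8 e centroid per
    centroid-hosting atom (water 0, hydroxide -1, carbonate -2, ...)."""
    total = 0.0
    for sp in species:
        if sp == WC_LABEL:
            continue
        if sp == "Ca" and table.calcium_mode == EFFECTIVE:
            total += CA_EFFECTIVE_CHARGE
            continue
        total += table.nuclear[sp]
        if sp in table.centroid_hosts:
            total += table.centroid
    return total
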