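# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the spirit of a methods section: everything
here is implemented and exercised by the test suite; no empirical number is
quoted that the tests or `scripts/acceptance.py` do not themselves compute.

## Unit system and constants

All quantities are in A, ps, K, kJ/mol and elementary charges.
kB = 0.008314463 kJ/mol/K; the Coulomb prefactor e^2/(4 pi eps0) =
1389.35458 kJ A/mol. The default temperature is 330 K (the simulation
temperature of the underlying first-principles model, chosen to offset the
~30 K shift of water properties in that functional). The 1 M standard state
corresponds to one formula unit per 1e27/N_A ~= 1660 A^3; the association
integral uses the printed value 1660 A^3 by default.

## Synthetic-data generators (`toysim`)

The generators produce data with the statistical structure the analysis
assumes, with known ground truth; they are the package's study conditions.

**Model pair potential.** A radial potential for the Ca-CO3 relative
coordinate: Gaussian basins on top of a screened-Coulomb tail
q1 q2 e^2/(4 pi eps0 eps r) and an (r_in/r)^12 repulsive core. The presets
(`caco3_lr`, `caco3_sr`) place basins at the bidentate (2.9 A), monodentate
(3.4 A) and solvent-shared (5.0 A) separations with a barrier bump near
4.1 A, charge product -4 e^2 and dielectric 102; depths and widths are
package choices producing association free energies in the -12 to -13
kJ/mol range, not fits to any published curve. The short-ranged preset
switches the tail off smoothly between the 6 A model cutoff and twice the
cutoff, which is also where its W(r) plateaus. The core is an r^-12 power
law rather than a one-sided harmonic because, against an attractive 1/r
tail, any harmonic wall creates a spurious contact minimum where the two
slopes balance; `inner_wall_radius` is the radius at which the core reaches
1 kJ/mol.

**Dynamics.** Overdamped Langevin (position) dynamics with D = kB*T /
friction; friction is an inverse mobility in these units (friction 1/ps at
330 K gives D = 2.744 A^2/ps). Only stationary statistics matter to every
downstream estimator, and those are independent of D; friction is chosen
per experiment for mixing speed. The tabulated samplers are
Metropolis-adjusted (MALA): the Euler-Maruyama move is a proposal accepted
against the tabulated total energy, so the sampled stationary distribution
is exact at any step size and the step size only sets the mixing rate
(acceptance stays above ~80% at the production settings and is logged).
This matters quantitatively: unadjusted dynamics at the step sizes needed
for adequate basin-tail round trips left a reproducible few-tenths-kJ/mol
depth error in the stiff basin region. The generic `langevin_sample` keeps
the plain (unadjusted) Euler-Maruyama update as documented. The confining
sphere used by the ideal-pair distribution test is a hard boundary
(proposals beyond it are rejected), which is exact under Metropolis.
Energies and forces are tabulated on fine grids (~0.004-0.01 A) and
linearly interpolated. Divergence aborts with a diagnostic. Every
generator is a pure function of its seed.

**Ion-pair emulation.** The pair is a single 3D relative coordinate; water
structure enters only through the shape of the model potential. The
4 pi r^2 entropy of the separation vector then arises naturally from the
dynamics, which is exactly the level at which the entropy-corrected W(r)
and the association integral operate.

**Other generators.** Brownian trajectories with per-axis increment
variance 2 D dt (1e-5 cm^2/s = 0.1 A^2/ps); alternating-exponential
two-state residence series; layered interfaces (Gaussian z about layer
positions, uniform laterally); committee force sets (truth + per-model
Gaussian noise of controlled scale); and an analytic proton-transfer
landscape F(d, n) = s(d) * 16 n^2 (1-n)^2 + confinement, with valleys at
protonation coordinate n = 0 and n = 1 and a saddle s(d) rising
sigmoidally from ~26 kJ/mol for the associated pair to ~46 kJ/mol past 6 A.

## OPES bias (`sampling`)

Fixed-bandwidth Gaussian kernels accumulate a weighted on-the-fly estimate
P(s) of the biased CV distribution (weights e^{beta V} at deposit time,
deposits every `update_pace` = 500 steps); the bias is

    V(s) = (1 - 1/gamma) kB*T ln( P(s)/Z + eps ),

with gamma = dE/kB*T, eps = exp[-beta dE/(1 - 1/gamma)] and Z the mean of
P over the explored range. The bias is kept in this natural gauge — an
earlier re-shifted nonnegative gauge made the deposit weights time-
inconsistent and visibly degraded sampling — and floored at max(V) -
(1 - 1/gamma) dE, so the deposited bias range never exceeds
(1 - 1/gamma) dE <= dE (30 kJ/mol by default). No kernel compression; the
bias lives on a 512-point grid and forces are its finite-difference
gradient. A run is flagged "converged" when the per-update sup-norm change
of the bias, relative to its maximum, stays below 1e-3 over the last 10% of
updates. Harmonic walls contribute kappa (excess)^2 with the PLUMED
quadratic-wall unit reading of the production wall constant
(2e3 kJ/mol/nm^2 = 20 kJ/mol/A^2); wall energies are recorded separately
from the bias.

## Reweighting and run averaging

Free-energy surfaces over any recorded CVs come from umbrella-sampling-type
reweighting with weights e^{beta (V + wall)}; bins never visited are NaN,
never zero. Adding any constant to the bias column changes no free-energy
value. Multi-run averaging aligns runs on a common additive gauge by
subtracting each run's Boltzmann-weighted mean free energy over the
globally deepest basin (bins within 2 kB*T of the pooled minimum) and then
combines bin-wise, either as the arithmetic mean of F (for mean-surface
plots with standard-error bars) or as the log of the mean Boltzmann density
(for downstream Boltzmann integrals). Scalar results carry
uncertainty-in-last-digit strings, e.g. "-8.53(5)".

## Association free energy (`pairing`)

W(r) = G(r) + kB*T ln(4 pi r^2) preserves the additive gauge. Tail
alignment subtracts the unweighted mean of W (zero-tail, window
[2 rc, r*]) or of W - E (Coulomb tail, window [12, r*] by default; both
windows configurable — only the 12 A landmark is given, not the window
widths). The association integral is composite Simpson of
4 pi r^2 e^{-beta W} on the native grid up to r* = 14 A (a fixed constant
here; its Bjerrum-length derivation is not reproduced); the hard-core
region below the first grid point contributes zero, which is logged when
that point exceeds 1 A. dG is only defined for tail-aligned curves —
alignment is what establishes W -> 0 at infinity. Uncertainties come from
recomputing dG per independent run. Dielectric rescaling replaces the tail
E(r; eps_old) -> E(r; eps_new) beyond the fit-window start and reports the
change in dG.

Basins are local minima over the visited region within a configurable
neighbourhood radius (plateau ties resolved to the lowest index and
flagged). Minimax barriers between grid regions use a priority flood
(Dijkstra with running-maximum cost), which is the exact discrete optimum
over 4-connected paths; disconnected regions give an infinite barrier.
Region free-energy differences integrate e^{-beta F} over equal-volume bins.

## The production pipeline and its study conditions

`workflows.association_pipeline` fixes the end-to-end conditions: four
seeds x 1e6 steps of OPES-biased radial dynamics (pace 500, barrier
30 kJ/mol, kernel bandwidth 0.15 A, friction 0.25/ps, dt 0.004 ps — a
fast-diffusing, large-step setting chosen purely for basin-tail round
trips, which the Metropolis adjustment makes safe), an
upper wall at 15 A (20 kJ/mol/A^2), staggered starting separations
(4/7/10/13 A), a 2-15 A reweighting grid with 0.05 A bins, the first half
of each run discarded as bias transient, density-mode run averaging, and
alignment windows ending at r* = 14 A. Under these conditions the recovered
dG agrees with deterministic quadrature of the generator potential to
within a few tenths of kJ/mol (verified over many independent seed sets in
the acceptance tests), and the Coulomb-aligned long-range preset is
strictly more negative than the zeroed-tail truncated counterpart — the
qualitative long-range-matters statement.

The ideal-pair null (`workflows.ideal_pair_null`) samples a zero potential
confined by a wall placed outside the analysis window and pools two runs at
a fast-diffusing setting (friction 0.05); a reflecting-sphere boundary was
rejected because mirror reflection of the radial coordinate biases the
density when steps are large. W(r) is then flat to a fraction of kB*T
wherever bins hold more than 100 samples.

## Structural and dynamical observables (`structure`)

RDFs use the standard ideal-gas shell normalisation with self-pairs
excluded and require r_max <= half the smallest box edge; difference curves
interpolate the second curve onto the first grid (cubic spline) over the
overlap. Sharp coordination counts use a closed boundary (a neighbour
exactly at the cutoff counts — an explicit tie-break). The cubic switch is
(y-1)^2(1+2y) with y = (d-D0)/(Dmax-D0): weight 1 at D0, 0 at Dmax, C1 at
both ends, monotone between. Electron-density profiles weight per-species
z-histograms by electron counts (O 8, H 1, C 6, Ca 20), use the mean z of
the topmost Ca layer as origin (single-linkage clustering, 1 A threshold)
and conserve total electrons exactly, including under Gaussian smoothing;
the lateral-area normalisation is carried so either e/A^3 or
per-unit-cell conventions can be emitted. Einstein diffusion uses multiple
time origins spaced by the fit-window length (default window 10-50% of the
trajectory), D = slope/6 in 1e-5 cm^2/s, and flags MSDs whose linear fit
has r^2 < 0.99 (ballistic misuse); finite-size extrapolation is ordinary
least squares of D against 1/L. The residence-time estimator — a
convention, since only experimental values are cited for it upstream — is
the bound-interval survival function with excursions shorter than t*
(default 2 ps) ignored and a weighted exponential fit; a never-bound series
returns NaN with a flag. Lattice constants divide supercell edges by
replication counts with block-averaged standard errors.

## Wannier-centroid electrostatics (`wannier`)

Charge bookkeeping: nuclei O +6, C +4, H +1, Ca +10; one -8 e centroid per
O (and per Ca in explicit mode; the default effective mode gives Ca a
single +2 e site and omits its centroids, since a short-ranged model
captures Ca polarisation within its cutoff — both conventions are
supported because the choice is not fixed upstream). Centers are matched
to host atoms by exact optimal assignment (Hungarian algorithm on
minimum-image distances with four slots per atom); this replaces a
greedy-and-rebalance scheme because the exact matcher is available, equally
fast at these sizes, and has no pathological cases. Centroid displacements
are minimum-image means of the four center displacements; displacements
over 1 A are flagged, assignment distances over 1.5 A warn. Externally
predicted displacements can be passed through in place of geometric ones.

The Gaussian density convention is rho(x) ∝ exp(-spread^2 |x|^2) with
spread in 1/A (default 0.1 A^-1, the upstream setting; the functional form
is a package reading, logged and exposed, since it is not defined
upstream). The periodic energy is a reciprocal-space-only sum with form
factor e^{-k^2/(2 spread^2)}, cutoff pi/grid_spacing (default grid 1 A),
isolated-Gaussian self energies subtracted, tin-foil (conducting) boundary
conditions, and a uniform-background correction for net-charged sets
(logged); a too-coarse Fourier grid raises an error with a suggested
spacing. This is exact for these wide Gaussians — validated against the
NaCl Madelung constant to 1e-7 and the single-charge Wigner lattice energy
to 1e-3 in the tests. Forces are the analytic negative gradient.

The independent oracle is a real-space image sum of
q_i q_j erf(spread/sqrt(2) r)/r over cubic shells of cells with two
corrections: the cell-dipole surface term 2 pi k_e M^2/(3V) (shell-ordered
vacuum sums converge to the conducting-boundary value plus this term), and
least-squares extrapolation of the remaining smooth quadrupole-tail
truncation error (E(S) = E_inf + sum a_p S^-p, p = 2..5, fitted on the
outermost shells, since inner shells of wide Gaussians are still inside
the erf transition). Agreement with the reciprocal-space energy is ~1e-5
kJ/mol on random neutral site sets. The oracle is O(N^2 shells^3) and for
verification only.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the estimators assume —
Boltzmann-distributed configurations of a known potential, exponential
kinetics, Gaussian committee noise, layered density — so passing tests
demonstrate the correctness of the analysis chain, including its exactness
properties (gauge invariances, conservation laws, closed forms, oracle
agreement) and its statistical behaviour at known ground truth. They do
not demonstrate anything about real water or real calcium carbonate: there
is no explicit solvent, no reactive chemistry, no Newtonian dynamics or
thermostats, and the model potentials are qualitative stand-ins, not fits.
Conclusions about the real system require trajectories from a production
force field; this package then supplies the analysis layer.

## Known limitations

* Orthorhombic boxes only; triclinic cells raise a clear error.
* OPES here is 1D (the pair separation or a line coordinate); no
  multi-walker sampling, no kernel compression, no 2D biasing.
* The association pipeline assumes the CV grid covers the sampled range
  and that the tail window is reachable within the run length; runs that
  never visit the window are skipped (with a warning) in the per-run
  uncertainty.
* The reciprocal-space electrostatics assumes one common spread per site
  set; per-site spreads are only supported in the oracle's pair formula.
* The residence-time and layer-origin conventions are package choices,
  stated above, not reproductions of a published estimator.
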