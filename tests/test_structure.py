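"""RDFs, coordination, density profiles, diffusion, residence, lattice."""

import math

import numpy as np
import pytest

from calcipair import (
    SimulationBox,
    SwitchSpec,
    Trajectory,
    brownian_trajectory,
    coordination_sharp,
    delta_rdf,
    einstein_diffusion,
    electron_density_profile,
    finite_size_extrapolate,
    lattice_constants,
    layered_interface_frames,
    rdf,
    residence_time,
    switch_cubic,
    two_state_residence_series,
)
from calcipair.errors import CalcipairError
from calcipair.structure import RadialDistribution
from calcipair.switching import switch_cubic_derivative


def uniform_gas(rng, n, box_edge, n_frames, species="O"):
    box = SimulationBox.cubic(box_edge)
    pos = rng.uniform(0, box_edge, (n_frames, n, 3))
    return Trajectory((species,) * n, pos, np.arange(n_frames, dtype=float), box, wrapped=True)


class TestRDF:
    def test_fixed_pair_single_bin(self):
        box = SimulationBox.cubic(30.0)
        pos = np.array([[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]])
        traj = Trajectory(("Ca", "O"), pos, np.array([0.0]), box, wrapped=True)
        g = rdf(traj, "Ca", "O", r_max=10.0, dr=0.1)
        nonzero = np.flatnonzero(g.g)
        assert nonzero.size == 1
        assert g.bin_centers[nonzero[0]] == pytest.approx(3.05, abs=0.051)

    def test_ideal_gas_unity(self, rng):
        traj = uniform_gas(rng, 150, 20.0, 80)
        g = rdf(traj, "O", "O", r_max=9.0, dr=0.25)
        sel = g.bin_centers >= 2.0
        # 3 counting sigmas: shell count ~ N(N-1)/2 / V * 4 pi r^2 dr per frame
        n_pairs = 150 * 149 / 2
        shell = 4 * np.pi * g.bin_centers[sel] ** 2 * 0.25
        expect = n_pairs / 20.0**3 * shell * 80
        sigma = 3.0 / np.sqrt(expect)
        assert np.all(np.abs(g.g[sel] - 1.0) < sigma)

    def test_noise_scales_with_frames(self):
        """Doubling the frame count halves the counting-noise variance
        (Poisson scaling), pooled over independent repetitions."""
        v_short, v_long = [], []
        for rep in range(16):
            rng = np.random.default_rng(1000 + rep)
            t1 = uniform_gas(rng, 100, 20.0, 30)
            t2 = uniform_gas(rng, 100, 20.0, 60)
            g1 = rdf(t1, "O", "O", r_max=9.0, dr=0.2)
            g2 = rdf(t2, "O", "O", r_max=9.0, dr=0.2)
            sel = g1.bin_centers >= 2.0
            v_short.append(np.mean((g1.g[sel] - 1.0) ** 2))
            v_long.append(np.mean((g2.g[sel] - 1.0) ** 2))
        ratio = np.mean(v_short) / np.mean(v_long)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_r_max_validated(self, rng):
        traj = uniform_gas(rng, 10, 10.0, 2)
        with pytest.raises(CalcipairError, match="half"):
            rdf(traj, "O", "O", r_max=6.0)


class TestDeltaRDF:
    def test_identical_curves_zero(self, rng):
        traj = uniform_gas(rng, 50, 20.0, 10)
        g = rdf(traj, "O", "O", r_max=8.0)
        d = delta_rdf(g, g)
        assert np.allclose(d.values, 0.0)

    def test_half_bin_offset_interpolation(self):
        centers1 = np.arange(0.025, 5.0, 0.05)
        centers2 = centers1 + 0.025
        smooth = lambda r: np.exp(-((r - 2.0) ** 2))
        g1 = RadialDistribution(centers1, smooth(centers1), ("A", "B"), 1, 0.05)
        g2 = RadialDistribution(centers2, smooth(centers2), ("A", "B"), 1, 0.05)
        d = delta_rdf(g1, g2)
        # cubic-spline interpolation error of a smooth curve on a 0.05 A grid
        assert np.max(np.abs(d.values)) < 1e-6

    def test_disjoint_ranges_empty(self):
        g1 = RadialDistribution(np.arange(0.05, 2.0, 0.1), np.ones(20), ("A", "B"), 1, 0.1)
        g2 = RadialDistribution(np.arange(5.05, 7.0, 0.1), np.ones(20), ("A", "B"), 1, 0.1)
        assert delta_rdf(g1, g2).values.size == 0


class TestCoordination:
    def test_four_neighbors_exact(self):
        box = SimulationBox.cubic(20.0)
        center = np.array([10.0, 10.0, 10.0])
        neighbors = center + np.array(
            [[2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0]]
        )
        pos = np.vstack([center[None], neighbors])[None]
        traj = Trajectory(("Ca",) + ("O",) * 4, pos, np.array([0.0]), box, wrapped=True)
        mean, err = coordination_sharp(traj, "Ca", "O", cutoff=3.1)
        assert mean == 4.0 and err == 0.0

    def test_boundary_closed(self):
        box = SimulationBox.cubic(20.0)
        pos = np.array([[[0.0, 0.0, 0.0], [3.1, 0.0, 0.0]]])
        traj = Trajectory(("Ca", "O"), pos, np.array([0.0]), box, wrapped=True)
        mean, _ = coordination_sharp(traj, "Ca", "O", cutoff=3.1)
        assert mean == 1.0  # neighbour exactly at the cutoff counts

    def test_ideal_gas_expectation(self, rng):
        traj = uniform_gas(rng, 300, 15.0, 40)
        cutoff = 3.3
        mean, _ = coordination_sharp(traj, "O", "O", cutoff=cutoff)
        rho = 299 / 15.0**3  # neighbours available per center
        expect = rho * 4.0 / 3.0 * math.pi * cutoff**3
        sigma = 3 * math.sqrt(expect / (300 * 40))
        assert abs(mean - expect) < sigma


class TestSwitchCubic:
    CA_OW = SwitchSpec(2.5, 3.75)   # calcium-water oxygen coordination
    OC_H = SwitchSpec(0.95, 1.6)    # carbonate oxygen protonation

    @pytest.mark.parametrize("spec", [CA_OW, OC_H])
    def test_endpoint_semantics(self, spec):
        assert switch_cubic(spec.d0, spec) == 1.0
        assert switch_cubic(spec.dmax, spec) == 0.0
        assert switch_cubic(spec.d0 - 0.2, spec) == 1.0
        assert switch_cubic(spec.dmax + 0.2, spec) == 0.0

    @pytest.mark.parametrize("spec", [CA_OW, OC_H])
    def test_midpoint_half(self, spec):
        mid = 0.5 * (spec.d0 + spec.dmax)
        assert switch_cubic(mid, spec) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("spec", [CA_OW, OC_H])
    def test_c1_at_both_ends(self, spec):
        """One-sided 4-point finite differences of the interior cubic are
        exact for cubics, so the derivative at D0 and Dmax must vanish to
        roundoff; outside the switch is constant."""
        h = (spec.dmax - spec.d0) / 100.0
        for x0, sgn in ((spec.d0, +1), (spec.dmax, -1)):
            pts = x0 + sgn * h * np.arange(4)
            w = np.asarray(switch_cubic(pts, spec))
            deriv = sgn * (-11 * w[0] + 18 * w[1] - 9 * w[2] + 2 * w[3]) / (6 * h)
            assert abs(deriv) < 1e-8
        assert switch_cubic_derivative(spec.d0, spec) == 0.0
        assert switch_cubic_derivative(spec.dmax, spec) == 0.0

    def test_monotone_nonincreasing(self):
        spec = SwitchSpec(2.5, 3.75)
        d = np.linspace(2.5, 3.75, 500)
        assert np.all(np.diff(np.asarray(switch_cubic(d, spec))) <= 0)


class TestDensityProfile:
    def test_single_layer_weight_arithmetic(self):
        traj = layered_interface_frames(
            [(0.0, "Ca", 4, 0.0), (2.0, "O", 4, 0.0)], (10.0, 10.0), 1, seed=0
        )
        profile = electron_density_profile(traj, bin_width=0.25)
        # the O layer sits 2 A above the Ca origin and carries 4 * 8 electrons;
        # a zero-width layer may straddle a bin edge, so sum a narrow window
        window = np.abs(profile.z_centers - 2.0) < 0.3
        electrons = profile.values[window].sum() * profile.lateral_area * profile.bin_width
        assert electrons == pytest.approx(32.0)

    def test_total_electron_conservation(self, rng):
        traj = layered_interface_frames(
            [(0.0, "Ca", 6, 0.2), (2.0, "O", 10, 0.3), (3.0, "H", 20, 0.4)],
            (12.0, 12.0), n_frames=7, seed=3,
        )
        profile = electron_density_profile(traj, bin_width=0.1)
        assert profile.total_electrons == pytest.approx(6 * 20 + 10 * 8 + 20 * 1, rel=1e-9)
        smoothed = electron_density_profile(traj, bin_width=0.1, smoothing=0.3)
        assert smoothed.total_electrons == pytest.approx(profile.total_electrons, rel=1e-6)

    def test_two_layer_peaks(self):
        traj = layered_interface_frames(
            [(0.0, "Ca", 8, 0.05), (2.0, "O", 30, 0.08), (5.0, "O", 30, 0.08)],
            (15.0, 15.0), n_frames=25, seed=4,
        )
        profile = electron_density_profile(traj, bin_width=0.2)
        for z0 in (2.0, 5.0):
            window = np.abs(profile.z_centers - z0) < 0.5
            peak = profile.z_centers[window][np.argmax(profile.values[window])]
            assert abs(peak - z0) <= 0.2

    def test_missing_ca_rejected(self):
        traj = layered_interface_frames([(2.0, "O", 5, 0.1)], (10.0, 10.0), 2, seed=0)
        with pytest.raises(CalcipairError, match="Ca"):
            electron_density_profile(traj)


class TestDiffusion:
    def test_recovers_generator_d(self):
        traj = brownian_trajectory(
            2.4e-5, 1000, 400, 0.1, seed=11, box=SimulationBox.cubic(30)
        )
        result = einstein_diffusion(traj)
        assert result.d == pytest.approx(2.4, rel=0.05)
        assert not result.low_quality

    def test_static_particles_zero(self):
        traj = brownian_trajectory(0.0, 20, 100, 0.1, seed=0, box=SimulationBox.cubic(30))
        assert einstein_diffusion(traj).d == 0.0

    def test_ballistic_flagged(self):
        box = SimulationBox.cubic(100.0)
        times = np.arange(200) * 0.1
        v = np.array([1.0, 0.5, -0.2])
        pos = times[:, None, None] * v[None, None, :] + np.zeros((200, 5, 3))
        traj = Trajectory(("O",) * 5, pos, times, box, wrapped=False)
        result = einstein_diffusion(traj)
        assert result.low_quality

    def test_finite_size_exact_linear_recovery(self):
        """D(L) = D_inf - a/L at the production box edges 18/36/53 A is
        recovered exactly by the 1/L least-squares intercept."""
        edges = np.array([18.0, 36.0, 53.0])
        d_vals = 2.4 - 10.0 / edges
        d_inf, slope = finite_size_extrapolate(d_vals, edges)
        assert d_inf == pytest.approx(2.4, abs=1e-12)
        assert slope == pytest.approx(-10.0, abs=1e-9)

    def test_finite_size_degenerate_cases(self):
        d_inf, slope = finite_size_extrapolate([1.5, 1.5, 1.5], [18, 36, 53])
        assert d_inf == pytest.approx(1.5, abs=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-9)
        d_inf, _ = finite_size_extrapolate([2.0, 2.2], [20, 40])
        assert d_inf == pytest.approx(2.4, abs=1e-12)  # exact line through 2 points


class TestResidence:
    def test_recovers_generator_tau(self):
        series = two_state_residence_series(100.0, 50.0, 10_000, seed=21, dt=0.5)
        result = residence_time(series, transient_tolerance=0.0)
        assert result.defined
        assert result.tau == pytest.approx(100.0, rel=0.10)

    def test_never_bound_undefined(self):
        result = residence_time(np.zeros(100, dtype=bool), dt=0.5)
        assert not result.defined
        assert math.isnan(result.tau)

    def test_transient_tolerance_noop_without_short_excursions(self):
        series = two_state_residence_series(50.0, 50.0, 200, seed=5, dt=0.5)
        # remove excursions shorter than 2 ps so t* cannot matter
        from calcipair.toysim import ResidenceSeries

        ind = series.indicator.copy()
        padded = np.concatenate([[True], ind, [True]])
        changes = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(changes[::2], changes[1::2]):
            if stop - start < 4:
                ind[start:stop] = True
        clean = ResidenceSeries(ind, series.dt)
        r0 = residence_time(clean, transient_tolerance=0.0)
        r1 = residence_time(clean, transient_tolerance=series.dt)
        assert r0.tau == pytest.approx(r1.tau, rel=1e-12)


class TestLatticeConstants:
    def test_constant_edges(self):
        series = np.full((100, 1), 49.84)
        [(mean, err, text)] = lattice_constants(series, [10])
        assert mean == pytest.approx(4.984)
        assert err == 0.0
        assert text == "4.984(0)"

    def test_white_noise_uncertainty(self, rng):
        series = (17.07 + rng.normal(0, 0.02, 2000))[:, None]
        [(mean, err, _)] = lattice_constants(series, [1], n_blocks=20)
        expected = 0.02 / math.sqrt(2000)
        assert err == pytest.approx(expected, rel=0.2)
        assert mean == pytest.approx(17.07, abs=3 * expected)

    def test_replication_one_passthrough(self):
        series = np.column_stack([np.linspace(4.9, 5.1, 50), np.full(50, 8.0)])
        out = lattice_constants(series, [1, 1])
        assert out[0][0] == pytest.approx(5.0)
        assert out[1][0] == pytest.approx(8.0)
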