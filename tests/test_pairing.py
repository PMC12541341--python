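"""Entropy correction, tail alignment, association dG, basins and barriers."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calcipair import (
    AssociationSpec,
    FESAxis,
    FESGrid,
    RadialPMF,
    TailSpec,
    align_tail_coulomb,
    align_tail_zero,
    association_delta_g,
    coulomb_tail,
    dielectric_rescale,
    entropy_correct,
    load_preset,
    locate_basins,
    minimax_barrier,
    state_free_energy_difference,
)
from calcipair.errors import CalcipairError, ContractError
from calcipair.pairing import ZEROED_TAIL
from calcipair.units import COULOMB


def make_pmf(r, w, thermo, alignment="raw", tail=None):
    return RadialPMF(r=np.asarray(r, float), w=np.asarray(w, float),
                     thermo=thermo, alignment=alignment, tail=tail)


class TestEntropyCorrect:
    def test_ideal_pair_flattens_to_zero(self, thermo):
        r = np.linspace(0.5, 14.0, 200)
        g = -thermo.kbt * np.log(4 * np.pi * r**2)
        pmf = entropy_correct((r, g), thermo)
        assert np.allclose(pmf.w, 0.0, atol=1e-12)

    def test_closed_form_at_unit_radius(self, thermo):
        pmf = entropy_correct((np.array([1.0]), np.array([0.0])), thermo)
        assert pmf.w[0] == pytest.approx(thermo.kbt * math.log(4 * math.pi), rel=1e-12)
        assert pmf.w[0] == pytest.approx(6.944, abs=1e-3)

    def test_nonpositive_r_rejected(self, thermo):
        with pytest.raises(Exception):
            entropy_correct((np.array([0.0, 1.0]), np.zeros(2)), thermo)

    def test_accepts_fes_grid(self, thermo):
        fes = FESGrid([FESAxis.linear("d", 2.0, 4.0, 10)], np.zeros(10))
        pmf = entropy_correct(fes, thermo)
        assert pmf.alignment == "raw"
        assert pmf.r[0] == pytest.approx(2.1)


class TestCoulombTail:
    def test_paper_value_at_bjerrum_distance(self, thermo):
        """Charges +2/-2 screened by eps=102 at r* = 14 A: -3.892 kJ/mol."""
        tail = TailSpec(-4.0, 102.0, (12.0, 14.0))
        assert coulomb_tail(14.0, tail) == pytest.approx(
            COULOMB * (-4.0) / (102.0 * 14.0), rel=1e-12
        )
        assert coulomb_tail(14.0, tail) == pytest.approx(-3.892, abs=5e-4)

    def test_perfect_screening(self):
        assert coulomb_tail(5.0, TailSpec(-4.0, 1e12, (1, 2))) == pytest.approx(0.0, abs=1e-8)

    def test_inverse_distance_scaling(self):
        tail = TailSpec(-4.0, 102.0, (1, 2))
        assert coulomb_tail(10.0, tail) == pytest.approx(coulomb_tail(5.0, tail) / 2)


class TestAlignment:
    def test_constant_shifts_to_zero(self, thermo):
        r = np.linspace(2.0, 15.0, 131)
        pmf = make_pmf(r, np.full_like(r, 3.7), thermo)
        aligned = align_tail_zero(pmf, 6.0, 14.0)
        window = aligned.window_mask(12.0, 14.0)
        assert np.mean(aligned.w[window]) == pytest.approx(0.0, abs=1e-12)
        assert aligned.alignment == ZEROED_TAIL

    def test_idempotent_when_zero_mean(self, thermo, rng):
        r = np.linspace(2.0, 15.0, 131)
        w = rng.normal(0, 0.1, r.size)
        window = (r >= 12.0) & (r <= 14.0)
        w[window] -= w[window].mean()
        pmf = make_pmf(r, w, thermo)
        aligned = align_tail_zero(pmf, 6.0, 14.0)
        assert np.allclose(aligned.w, w, atol=1e-12)

    def test_noisy_tail_mean_exactly_removed(self, thermo, rng):
        r = np.linspace(2.0, 15.0, 131)
        pmf = make_pmf(r, rng.normal(5.0, 0.1, r.size), thermo)
        aligned = align_tail_zero(pmf, 6.0, 14.0)
        assert abs(np.mean(aligned.w[aligned.window_mask(12.0, 14.0)])) < 1e-12

    def test_empty_window_error(self, thermo):
        pmf = make_pmf(np.linspace(2.0, 8.0, 30), np.zeros(30), thermo)
        with pytest.raises(CalcipairError, match="window"):
            align_tail_zero(pmf, 6.0, 14.0)

    def test_coulomb_alignment_removes_offset(self, thermo):
        r = np.linspace(2.0, 15.0, 131)
        tail = TailSpec(-4.0, 102.0, (12.0, 14.0))
        w = coulomb_tail(r, tail) + 5.0
        aligned = align_tail_coulomb(make_pmf(r, w, thermo), tail)
        assert np.allclose(aligned.w, coulomb_tail(r, tail), atol=1e-12)

    def test_coulomb_alignment_idempotent(self, thermo):
        r = np.linspace(2.0, 15.0, 131)
        tail = TailSpec(-4.0, 102.0, (12.0, 14.0))
        w = np.asarray(coulomb_tail(r, tail))
        aligned = align_tail_coulomb(make_pmf(r, w, thermo), tail)
        assert np.allclose(aligned.w, w, atol=1e-12)


class TestAssociationDeltaG:
    def test_ideal_gas_closed_form(self, thermo):
        """W = 0 up to r* = 14 A: dG = -kBT ln(C0 (4/3) pi r*^3) = -5.31."""
        r = np.linspace(1e-3, 14.0, 14001)
        pmf = make_pmf(r, np.zeros_like(r), thermo, alignment=ZEROED_TAIL)
        dg = association_delta_g(pmf, AssociationSpec(), thermo)
        closed = -thermo.kbt * math.log(4.0 / 3.0 * math.pi * 14.0**3 / 1660.0)
        assert dg == pytest.approx(closed, rel=1e-6)
        assert dg == pytest.approx(-5.31, abs=5e-3)

    def test_constant_offset_passes_through(self, thermo):
        r = np.linspace(1e-3, 14.0, 14001)
        pmf = make_pmf(r, np.full_like(r, 50.0), thermo, alignment=ZEROED_TAIL)
        dg = association_delta_g(pmf, AssociationSpec(), thermo)
        closed = 50.0 - thermo.kbt * math.log(4.0 / 3.0 * math.pi * 14.0**3 / 1660.0)
        assert dg == pytest.approx(closed, rel=1e-9)

    def test_grid_refinement_invariance(self, thermo):
        def dg(n):
            r = np.linspace(0.5, 14.0, n)
            w = 5.0 * np.exp(-((r - 3.0) ** 2)) * -1.0
            return association_delta_g(
                make_pmf(r, w, thermo, alignment=ZEROED_TAIL), AssociationSpec(), thermo
            )

        assert abs(dg(2001) - dg(4001)) < 0.01

    def test_unaligned_pmf_rejected(self, thermo):
        r = np.linspace(1.0, 14.0, 100)
        with pytest.raises(ContractError):
            association_delta_g(make_pmf(r, np.zeros(100), thermo), AssociationSpec(), thermo)

    def test_r_star_beyond_grid_rejected(self, thermo):
        r = np.linspace(1.0, 10.0, 100)
        pmf = make_pmf(r, np.zeros(100), thermo, alignment=ZEROED_TAIL)
        with pytest.raises(CalcipairError, match="beyond"):
            association_delta_g(pmf, AssociationSpec(r_star=14.0), thermo)


class TestDielectricRescale:
    @staticmethod
    def _aligned_lr_pmf(thermo):
        r = np.linspace(0.5, 14.0, 2701)
        tail = TailSpec(-4.0, 102.0, (12.0, 14.0))
        pot = load_preset("caco3_lr")
        w = np.asarray(pot.energy(r))
        return align_tail_coulomb(make_pmf(r, w, thermo), tail)

    def test_same_epsilon_zero_shift(self, thermo):
        pmf = self._aligned_lr_pmf(thermo)
        assert dielectric_rescale(pmf, 102.0) == pytest.approx(0.0, abs=1e-12)

    def test_less_screening_more_association(self, thermo):
        pmf = self._aligned_lr_pmf(thermo)
        assert dielectric_rescale(pmf, 78.0) < 0.0

    def test_matches_brute_force_generator_recomputation(self, thermo):
        """Rescaling the tail dielectric 102 -> 78 reproduces the dG change
        of re-integrating the generator potential with the modified tail."""
        from calcipair.workflows import true_association_delta_g
        from dataclasses import replace

        pmf = self._aligned_lr_pmf(thermo)
        ddg = dielectric_rescale(pmf, 78.0)
        pot = load_preset("caco3_lr")
        pot78 = replace(pot, epsilon=78.0)
        # brute force: modify the tail beyond the fit-window start only
        r = np.linspace(1e-3, 14.0, 28001)
        u = np.asarray(pot.energy(r))
        beyond = r >= 12.0
        u78 = u.copy()
        u78[beyond] += np.asarray(pot78.tail_energy(r[beyond])) - np.asarray(
            pot.tail_energy(r[beyond])
        )
        from scipy.integrate import simpson

        def dg_of(uu):
            integrand = 4 * np.pi * r**2 * np.exp(-thermo.beta * uu)
            return -thermo.kbt * math.log(simpson(integrand, x=r) / 1660.0)

        assert ddg == pytest.approx(dg_of(u78) - dg_of(u), abs=0.1)


class TestLocateBasins:
    def test_single_parabola(self, thermo):
        axis = FESAxis.linear("d", 0.0, 10.0, 50)
        values = (axis.centers - 4.3) ** 2
        basins = locate_basins(FESGrid([axis], values))
        assert len(basins) == 1
        assert abs(basins[0].position[0] - 4.3) <= axis.width

    def test_preset_surface_basins(self, thermo):
        """Basins of the analytic preset potential are recovered within one
        bin of the curve's true local minima."""
        pot = load_preset("caco3_lr")
        axis = FESAxis.linear("d", 2.2, 8.0, 232)  # dr = 0.025
        u = np.asarray(pot.energy(axis.centers))
        basins = locate_basins(FESGrid([axis], u), search_radius=4)
        # true minima from a dense scan
        r_dense = np.linspace(2.2, 8.0, 100_001)
        u_dense = np.asarray(pot.energy(r_dense))
        interior = (
            (u_dense < np.roll(u_dense, 1)) & (u_dense < np.roll(u_dense, -1))
        )
        interior[[0, -1]] = False
        true_minima = r_dense[interior]
        assert len(basins) == len(true_minima)
        found = sorted(b.position[0] for b in basins)
        for f, t in zip(found, sorted(true_minima)):
            assert abs(f - t) <= axis.width

    def test_constant_grid_no_basins(self, caplog):
        import logging

        axis = FESAxis.linear("d", 0.0, 1.0, 10)
        with caplog.at_level(logging.WARNING, logger="calcipair"):
            basins = locate_basins(FESGrid([axis], np.zeros(10)))
        assert basins == []

    def test_plateau_tie_flagged_lowest_index(self):
        axis = FESAxis.linear("d", 0.0, 6.0, 6)
        values = np.array([5.0, 1.0, 1.0, 1.0, 5.0, 6.0])
        basins = locate_basins(FESGrid([axis], values), search_radius=1)
        assert len(basins) == 1
        assert basins[0].index == (1,)
        assert basins[0].plateau


def brute_force_minimax(values, a_set, b_set):
    """Exhaustive enumeration of simple 4-connected paths (oracle)."""
    shape = values.shape
    best = math.inf

    def neighbours(idx):
        for dim in range(len(shape)):
            for off in (-1, 1):
                j = idx[dim] + off
                if 0 <= j < shape[dim]:
                    yield idx[:dim] + (j,) + idx[dim + 1:]

    b_lookup = set(b_set)

    def dfs(idx, running_max, visited):
        nonlocal best
        running_max = max(running_max, values[idx])
        if running_max >= best:
            return
        if idx in b_lookup:
            best = running_max
            return
        for nb in neighbours(idx):
            if nb not in visited and np.isfinite(values[nb]):
                dfs(nb, running_max, visited | {nb})

    for a in a_set:
        dfs(a, -math.inf, {a})
    return best


class TestMinimaxBarrier:
    def test_1d_hand_example(self):
        axis = FESAxis.linear("d", 0.0, 5.0, 5)
        values = np.array([0.0, 12.0, 4.0, 20.0, 2.0])
        barrier, pass_value, path = minimax_barrier(FESGrid([axis], values), [(0,)], [(4,)])
        assert pass_value == 20.0
        assert barrier == 20.0
        assert path[0] == (0,) and path[-1] == (4,)

    def test_3x3_hand_example(self):
        axes = [FESAxis.linear("x", 0, 3, 3), FESAxis.linear("y", 0, 3, 3)]
        values = np.array([[0.0, 9.0, 2.0], [4.0, 8.0, 3.0], [1.0, 7.0, 0.0]])
        barrier, pass_value, _ = minimax_barrier(
            FESGrid(axes, values), [(0, 0)], [(2, 2)]
        )
        assert pass_value == 7.0

    def test_b_subset_of_a_zero_barrier(self):
        axis = FESAxis.linear("d", 0.0, 5.0, 5)
        values = np.array([0.0, 12.0, 4.0, 20.0, 2.0])
        barrier, _, _ = minimax_barrier(
            FESGrid([axis], values), [(0,), (1,), (2,)], [(1,)]
        )
        assert barrier == 0.0

    def test_disconnected_infinite(self):
        axis = FESAxis.linear("d", 0.0, 5.0, 5)
        values = np.array([0.0, np.nan, np.nan, np.nan, 2.0])
        barrier, _, path = minimax_barrier(FESGrid([axis], values), [(0,)], [(4,)])
        assert math.isinf(barrier)
        assert path == []

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        values = np.round(rng.uniform(0, 30, (nx, ny)), 2)
        axes = [FESAxis.linear("x", 0, nx, nx), FESAxis.linear("y", 0, ny, ny)]
        a = (int(rng.integers(nx)), int(rng.integers(ny)))
        b = (int(rng.integers(nx)), int(rng.integers(ny)))
        fes = FESGrid(axes, values)
        _, pass_value, _ = minimax_barrier(fes, [a], [b])
        assert pass_value == pytest.approx(brute_force_minimax(values, [a], [b]))


class TestStateFreeEnergy:
    def test_identical_regions_zero(self, thermo):
        axis = FESAxis.linear("d", 0, 10, 20)
        fes = FESGrid([axis], np.linspace(0, 5, 20))
        region = [(i,) for i in range(5)]
        assert state_free_energy_difference(fes, region, region, thermo) == 0.0

    def test_symmetric_double_well_zero(self, thermo):
        axis = FESAxis.linear("x", -2, 2, 80)
        values = 10.0 * (axis.centers**2 - 1.0) ** 2
        fes = FESGrid([axis], values)
        a = [(i,) for i in range(40)]
        b = [(i,) for i in range(40, 80)]
        assert state_free_energy_difference(fes, a, b, thermo) == pytest.approx(0.0, abs=1e-9)

    def test_laplace_limit_recovers_offset(self, thermo):
        """Two narrow equal-width wells offset by delta: dF -> delta as the
        wells become narrow."""
        delta = 3.0
        axis = FESAxis.linear("x", -2, 2, 4000)
        x = axis.centers
        width = 0.01
        values = np.minimum(
            (x + 1.0) ** 2 / (2 * width**2) * thermo.kbt,
            (x - 1.0) ** 2 / (2 * width**2) * thermo.kbt + delta,
        )
        fes = FESGrid([axis], values)
        a = [(i,) for i in np.flatnonzero(x < 0)]
        b = [(i,) for i in np.flatnonzero(x > 0)]
        assert state_free_energy_difference(fes, a, b, thermo) == pytest.approx(
            delta, abs=0.02
        )
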