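"""State enumeration, generator assembly, stationary solve and observables."""

import math

import numpy as np
import pytest

from exoantenna.antenna import RC_ID, build_branched, build_illustrative
from exoantenna.constants import k_B
from exoantenna.photophysics import ThermoParams
from exoantenna.steady_state import (EMPTY, build_generator, build_rate_set,
                                     enumerate_states, gillespie, observables,
                                     quantum_efficiency, solve_photosystem,
                                     solve_stationary)


class TestStateSpace:
    def test_counts_scale_as_twice_locations(self):
        g3 = build_branched(3, 1, 10, [665.0])
        assert len(enumerate_states(g3)) == 10  # 2 * (3 + 2)
        g1 = build_illustrative(50, 660.0)
        assert len(enumerate_states(g1)) == 6

    def test_indices_bijective(self):
        space = enumerate_states(build_branched(2, 2, 10, [665.0]))
        assert len(space.index) == len(space.states)
        for s, i in space.index.items():
            assert space.states[i] == s


class TestGenerator:
    def test_columns_sum_to_zero(self, sun_flux):
        g = build_branched(2, 3, 50, [660.0])
        rates = build_rate_set(g, sun_flux)
        q = build_generator(enumerate_states(g), rates)
        np.testing.assert_allclose(q.sum(axis=0), 0, atol=1e-12 * np.abs(q).max())

    def test_dark_generator_has_no_absorption_edges(self):
        g = build_illustrative(50, 660.0)
        space = enumerate_states(g)
        q = build_generator(space, build_rate_set(g, None))
        i_empty0 = space.index[(EMPTY, 0)]
        assert q[:, i_empty0].sum() == 0  # ground state is absorbing
        assert q[space.index[("s1", 0)], i_empty0] == 0

    def test_absorption_entry_is_gamma_times_pool_size(self, sun_flux):
        g = build_illustrative(100, 659.0)
        space = enumerate_states(g)
        rates = build_rate_set(g, sun_flux)
        q = build_generator(space, rates)
        entry = q[space.index[("s1", 0)], space.index[(EMPTY, 0)]]
        assert entry == pytest.approx(rates.gamma["s1"] * 100, rel=1e-12)

    def test_detailed_balance_of_assembled_rates(self, sun_flux):
        g = build_branched(2, 2, 100, [660.0])
        rates = build_rate_set(g, sun_flux)
        th = rates.thermo
        nodes = {s.id: s for s in g.subunits}
        for (a, b), k_ab in rates.k.items():
            k_ba = rates.k[(b, a)]
            la = nodes[a].profile.lambda_peak if a in nodes else g.rc.profile.lambda_peak
            lb = nodes[b].profile.lambda_peak if b in nodes else g.rc.profile.lambda_peak
            na = nodes[a].n_pigments if a in nodes else g.rc.n_pigments
            nb = nodes[b].n_pigments if b in nodes else g.rc.n_pigments
            from exoantenna.photophysics import free_energy
            df = free_energy(la, na, lb, nb, th.temperature).dF
            assert k_ab / k_ba == pytest.approx(math.exp(-df * th.beta),
                                                rel=1e-12)


class TestStationary:
    def test_dark_system_rests_in_open_ground_state(self):
        g = build_branched(2, 2, 10, [665.0])
        space = enumerate_states(g)
        pi = solve_stationary(build_generator(space, build_rate_set(g, None)))
        assert pi[space.index[(EMPTY, 0)]] == pytest.approx(1.0, abs=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_branches_have_equal_occupancy(self, sun_flux):
        g = build_branched(2, 1, 50, [665.0])
        res = solve_photosystem(g, sun_flux, compute_phi=False)
        occ = list(res.occ_subunits.values())
        assert occ[0] == pytest.approx(occ[1], rel=1e-9)

    def test_probabilities_conserved_on_randomized_systems(self, sun_flux):
        rng = np.random.default_rng(7)
        for _ in range(8):
            g = build_branched(int(rng.integers(1, 5)), int(rng.integers(1, 4)),
                               int(rng.integers(5, 120)),
                               [float(rng.uniform(620, 700))])
            th = ThermoParams(k_hop=float(rng.uniform(1e10, 2e11)),
                              k_diss=float(rng.uniform(1e8, 5e9)))
            res = solve_photosystem(g, sun_flux, thermo=th, compute_phi=False)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(res.probabilities >= 0)
            assert np.all(res.probabilities <= 1)
            assert 0 <= res.occ_trap <= 1
            assert res.nu_e <= th.k_out

    def test_non_conservative_matrix_rejected(self):
        with pytest.raises(ValueError, match="conservative"):
            solve_stationary(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestObservables:
    def test_electron_output_is_k_out_times_trap_occupancy(self, sun_flux):
        g = build_branched(6, 2, 100, [665.0])
        res = solve_photosystem(g, sun_flux, compute_phi=False)
        assert res.nu_e == pytest.approx(100.0 * res.occ_trap, rel=1e-12)
        assert res.nu_e_per_pigment == pytest.approx(res.nu_e / 1200, rel=1e-12)

    def test_output_monotone_in_flux_over_six_decades(self, sun_flux):
        g = build_branched(6, 2, 100, [665.0])
        rates = build_rate_set(g, sun_flux)
        space = enumerate_states(g)
        outputs = []
        for scale in 10.0 ** np.arange(-3, 4):
            pi = solve_stationary(build_generator(space, rates, gamma_scale=scale))
            outputs.append(observables(pi, space, rates, g).nu_e)
        assert np.all(np.diff(outputs) > 0)

    def test_output_saturates_at_k_out(self, sun_flux):
        g = build_branched(6, 5, 100, [665.0])
        rates = build_rate_set(g, sun_flux)
        space = enumerate_states(g)
        pi = solve_stationary(build_generator(space, rates, gamma_scale=1e6))
        res = observables(pi, space, rates, g)
        assert res.nu_e <= 100.0
        assert res.nu_e == pytest.approx(100.0, rel=0.01)

    def test_quantum_efficiency_unity_without_dissipation(self, sun_flux):
        g = build_illustrative(50, 665.0)
        th = ThermoParams(k_diss=0.0)
        rates = build_rate_set(g, sun_flux, th)
        assert quantum_efficiency(enumerate_states(g), rates) \
            == pytest.approx(1.0, abs=1e-12)

    def test_quantum_efficiency_in_unit_interval_and_scale_free(self, sun_flux):
        g = build_branched(2, 2, 100, [660.0])
        rates = build_rate_set(g, sun_flux)
        phi = quantum_efficiency(enumerate_states(g), rates)
        assert 0 < phi < 1
        res = solve_photosystem(g, sun_flux)
        assert res.phi_e == pytest.approx(phi, rel=1e-9)


class TestGillespie:
    def test_same_seed_reproduces_trajectory(self, sun_flux):
        g = build_illustrative(100, 660.0)
        rates = build_rate_set(g, sun_flux)
        a = gillespie(g, rates, seed=11, n_events=2000)
        b = gillespie(g, rates, seed=11, n_events=2000)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        assert a.nu_e == b.nu_e

    def test_electron_and_trap_fill_counts_balance(self, sun_flux):
        g = build_illustrative(100, 660.0)
        rates = build_rate_set(g, sun_flux)
        sim = gillespie(g, rates, seed=3, n_events=20_000, gamma_scale=1.0)
        assert sim.electron_events > 100
        assert abs(sim.electron_events - sim.trap_fill_events) <= 1

    def test_matches_linear_solve_on_illustrative_model(self, sun_flux):
        g = build_illustrative(100, 660.0)
        rates = build_rate_set(g, sun_flux)
        space = enumerate_states(g)
        pi = solve_stationary(build_generator(space, rates, gamma_scale=5.0))
        res = observables(pi, space, rates, g)
        sim = gillespie(g, rates, seed=42, n_events=60_000, gamma_scale=5.0)
        assert abs(sim.nu_e - res.nu_e) <= 3 * sim.nu_e_se
        assert abs(sim.occ_trap() - res.occ_trap) \
            <= 3 * max(sim.occupancy_se.max(), 1e-4)

    def test_agrees_with_solver_on_randomized_systems(self, sun_flux):
        rng = np.random.default_rng(123)
        for trial in range(5):
            g = build_branched(int(rng.integers(1, 4)), int(rng.integers(1, 3)),
                               int(rng.integers(10, 120)),
                               [float(rng.uniform(630, 690))])
            scale = float(rng.uniform(2, 20))
            rates = build_rate_set(g, sun_flux)
            space = enumerate_states(g)
            pi = solve_stationary(build_generator(space, rates, gamma_scale=scale))
            res = observables(pi, space, rates, g)
            sim = gillespie(g, rates, seed=1000 + trial, n_events=40_000,
                            gamma_scale=scale)
            occ_sub_sim = sum(
                p for (loc, t), p in zip(space.states, sim.occupancy)
                if loc not in (EMPTY, RC_ID))
            occ_sub_ref = sum(res.occ_subunits.values())
            tol = 3 * max(float(sim.occupancy_se.max()), 3e-4)
            assert abs(sim.occ_trap() - res.occ_trap) <= tol
            assert abs(occ_sub_sim - occ_sub_ref) <= tol

    def test_dark_start_is_absorbing(self, caplog):
        g = build_illustrative(10, 665.0)
        rates = build_rate_set(g, None)
        with caplog.at_level("WARNING"):
            sim = gillespie(g, rates, seed=1, n_events=1000)
        assert sim.electron_events == 0
        assert "absorbing" in caplog.text
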