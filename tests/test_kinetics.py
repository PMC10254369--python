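"""Eyring rates, master-equation kinetics, RCMC contraction, navigation."""

import numpy as np
import pytest

from forcepath.afir import ReactionNetwork, ReactionPath
from forcepath.constants import BOLTZMANN_J, GAS_CONSTANT_KJ, PLANCK_J
from forcepath.fixtures import random_rate_model
from forcepath.geometry import surface_point
from forcepath.kinetics import (
    RateModel,
    build_rate_model,
    eyring_rate,
    kinetic_navigation_select,
    ode_oracle,
    rcmc_contract,
    yield_report,
)


def _toy_network(energies, edges):
    """Hand-built network: energies per EQ, edges as (a, b, ts_energy)."""
    net = ReactionNetwork()
    for i, e in enumerate(energies):
        net.add_eq(surface_point(float(i), 0.0), e)
    for k, (a, b, ts) in enumerate(edges):
        frames = [net.eq(a).geometry, surface_point(0.5 * (a + b), 1.0), net.eq(b).geometry]
        es = np.array([energies[a], ts, energies[b]])
        net.add_path(ReactionPath(frames, es, 1, (a, b), k))
    return net


class TestEyring:
    def test_zero_barrier_gives_prefactor(self):
        for T in (250.0, 300.0, 350.0):
            assert eyring_rate(0.0, T) == BOLTZMANN_J * T / PLANCK_J

    def test_rt_ln10_reduces_rate_tenfold(self):
        T = 300.0
        ddG = GAS_CONSTANT_KJ * T * np.log(10.0)
        assert eyring_rate(ddG, T) == pytest.approx(eyring_rate(0.0, T) / 10.0, rel=1e-12)

    def test_prefactor_at_300K_from_constants_arithmetic(self):
        # independent CODATA arithmetic, no kinetics code involved
        expected = 1.380649e-23 * 300.0 / 6.62607015e-34
        assert eyring_rate(0.0, 300.0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eyring_rate(-1.0, 300.0)
        with pytest.raises(ValueError):
            eyring_rate(5.0, 0.0)


class TestBuildRateModel:
    def test_symmetric_double_well(self):
        net = _toy_network([0.0, 0.0], [(0, 1, 40.0)])
        model = build_rate_model(net, 300.0)
        assert model.rate_matrix[0, 1] == pytest.approx(model.rate_matrix[1, 0], rel=1e-12)

    def test_parallel_paths_double_the_rate(self):
        single = build_rate_model(_toy_network([0.0, -5.0], [(0, 1, 40.0)]), 300.0)
        double = build_rate_model(
            _toy_network([0.0, -5.0], [(0, 1, 40.0), (0, 1, 40.0)]), 300.0
        )
        assert double.rate_matrix[0, 1] == pytest.approx(2 * single.rate_matrix[0, 1], rel=1e-12)

    def test_flagged_paths_are_excluded(self):
        net = _toy_network([0.0, 0.0], [(0, 1, 40.0), (0, 1, 20.0)])
        net.paths[1].flag = "incomplete"
        model = build_rate_model(net, 300.0)
        ref = build_rate_model(_toy_network([0.0, 0.0], [(0, 1, 40.0)]), 300.0)
        assert model.rate_matrix[0, 1] == ref.rate_matrix[0, 1]

    def test_muller_brown_rates_match_saddle_oracle(self, mb_fixture, mb_oracle):
        # the refined network's dominant channel between each basin pair must
        # carry the Eyring rate of the oracle saddle; parallel higher paths
        # only add on top of it
        model = build_rate_model(mb_fixture.network, 300.0)
        energies = {i: e for i, (_, e) in enumerate(mb_oracle["stationary"]["minima"])}
        for i, j, e_saddle in mb_oracle["catalog"]:
            best_ts = min(
                p.ts_energy
                for p in mb_fixture.network.paths
                if p.flag == "ok" and tuple(sorted(p.endpoints)) == (i, j)
            )
            k_best = eyring_rate(max(best_ts - energies[i], 0.0), 300.0)
            k_oracle = eyring_rate(e_saddle - energies[i], 300.0)
            assert k_best == pytest.approx(k_oracle, rel=0.15)
            assert model.rate_matrix[i, j] >= k_best * (1 - 1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateModel(300.0, np.array([[0.0, -1.0], [0.0, 0.0]]), np.zeros(2))


class TestOdeOracle:
    def test_isolated_state_is_static(self):
        model = RateModel(300.0, np.zeros((1, 1)), np.zeros(1))
        state = ode_oracle(model, [1.0], 10.0)
        assert state.populations[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_two_state_equilibrates_to_half(self):
        k = 1e3
        model = RateModel(300.0, np.array([[0.0, k], [k, 0.0]]), np.zeros(2))
        state = ode_oracle(model, [1.0, 0.0], 1.0)
        assert np.allclose(state.populations, 0.5, atol=1e-6)

    def test_detailed_balance_ratio(self):
        T, dE = 300.0, 10.0
        k_f = eyring_rate(20.0, T)  # low barrier: fast equilibration
        k_b = eyring_rate(20.0 + dE, T)
        model = RateModel(T, np.array([[0.0, k_f], [k_b, 0.0]]), np.array([0.0, -dE]))
        state = ode_oracle(model, [1.0, 0.0], 1e-4, rtol=1e-12, atol=1e-14)
        ratio = state.populations[1] / state.populations[0]
        assert ratio == pytest.approx(np.exp(dE / (GAS_CONSTANT_KJ * T)), rel=1e-6)

    def test_conservation(self):
        model = random_rate_model(10, 3)
        p0 = np.full(10, 0.1)
        state = ode_oracle(model, p0, 1.0)
        assert state.populations.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(state.populations >= 0)

    def test_bad_initial_rejected(self):
        model = random_rate_model(5, 0)
        with pytest.raises(ValueError):
            ode_oracle(model, np.full(5, 0.3), 1.0)


class TestRcmc:
    def test_frozen_limit_keeps_initial_populations(self):
        # all barriers enormous: every rate far below 1/t
        k = eyring_rate(200.0, 300.0)
        K = np.array([[0.0, k], [k, 0.0]])
        model = RateModel(300.0, K, np.zeros(2))
        state = rcmc_contract(model, 1.0, [0.7, 0.3])
        assert np.allclose(state.populations, [0.7, 0.3], atol=1e-12)
        assert len(set(state.contracted_map.values())) == 2  # nothing contracted

    def test_full_equilibration_limit_is_boltzmann(self):
        T = 300.0
        energies = np.array([0.0, 4.0, 9.0])
        K = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:  # tiny barriers -> huge rates, detailed balance
                    K[i, j] = eyring_rate(max(energies[j], energies[i]) + 1.0 - energies[i], T)
        model = RateModel(T, K, energies)
        state = rcmc_contract(model, 1.0, [1.0, 0.0, 0.0])
        w = np.exp(-energies / (GAS_CONSTANT_KJ * T))
        assert np.allclose(state.populations, w / w.sum(), atol=1e-9)

    def test_detailed_balance_two_state_exact(self):
        T, dE = 300.0, 10.0
        k_f, k_b = eyring_rate(20.0, T), eyring_rate(20.0 + dE, T)
        model = RateModel(T, np.array([[0.0, k_f], [k_b, 0.0]]), np.array([0.0, -dE]))
        state = rcmc_contract(model, 1.0, [1.0, 0.0])
        ratio = state.populations[1] / state.populations[0]
        assert ratio == pytest.approx(np.exp(dE / (GAS_CONSTANT_KJ * T)), rel=1e-6)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_ode_oracle_on_random_networks(self, seed):
        model = random_rate_model(12, seed)
        p0 = np.zeros(12)
        p0[seed % 12] = 1.0
        a = rcmc_contract(model, 1.0, p0)
        b = ode_oracle(model, p0, 1.0)
        assert np.abs(a.populations - b.populations).max() < 1e-2
        assert a.populations.sum() == pytest.approx(1.0, abs=1e-9)


class TestYields:
    def test_complete_and_empty_product_sets(self):
        model = random_rate_model(6, 1)
        p0 = np.full(6, 1 / 6)
        state = rcmc_contract(model, 1.0, p0)
        assert yield_report(state, range(6)) == pytest.approx(100.0, abs=1e-9)
        assert yield_report(state, []) == 0.0
        with pytest.raises(ValueError):
            yield_report(state, [17])

    def test_two_state_closed_form_percentage(self):
        T, dE = 300.0, 10.0
        k_f, k_b = eyring_rate(20.0, T), eyring_rate(20.0 + dE, T)
        model = RateModel(T, np.array([[0.0, k_f], [k_b, 0.0]]), np.array([0.0, -dE]))
        state = rcmc_contract(model, 1.0, [1.0, 0.0])
        q = np.exp(dE / (GAS_CONSTANT_KJ * T))
        assert yield_report(state, [1]) == pytest.approx(100.0 * q / (1 + q), rel=1e-9)

    def test_arrhenius_trend_through_activated_channel(self):
        # two-channel toy: the product sits behind a 72 kJ/mol barrier;
        # at 1 s the conversion must rise monotonically with temperature
        net = _toy_network([0.0, -20.0], [(0, 1, 72.0)])
        yields = []
        for T in (250.0, 300.0, 350.0):
            model = build_rate_model(net, T)
            state = rcmc_contract(model, 1.0, [1.0, 0.0])
            yields.append(yield_report(state, [1]))
        assert yields[0] < yields[1] < yields[2]


class TestKineticNavigation:
    def test_single_eq_network(self):
        net = _toy_network([0.0], [])
        assert kinetic_navigation_select(net, 300.0, 1.0, set()) == 0

    def test_unreachable_state_not_selected(self):
        # B reachable over a small barrier, C blocked by a 200 kJ/mol wall
        net = _toy_network([0.0, -5.0, -50.0], [(0, 1, 30.0), (0, 2, 200.0)])
        pick = kinetic_navigation_select(net, 300.0, 1.0, expanded={0})
        assert pick == 1

    def test_matches_ode_ranking_on_partial_network(self, mb_fixture):
        net = mb_fixture.network.truncate(4)
        expanded = {0}
        pick = kinetic_navigation_select(net, 300.0, 1.0, expanded)
        model = build_rate_model(net, 300.0)
        p0 = np.zeros(net.n_eqs)
        p0[0] = 1.0
        pops = ode_oracle(model, p0, 1.0).populations
        unexpanded = [r.eq_id for r in net.eqs if r.eq_id not in expanded]
        assert pick == max(unexpanded, key=lambda i: pops[i])

    def test_kinetic_navigation_explores(self, mb_potential):
        from forcepath.afir import ExplorationSchedule, explore_network

        schedule = ExplorationSchedule(
            gammas=(500.0,), mode="directions", n_directions=4,
            n_frames=15, lup_sweeps=20, max_expansions=2, eq_energy_ceiling=-20.0,
        )
        net = explore_network(
            surface_point(-0.55, 1.44), mb_potential, schedule, navigation="kinetic"
        )
        assert net.n_eqs >= 2
        assert net.metadata["navigation"] == "kinetic"
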