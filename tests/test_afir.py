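"""Artificial-force tracing, LUP refinement, EQ identity, and exploration."""

import json

import numpy as np
import pytest

from forcepath.afir import (
    AfirBias,
    AfirForceSpec,
    ExplorationSchedule,
    FragmentPair,
    LinearBias,
    ReactionNetwork,
    afir_bias,
    explore_network,
    identify_eq,
    load_network,
    lup_refine,
    minimize_geometry,
    save_network,
    trace_afir_path,
)
from forcepath.fixtures import morse_trimer_truth, wall_channel_truth
from forcepath.geometry import Geometry, surface_point
from forcepath.oracles import surface_basin
from forcepath.potentials import (
    PairClusterPotential,
    Potential,
    PotentialResult,
    finite_difference_gradient,
)


def _morse_dimer(D=60.0, a=1.6, r0=2.0):
    return PairClusterPotential({(1, 1): {"kind": "morse", "D": D, "a": a, "r0": r0}})


def _dimer_geometry(r):
    return Geometry((1, 1), np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


class TestAfirBias:
    def test_zero_gamma_is_null_force(self, rng):
        g = Geometry((1, 2, 1), rng.normal(scale=1.5, size=(3, 3)) + np.eye(3))
        res = afir_bias(g, FragmentPair((0,), (2,)), AfirForceSpec(0.0, "pull"))
        assert res.energy == 0.0
        assert np.all(res.gradient == 0.0)

    def test_single_atom_fragments_reduce_to_pair_distance(self):
        r = 2.7
        g = _dimer_geometry(r)
        spec = AfirForceSpec(gamma=30.0, direction="pull")
        res = afir_bias(g, FragmentPair((0,), (1,)), spec)
        c = 2 * 0.31  # H covalent contact distance
        alpha = 30.0 / c
        assert res.energy == pytest.approx(alpha * r, rel=1e-12)
        # gradient strictly along the bond axis
        assert abs(res.gradient[0, 1]) < 1e-14 and abs(res.gradient[0, 2]) < 1e-14
        assert res.gradient[0, 0] == pytest.approx(-alpha, rel=1e-10)

    @pytest.mark.parametrize("direction", ["pull", "push"])
    def test_gradient_matches_finite_differences(self, direction, rng):
        frag = FragmentPair((0, 1, 2), (3, 4, 5))
        bias = AfirBias(frag, AfirForceSpec(45.0, direction))
        for _ in range(5):
            g = Geometry((1, 6, 1, 8, 6, 1), rng.normal(scale=1.8, size=(6, 3)) * 1.2)
            res = bias.evaluate(g)
            fd = finite_difference_gradient(bias, g)
            denom = max(np.linalg.norm(fd), 1e-6)
            assert np.linalg.norm(fd - res.gradient) / denom < 1e-6

    def test_overlapping_fragments_rejected(self):
        with pytest.raises(ValueError):
            FragmentPair((0, 1), (1, 2))
        with pytest.raises(ValueError):
            FragmentPair((), (1,))


class TestTrace:
    def test_zero_force_stays_at_minimum(self):
        pot = _morse_dimer()
        start, ok = minimize_geometry(pot, _dimer_geometry(2.1))
        assert ok
        res = trace_afir_path(start, pot, LinearBias((1.0, 0.0), 0.0))
        assert res.converged
        drift = max(np.linalg.norm(f.flat() - start.flat()) for f in res.frames)
        assert drift < 1e-6

    def test_pull_compresses_and_push_dissociates_dimer(self):
        pot = _morse_dimer(D=60.0, r0=2.0)
        start, _ = minimize_geometry(pot, _dimer_geometry(2.0))
        pull = trace_afir_path(
            start, pot, AfirBias(FragmentPair((0,), (1,)), AfirForceSpec(200.0, "pull"))
        )
        sep_end = np.linalg.norm(
            pull.frames[-1].coordinates[0] - pull.frames[-1].coordinates[1]
        )
        assert sep_end < 2.0  # squeezed inside the bonded distance

        push = trace_afir_path(
            start, pot, AfirBias(FragmentPair((0,), (1,)), AfirForceSpec(200.0, "push"))
        )
        seps = [
            np.linalg.norm(f.coordinates[0] - f.coordinates[1]) for f in push.frames
        ]
        assert seps[-1] > 6.0  # dissociated
        assert np.all(np.diff(seps) > -1e-9)  # monotone separation

    def test_muller_brown_bias_changes_basin(self, mb_potential, mb_oracle):
        minima = mb_oracle["stationary"]["minima"]
        start = surface_point(*minima[0][0])  # deepest basin
        res = trace_afir_path(start, mb_potential, LinearBias((0.3, -1.0), 400.0))
        endpoint, ok = minimize_geometry(mb_potential, res.frames[-1])
        assert ok
        basin_start = surface_basin(mb_potential, start.coordinates[0, :2], minima)
        basin_end = surface_basin(mb_potential, endpoint.coordinates[0, :2], minima)
        assert basin_start != basin_end


class _Paraboloid(Potential):
    """Quadratic valley with floor along the x axis."""

    def evaluate(self, geometry):
        x, y = geometry.coordinates[0, :2]
        grad = np.zeros_like(geometry.coordinates)
        grad[0, 0] = 0.2 * x
        grad[0, 1] = 8.0 * y
        return PotentialResult(0.1 * x**2 + 4.0 * y**2, grad)


class TestLupRefine:
    def test_straight_valley_floor_is_fixed_point(self):
        pot = _Paraboloid()
        frames = [surface_point(x, 0.0) for x in np.linspace(-1.0, 1.0, 11)]
        path = lup_refine(frames, pot, n_sweeps=20, reminimize_endpoints=False)
        coords = np.stack([f.coordinates[0, :2] for f in path.frames])
        assert np.abs(coords[:, 1]).max() < 1e-10
        assert np.allclose(coords[:, 0], np.linspace(-1.0, 1.0, 11), atol=1e-8)

    def test_muller_brown_saddle_recovered_within_one_percent(
        self, mb_potential, mb_oracle
    ):
        minima = mb_oracle["stationary"]["minima"]
        A, C = minima[0][0], minima[2][0]  # deep basin and the shallow one
        frames = [
            surface_point(*(A + t * (C - A))) for t in np.linspace(0.0, 1.0, 31)
        ]
        path = lup_refine(frames, mb_potential, n_sweeps=80)
        saddle_e = mb_oracle["stationary"]["saddles"][1][1]  # the high saddle
        barrier_true = saddle_e - minima[0][1]
        barrier_lup = path.ts_energy - path.energies[0]
        assert abs(barrier_lup - barrier_true) / barrier_true < 0.01

    def test_descent_stage_never_raises_a_frame(self, mb_potential, mb_oracle):
        minima = mb_oracle["stationary"]["minima"]
        A, B = minima[0][0], minima[1][0]
        frames = [
            surface_point(*(A + t * (B - A))) for t in np.linspace(0.0, 1.0, 21)
        ]
        log = []
        lup_refine(frames, mb_potential, n_sweeps=15, sweep_log=log)
        assert len(log) >= 1
        for pre, post in log:
            assert np.all(post <= pre + 1e-9)

    def test_too_few_frames_rejected(self, mb_potential):
        with pytest.raises(ValueError):
            lup_refine([surface_point(0, 0)] * 2, mb_potential)


class TestIdentifyEq:
    def test_resubmission_is_idempotent(self, mb_potential, mb_oracle):
        net = ReactionNetwork()
        minima = mb_oracle["stationary"]["minima"]
        g0 = surface_point(*minima[0][0])
        first = identify_eq(g0, net, mb_potential)
        again = identify_eq(g0, net, mb_potential)
        assert first == again
        assert net.n_eqs == 1

    def test_distinct_minima_get_distinct_ids(self, mb_potential, mb_oracle):
        net = ReactionNetwork()
        ids = [
            identify_eq(surface_point(*p), net, mb_potential)
            for p, _ in mb_oracle["stationary"]["minima"]
        ]
        assert sorted(ids) == [0, 1, 2]

    def test_rotated_copy_of_cluster_minimum_matches(self, rng):
        pot = morse_trimer_truth()
        g, ok = minimize_geometry(
            pot,
            Geometry(
                (1, 2, 1),
                np.array([[-0.95, 1.55, 0.0], [0.0, 0.0, 0.0], [0.95, 1.55, 0.0]]),
            ),
        )
        assert ok
        net = ReactionNetwork()
        first = identify_eq(g, net, pot)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = g.with_coordinates(g.coordinates @ q.T + np.array([1.0, 2.0, 3.0]))
        assert identify_eq(rotated, net, pot) == first
        assert net.n_eqs == 1

    def test_unminimized_candidate_rejected(self, mb_potential):
        net = ReactionNetwork()
        with pytest.raises(ValueError):
            identify_eq(surface_point(0.3, 1.0), net, mb_potential)


class TestExploreNetwork:
    def test_zero_budget_yields_seed_only(self, mb_potential):
        schedule = ExplorationSchedule(gammas=(200.0,), mode="directions", max_expansions=0)
        net = explore_network(surface_point(-0.55, 1.44), mb_potential, schedule)
        assert net.n_eqs == 1
        assert net.paths == []

    def test_muller_brown_finds_all_three_basins(self, mb_fixture):
        assert mb_fixture.network.n_eqs == 3
        edges = {
            tuple(sorted(p.endpoints))
            for p in mb_fixture.network.paths
            if p.flag == "ok" and p.endpoints[0] != p.endpoints[1]
        }
        assert len(edges) >= 2

    def test_trimer_isomers_and_isomerization_edge(self, trimer_fixture):
        net = trimer_fixture.network
        r_hh = [
            float(np.linalg.norm(rec.geometry.coordinates[0] - rec.geometry.coordinates[2]))
            for rec in net.eqs
        ]
        assert any(r < 2.6 for r in r_hh)  # compact (bent) isomer
        assert any(r > 2.6 for r in r_hh)  # extended isomer
        inter = [
            p for p in net.paths if p.flag == "ok" and p.endpoints[0] != p.endpoints[1]
        ]
        assert inter, "no isomerization edge found"

    def test_ts_energy_dominates_endpoints(self, mb_fixture, wall_fixture):
        for net in (mb_fixture.network, wall_fixture.network):
            for p in net.paths:
                assert p.ts_energy >= p.energies[0] - 1e-9
                assert p.ts_energy >= p.energies[-1] - 1e-9

    def test_discovery_indices_are_a_permutation(self, mb_fixture):
        net = mb_fixture.network
        assert sorted(r.discovery_index for r in net.eqs) == list(range(net.n_eqs))
        assert sorted(p.discovery_index for p in net.paths) == list(range(len(net.paths)))

    def test_truncation_yields_valid_subnetwork(self, mb_fixture):
        sub = mb_fixture.network.truncate(3)
        assert len(sub.paths) == 3
        for p in sub.paths:
            assert 0 <= p.endpoints[0] < sub.n_eqs
            assert 0 <= p.endpoints[1] < sub.n_eqs
        indices = [p.discovery_index for p in sub.paths]
        assert indices == sorted(indices)

    def test_exploration_is_deterministic(self, mb_potential, tmp_path):
        schedule = ExplorationSchedule(
            gammas=(500.0,), mode="directions", n_directions=4,
            n_frames=15, lup_sweeps=20, max_expansions=1, eq_energy_ceiling=-20.0,
        )
        nets = []
        for run in range(2):
            net = explore_network(
                surface_point(-0.55, 1.44), mb_potential, schedule, seed_rng=7
            )
            out = tmp_path / f"run{run}"
            save_network(net, str(out))
            nets.append((out / "network.json").read_bytes())
        assert nets[0] == nets[1]


def test_network_json_round_trip(wall_fixture, tmp_path):
    net = wall_fixture.network
    save_network(net, str(tmp_path))
    doc = json.loads((tmp_path / "network.json").read_text())
    assert {e["id"] for e in doc["eqs"]} == set(range(net.n_eqs))
    loaded = load_network(str(tmp_path))
    assert loaded.n_eqs == net.n_eqs
    assert len(loaded.paths) == len(net.paths)
    for a, b in zip(
        sorted(net.paths, key=lambda p: p.discovery_index),
        sorted(loaded.paths, key=lambda p: p.discovery_index),
    ):
        assert a.endpoints == b.endpoints
        assert b.ts_energy == pytest.approx(a.ts_energy, abs=1e-12)
        assert np.allclose(a.energies, b.energies, atol=1e-12)
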