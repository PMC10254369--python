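"""Future splits, kernel-ridge surrogates, metrics, robustness scanning."""

import numpy as np
import pytest

from forcepath.fixtures import morse_trimer_base, wall_channel_base
from forcepath.geometry import Geometry, surface_point
from forcepath.potentials import (
    CompositePotential,
    CompositionError,
    PairClusterPotential,
    Potential,
    PotentialResult,
)
from forcepath.surrogate import (
    PathDataset,
    PathRecord,
    SplitSpec,
    SurrogateSpec,
    evaluate_metrics,
    fit_surrogate,
    future_split,
    leaky_hole_scan,
    load_model,
    read_dataset_xyz,
    save_model,
)


def _surface_dataset(n_paths=50, frames_per_path=4, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for pid in range(n_paths):
        for _ in range(frames_per_path):
            xy = rng.uniform(-1.5, 1.5, 2)
            records.append(
                PathRecord(surface_point(*xy), float(xy @ xy), None, pid, pid)
            )
    return PathDataset(records)


class TestFutureSplit:
    def test_half_fraction_counts(self):
        ds = _surface_dataset(10)
        train, val, test = future_split(ds, SplitSpec(0.5, val_ratio=0.2, rng_seed=1))
        assert len(set(train.path_ids) | set(val.path_ids)) == 5
        assert len(test.path_ids) == 5

    def test_zero_val_ratio_gives_empty_validation(self):
        ds = _surface_dataset(10)
        _, val, _ = future_split(ds, SplitSpec(0.5, val_ratio=0.0))
        assert val.n_records == 0

    def test_no_path_straddles_and_test_is_strictly_later(self):
        ds = _surface_dataset(50)
        train, val, test = future_split(ds, SplitSpec(0.4, val_ratio=0.25, rng_seed=3))
        tr, va, te = set(train.path_ids), set(val.path_ids), set(test.path_ids)
        assert tr & va == set()
        assert (tr | va) & te == set()
        assert tr | va | te == set(range(50))
        last_early = max(r.discovery_index for r in train.records + val.records)
        first_late = min(r.discovery_index for r in test.records)
        assert last_early < first_late

    def test_degenerate_specs_rejected(self):
        ds = _surface_dataset(5)
        with pytest.raises(ValueError):
            SplitSpec(0.0)
        with pytest.raises(ValueError):
            SplitSpec(0.5, val_ratio=1.0)
        with pytest.raises(ValueError):
            future_split(PathDataset([]), SplitSpec(0.5))

    def test_mixed_stoichiometry_rejected(self):
        a = PathRecord(surface_point(0, 0), 0.0, None, 0, 0)
        b = PathRecord(
            Geometry((1, 1), np.array([[0.0, 0, 0], [1.0, 0, 0]])), 0.0, None, 1, 1
        )
        with pytest.raises(ValueError):
            PathDataset([a, b])


def _morse_dimer_dataset(n, r_lo, r_hi, seed=0, pid_splits=5):
    pot = PairClusterPotential({(1, 1): {"kind": "morse", "D": 60.0, "a": 1.6, "r0": 2.0}})
    rng = np.random.default_rng(seed)
    rs = np.sort(rng.uniform(r_lo, r_hi, n))
    records = []
    for i, r in enumerate(rs):
        g = Geometry((1, 1), np.array([[0.0, 0.0, 0.0], [float(r), 0.0, 0.0]]))
        records.append(PathRecord(g, pot.energy(g), None, i % pid_splits, i % pid_splits))
    return pot, PathDataset(records)


class TestFitSurrogate:
    def test_null_residual_in_delta_mode(self, wall_fixture):
        train, val, _ = future_split(
            wall_fixture.dataset, SplitSpec(0.8, val_ratio=0.2, rng_seed=0)
        )
        spec = SurrogateSpec(mode="delta", base=wall_fixture.truth)  # base == truth
        model = fit_surrogate(train, val, spec)
        mae = evaluate_metrics(model, val)["mae"]
        assert mae < 1e-6

    def test_morse_dimer_interpolation(self):
        pot, train_ds = _morse_dimer_dataset(50, 1.6, 3.2, seed=1)
        _, test_ds = _morse_dimer_dataset(200, 1.7, 3.1, seed=2)
        model = fit_surrogate(
            train_ds, PathDataset([]), SurrogateSpec(mode="pure", regularization=1e-10)
        )
        mae = evaluate_metrics(model, test_ds)["mae"]
        assert mae < 0.1

    def test_delta_prediction_is_exact_composition(self, wall_fixture, rng):
        train, val, _ = future_split(wall_fixture.dataset, SplitSpec(0.5, rng_seed=0))
        base = wall_channel_base()
        model = fit_surrogate(train, val, SurrogateSpec(mode="delta", base=base))
        assert isinstance(model, CompositePotential)
        for _ in range(10):
            g = surface_point(*rng.uniform(-2, 2, 2))
            total = model.evaluate(g)
            expected = (base.evaluate(g).energy + model.energy_shift) + model.correction.evaluate(g).energy
            assert total.energy == expected

    def test_surrogate_gradient_matches_finite_differences(self, wall_fixture, rng):
        from forcepath.potentials import finite_difference_gradient

        train, val, _ = future_split(wall_fixture.dataset, SplitSpec(0.5, rng_seed=0))
        model = fit_surrogate(train, val, SurrogateSpec(mode="pure"))
        for _ in range(10):
            g = surface_point(*rng.uniform(-2.0, 2.0, 2))
            res = model.evaluate(g)
            # wide-step five-point stencil: the kernel sum's cancelling
            # terms put narrow steps in the roundoff regime
            fd = finite_difference_gradient(model, g, step=1e-3, order=4)
            denom = max(np.linalg.norm(fd), 1.0)
            assert np.linalg.norm(fd - res.gradient) / denom < 1e-6

    def test_composition_mismatch_raises(self, wall_fixture):
        train, val, _ = future_split(wall_fixture.dataset, SplitSpec(0.5, rng_seed=0))
        model = fit_surrogate(train, val, SurrogateSpec(mode="pure"))
        g = Geometry((1, 1), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(CompositionError):
            model.evaluate(g)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SurrogateSpec(mode="delta", base=None)
        with pytest.raises(ValueError):
            SurrogateSpec(mode="pure", regularization=0.0)


class _ConstantPredictor(Potential):
    def __init__(self, value):
        self.value = value

    def evaluate(self, geometry):
        return PotentialResult(self.value, np.zeros_like(geometry.coordinates))


class TestMetrics:
    def test_perfect_predictor(self, wall_fixture):
        ds = wall_fixture.dataset
        m = evaluate_metrics(wall_fixture.truth, ds)
        assert m["mae"] == pytest.approx(0.0, abs=1e-10)
        assert m["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_mean_predictor_has_zero_r2(self, wall_fixture):
        ds = wall_fixture.dataset
        m = evaluate_metrics(_ConstantPredictor(float(ds.energies().mean())), ds)
        assert m["r2"] == pytest.approx(0.0, abs=1e-9)

    def test_worse_than_mean_is_negative(self, wall_fixture):
        ds = wall_fixture.dataset
        bad = float(ds.energies().mean()) + 10 * float(ds.energies().std())
        m = evaluate_metrics(_ConstantPredictor(bad), ds)
        assert m["r2"] < 0

    def test_gradient_mae_reported(self, wall_fixture):
        m = evaluate_metrics(wall_fixture.truth, wall_fixture.dataset, gradients=True)
        assert m["gradient_mae"] == pytest.approx(0.0, abs=1e-10)


class TestLeakyHoleScan:
    def test_truth_powered_search_is_self_consistent(self, wall_fixture):
        flags = leaky_hole_scan(wall_fixture.network, wall_fixture.truth, 100.0)
        assert flags == []

    def test_pure_surrogate_leaks_and_delta_does_not(self, replay_report):
        holes = replay_report["leaky_holes"]
        assert holes["pure-20"] >= 1
        for frac in (20, 50, 80):
            assert holes[f"delta-{frac}"] == 0
            assert holes[f"delta-{frac}"] <= holes[f"pure-{frac}"]


class TestReplayInvariants:
    def test_future_mae_improves_with_training_fraction(self, replay_report):
        metrics = replay_report["metrics"]
        for mode in ("pure", "delta"):
            assert metrics[f"{mode}-80"]["mae"] <= metrics[f"{mode}-20"]["mae"]

    def test_delta_recovers_truth_yields_at_half_training(self, replay_report):
        yields = replay_report["yields"]
        t_star = max(yields["truth"], key=lambda T: yields["truth"][T])
        for frac in (50, 80):
            assert abs(yields[f"delta-{frac}"][t_star] - yields["truth"][t_star]) <= 5.0

    def test_biased_base_deviates_more_than_delta(self, replay_report):
        yields = replay_report["yields"]
        t_star = max(yields["truth"], key=lambda T: yields["truth"][T])
        base_dev = abs(yields["base"][t_star] - yields["truth"][t_star])
        delta_dev = abs(yields["delta-50"][t_star] - yields["truth"][t_star])
        assert base_dev > delta_dev

    def test_base_yield_rises_with_temperature(self, replay_report):
        ys = replay_report["yields"]["base"]
        temps = sorted(ys)
        vals = [ys[T] for T in temps]
        assert vals[0] < vals[1] < vals[2]


class TestSerialization:
    def test_round_trip_and_determinism(self, wall_fixture, tmp_path, rng):
        train, val, _ = future_split(wall_fixture.dataset, SplitSpec(0.5, rng_seed=0))
        base = wall_channel_base()
        blobs = []
        for run in range(2):
            model = fit_surrogate(train, val, SurrogateSpec(mode="delta", base=base))
            path = tmp_path / f"model{run}.json"
            save_model(model, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]
        loaded = load_model(tmp_path / "model0.json", base=base)
        model = fit_surrogate(train, val, SurrogateSpec(mode="delta", base=base))
        for _ in range(5):
            g = surface_point(*rng.uniform(-2, 2, 2))
            assert loaded.energy(g) == pytest.approx(model.energy(g), abs=1e-12)

    def test_dataset_xyz_reader(self, trimer_fixture, tmp_path):
        trimer_fixture.save(str(tmp_path))
        ds = read_dataset_xyz(tmp_path / "dataset.xyz")
        assert ds.n_records == trimer_fixture.dataset.n_records
        orig = trimer_fixture.dataset.records[0]
        back = ds.records[0]
        assert back.energy == orig.energy
        assert np.array_equal(back.geometry.coordinates, orig.geometry.coordinates)
        assert back.path_id == orig.path_id
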