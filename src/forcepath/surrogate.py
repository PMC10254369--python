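"""Descriptor-based surrogate potentials with a robust Δ-learning safeguard.

The learned term is kernel ridge regression (RBF kernel) on the package's
distance-based descriptors.  Two modes:

* ``pure`` — the model regresses the target energy directly.  Outside its
  training domain an RBF model relaxes to a constant, so nothing stops a
  force-driven search from walking into regions whose true energy is
  enormous: the "leaky hole" failure.
* ``delta`` — the model regresses the residual E_truth − E_base over a
  robust-but-biased base potential and predicts base + correction.  The base
  keeps the repulsive walls and dissociation limits, acting as a continuously
  differentiable safeguard: far from the data the correction vanishes and the
  base physics takes over.

Generalization is assessed future-wise: paths are ordered by their discovery
index during the ground-truth search, the earliest fraction forms
train/validation (split path-wise, so no path straddles the two), and all
later paths form the test set — the model is always scored on chemistry it
has never seen, as it would be when powering a live search.

Energy gradients of the surrogate are analytic via the chain rule through the
descriptor Jacobian (sorting permutation frozen at the evaluation point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .descriptors import default_descriptor
from .geometry import Geometry
from .potentials import CompositePotential, CompositionError, Potential, PotentialResult


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class PathRecord:
    geometry: Geometry
    energy: float  # kJ/mol
    gradient: np.ndarray | None
    path_id: int
    discovery_index: int


@dataclass
class PathDataset:
    records: list

    def __post_init__(self):
        comps = {tuple(sorted(r.geometry.atomic_numbers)) for r in self.records}
        if len(comps) > 1:
            raise ValueError("dataset mixes stoichiometries")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def path_ids(self) -> list[int]:
        return sorted({r.path_id for r in self.records})

    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    def geometries(self) -> list[Geometry]:
        return [r.geometry for r in self.records]


def dataset_from_network(network, gradient_potential: Potential | None = None) -> PathDataset:
    """All refined path frames of a network as a path-labelled dataset."""
    records = []
    for path in sorted(network.paths, key=lambda p: p.discovery_index):
        for k, frame in enumerate(path.frames):
            grad = None
            if gradient_potential is not None:
                grad = gradient_potential.evaluate(frame).gradient
            records.append(
                PathRecord(frame, float(path.energies[k]), grad, path.discovery_index, path.discovery_index)
            )
    return PathDataset(records)


def read_dataset_xyz(path) -> PathDataset:
    """Read path-labelled records from extended-XYZ (``path_id`` and
    ``discovery_index`` comment keys; energy/forces as usual; stored dipoles,
    if any, are ignored)."""
    from .geometry import read_xyz_frames

    records = []
    for geom, fields in read_xyz_frames(path):
        pid = int(fields.get("path_id", 0))
        records.append(
            PathRecord(
                geom,
                float(geom.ref_energy if geom.ref_energy is not None else np.nan),
                geom.ref_gradient,
                pid,
                int(fields.get("discovery_index", pid)),
            )
        )
    return PathDataset(records)


@dataclass
class SplitSpec:
    fraction: float  # first portion of paths by discovery order
    val_ratio: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if not 0.0 <= self.val_ratio < 1.0:
            raise ValueError("val_ratio must be in [0, 1)")


def future_split(dataset: PathDataset, spec: SplitSpec):
    """Future-oriented path-wise split -> (train, validation, test).

    Paths are sorted by discovery index; the earliest ⌈fraction·n⌉ paths form
    train∪validation (validation drawn path-wise at random with ``rng_seed``),
    all later paths form the test set.  No path's geometries ever straddle
    train and validation.
    """
    if dataset.n_records == 0:
        raise ValueError("empty dataset")
    path_order = sorted({r.path_id for r in dataset.records})
    n_paths = len(path_order)
    n_early = int(np.ceil(spec.fraction * n_paths))
    if n_early == 0:
        raise ValueError("fraction selects no training paths")
    early = path_order[:n_early]
    later = set(path_order[n_early:])
    rng = np.random.default_rng(spec.rng_seed)
    n_val = int(round(spec.val_ratio * n_early))
    if spec.val_ratio > 0 and n_early >= 2:
        n_val = max(1, n_val)  # keep model selection alive on small path sets
    if n_val >= n_early:
        n_val = n_early - 1
    val_paths = set()
    if n_val > 0:
        idx = rng.choice(n_early, size=n_val, replace=False)
        val_paths = {early[int(i)] for i in idx}
    train_paths = set(early) - val_paths
    by = lambda keep: PathDataset([r for r in dataset.records if r.path_id in keep])
    return by(train_paths), by(val_paths), by(later)


# ---------------------------------------------------------------------------
# Kernel ridge correction


class KernelRidgeCorrection(Potential):
    """RBF kernel ridge regressor exposed through the potential contract."""

    def __init__(self, descriptor, train_descriptors: np.ndarray, coeffs: np.ndarray,
                 lengthscale: float, y_mean: float, n_atoms: int):
        self.descriptor = descriptor
        self.train_descriptors = np.asarray(train_descriptors, dtype=float)
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.lengthscale = float(lengthscale)
        self.y_mean = float(y_mean)
        self.n_atoms = int(n_atoms)

    def _kernel_row(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        diff = d[None, :] - self.train_descriptors  # (n, P)
        k = np.exp(-0.5 * (diff**2).sum(axis=1) / self.lengthscale**2)
        return k, diff

    def predict_from_descriptor(self, d: np.ndarray) -> float:
        k, _ = self._kernel_row(d)
        return self.y_mean + float(k @ self.coeffs)

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        if geometry.n_atoms != self.n_atoms:
            raise CompositionError("geometry composition differs from the training set")
        d, jac = self.descriptor.vector_and_jacobian(geometry)
        if d.shape[0] != self.train_descriptors.shape[1]:
            raise CompositionError("descriptor length differs from the training set")
        k, diff = self._kernel_row(d)
        energy = self.y_mean + float(k @ self.coeffs)
        # dE/dd = Σ_i c_i k_i (−(d − d_i)/ℓ²); then through the descriptor Jacobian
        dE_dd = -(self.coeffs * k) @ diff / self.lengthscale**2
        grad = (dE_dd @ jac).reshape(geometry.n_atoms, 3)
        return PotentialResult(energy, grad)


@dataclass
class SurrogateSpec:
    mode: str = "delta"  # "pure" | "delta"
    base: Potential | None = None
    lengthscale: float | None = None  # None -> median-distance heuristic
    regularization: float = 1e-7
    lengthscale_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    regularization_grid: tuple[float, ...] = (1e-7, 1e-6, 1e-5)
    max_train_points: int = 800
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("pure", "delta"):
            raise ValueError("mode must be 'pure' or 'delta'")
        if self.mode == "delta" and self.base is None:
            raise ValueError("delta mode requires a base potential")
        if self.regularization <= 0:
            raise ValueError("hyperparameters must be positive")


def _solve_krr(D: np.ndarray, y: np.ndarray, lengthscale: float, reg: float) -> np.ndarray:
    diff2 = ((D[:, None, :] - D[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * diff2 / lengthscale**2)
    n = D.shape[0]
    return np.linalg.solve(K + reg * n * np.eye(n), y)


def fit_surrogate(train: PathDataset, validation: PathDataset, spec: SurrogateSpec) -> Potential:
    """Fit the learned term; returns a ready-to-evaluate potential.

    Pure mode regresses total energies; delta mode regresses residuals over
    ``spec.base`` and returns the Δ-composite base + correction.
    Hyperparameters are selected on the validation energy MAE when a
    validation set is provided; deterministic given ``spec.rng_seed``.
    """
    if train.n_records == 0:
        raise ValueError("empty training set")
    records = train.records
    if len(records) > spec.max_train_points:
        idx = np.linspace(0, len(records) - 1, spec.max_train_points).astype(int)
        records = [records[i] for i in sorted(set(idx.tolist()))]
    geoms = [r.geometry for r in records]
    descriptor = default_descriptor(geoms[0])
    D = np.stack([descriptor.vector(g) for g in geoms])
    y = np.array([r.energy for r in records])
    if spec.mode == "delta":
        y = y - spec.base.energies(geoms)
    y_mean = float(y.mean())
    yc = y - y_mean

    # median-heuristic reference length scale
    rng = np.random.default_rng(spec.rng_seed)
    m = min(len(records), 200)
    sub = D[rng.choice(len(records), size=m, replace=False)]
    pd = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
    ref = float(np.median(pd[pd > 0])) if np.any(pd > 0) else 1.0
    if spec.lengthscale is not None:
        candidates = [(spec.lengthscale, spec.regularization)]
    elif validation.n_records > 0:
        candidates = [
            (ref * ls, rg)
            for ls in spec.lengthscale_grid
            for rg in spec.regularization_grid
        ]
    else:
        candidates = [(ref, spec.regularization)]

    def build(ls, rg):
        coeffs = _solve_krr(D, yc, ls, rg)
        return KernelRidgeCorrection(descriptor, D, coeffs, ls, y_mean, geoms[0].n_atoms)

    if len(candidates) == 1:
        correction = build(*candidates[0])
    else:
        vgeoms = validation.geometries()
        vy = validation.energies()
        if spec.mode == "delta":
            vy = vy - spec.base.energies(vgeoms)
        best, best_mae = None, np.inf
        for ls, rg in candidates:
            model = build(ls, rg)
            pred = np.array([model.predict_from_descriptor(descriptor.vector(g)) for g in vgeoms])
            mae = float(np.mean(np.abs(pred - vy)))
            if mae < best_mae - 1e-12:
                best, best_mae = model, mae
        correction = best
    if spec.mode == "delta":
        return CompositePotential(spec.base, correction, 0.0)
    return correction


def evaluate_metrics(model: Potential, test: PathDataset, gradients: bool = False) -> dict:
    """Energy MAE/RMSE/R² (R² may be negative) and optional gradient MAE."""
    if test.n_records == 0:
        raise ValueError("empty test set")
    y = test.energies()
    pred = model.energies(test.geometries())
    resid = pred - y
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    out = {
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "n": test.n_records,
    }
    if gradients:
        errs = []
        for r in test.records:
            if r.gradient is not None:
                g = model.evaluate(r.geometry).gradient
                errs.append(float(np.mean(np.abs(g - r.gradient))))
        out["gradient_mae"] = float(np.mean(errs)) if errs else float("nan")
    return out


# ---------------------------------------------------------------------------
# Robustness scanning


@dataclass
class LeakyHole:
    geometry: Geometry
    kind: str  # "eq" | "ts"
    predicted_energy: float
    true_energy: float

    @property
    def discrepancy(self) -> float:
        return self.true_energy - self.predicted_energy


def leaky_hole_scan(search_result, truth: Potential, threshold: float = 100.0) -> list:
    """Flag stationary points whose true energy exceeds the search potential's
    prediction by more than ``threshold`` kJ/mol.

    Scans every EQ and every approximate TS of a surrogate-powered network,
    re-evaluating with the ground truth; returns flags sorted by decreasing
    discrepancy.
    """
    flags = []
    for rec in search_result.eqs:
        e_true = truth.energy(rec.geometry)
        if e_true - rec.energy > threshold:
            flags.append(LeakyHole(rec.geometry, "eq", rec.energy, e_true))
    for path in search_result.paths:
        ts = path.frames[path.ts_index]
        e_true = truth.energy(ts)
        if e_true - path.ts_energy > threshold:
            flags.append(LeakyHole(ts, "ts", path.ts_energy, e_true))
    flags.sort(key=lambda f: -f.discrepancy)
    return flags


# ---------------------------------------------------------------------------
# Replay experiment


@dataclass
class ReplayConfig:
    system: str = "wall_channel"
    fractions: tuple[float, ...] = (0.2, 0.5, 0.8)
    temperatures: tuple[float, ...] = (250.0, 300.0, 350.0)
    t_target: float = 1.0  # s
    val_ratio: float = 0.15
    leaky_threshold: float = 100.0  # kJ/mol
    rng_seed: int = 0
    modes: tuple[str, ...] = ("pure", "delta")


def replay_experiment(config: ReplayConfig, out_dir: str | None = None) -> dict:
    """End-to-end surrogate-powered search replay on a toy fixture.

    Runs the ground-truth exploration; for each training fraction fits pure
    and Δ-composed surrogates on the earliest paths; re-runs the exploration
    powered by each surrogate and by the biased base alone; reports yields per
    temperature, future-test accuracy metrics, and leaky-hole counts.  Fully
    deterministic given the config seed.
    """
    from .afir import explore_network
    from .fixtures import FixtureSpec, make_fixture
    from .kinetics import build_rate_model, rcmc_contract, yield_report

    fixture = make_fixture(FixtureSpec(system=config.system, rng_seed=config.rng_seed))
    network_truth = fixture.network
    dataset = fixture.dataset

    def yields_for(network) -> dict:
        product_ids = [rec.eq_id for rec in network.eqs if fixture.is_product(rec.geometry)]
        out = {}
        for T in config.temperatures:
            try:
                model = build_rate_model(network, T)
            except ValueError:
                out[T] = 0.0
                continue
            p0 = np.zeros(network.n_eqs)
            seed_ids = [rec.eq_id for rec in network.eqs if fixture.is_reactant(rec.geometry)]
            p0[seed_ids[0] if seed_ids else 0] = 1.0
            state = rcmc_contract(model, config.t_target, p0)
            out[T] = yield_report(state, product_ids)
        return out

    report: dict = {
        "config": {
            "system": config.system,
            "fractions": list(config.fractions),
            "temperatures": list(config.temperatures),
            "t_target": config.t_target,
            "rng_seed": config.rng_seed,
        },
        "yields": {},
        "metrics": {},
        "leaky_holes": {},
    }
    report["yields"]["truth"] = yields_for(network_truth)

    base_net = explore_network(
        fixture.seed_geometry, fixture.base, fixture.schedule, seed_rng=config.rng_seed
    )
    report["yields"]["base"] = yields_for(base_net)
    report["leaky_holes"]["base"] = len(
        leaky_hole_scan(base_net, fixture.truth, config.leaky_threshold)
    )

    for fraction in config.fractions:
        split = SplitSpec(fraction, val_ratio=config.val_ratio, rng_seed=config.rng_seed)
        train, val, test = future_split(dataset, split)
        for mode in config.modes:
            key = f"{mode}-{int(round(100 * fraction))}"
            spec = SurrogateSpec(
                mode=mode,
                base=fixture.base if mode == "delta" else None,
                rng_seed=config.rng_seed,
            )
            model = fit_surrogate(train, val, spec)
            if test.n_records > 0:
                report["metrics"][key] = evaluate_metrics(model, test)
            net = explore_network(
                fixture.seed_geometry, model, fixture.schedule, seed_rng=config.rng_seed
            )
            report["yields"][key] = yields_for(net)
            report["leaky_holes"][key] = len(
                leaky_hole_scan(net, fixture.truth, config.leaky_threshold)
            )

    if out_dir is not None:
        import os

        import pandas as pd

        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for T in config.temperatures:
            row = {"temperature_K": T}
            for name, ys in report["yields"].items():
                row[name] = ys[T]
            rows.append(row)
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "yields.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Model serialization


def save_model(model: Potential, path: str) -> None:
    """Serialize a fitted surrogate (the learned term and, for Δ-composites,
    the shift) to versioned JSON.  Base potentials are reattached on load."""
    if isinstance(model, CompositePotential):
        corr, shift, mode = model.correction, model.energy_shift, "delta"
    else:
        corr, shift, mode = model, 0.0, "pure"
    doc = {
        "format_version": 1,
        "mode": mode,
        "energy_shift": shift,
        "descriptor": type(corr.descriptor).__name__,
        "lengthscale": corr.lengthscale,
        "y_mean": corr.y_mean,
        "n_atoms": corr.n_atoms,
        "train_descriptors": corr.train_descriptors.tolist(),
        "coeffs": corr.coeffs.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def load_model(path: str, base: Potential | None = None) -> Potential:
    from .descriptors import CoordinateDescriptor, SortedDistanceDescriptor

    with open(path) as fh:
        doc = json.load(fh)
    descriptor = (
        CoordinateDescriptor() if doc["descriptor"] == "CoordinateDescriptor" else SortedDistanceDescriptor()
    )
    corr = KernelRidgeCorrection(
        descriptor,
        np.array(doc["train_descriptors"]),
        np.array(doc["coeffs"]),
        doc["lengthscale"],
        doc["y_mean"],
        doc["n_atoms"],
    )
    if doc["mode"] == "delta":
        if base is None:
            raise ValueError("delta-mode model requires its base potential")
        return CompositePotential(base, corr, doc["energy_shift"])
    return corr
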