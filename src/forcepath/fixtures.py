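"""Deterministic toy-system fixtures: potentials, datasets, failure modes.

Every fixture bundles a ground-truth potential, a seed geometry, an
exploration schedule, a deliberately biased base potential where the system
participates in surrogate studies, and the network + path dataset produced
by a ground-truth exploration — everything the other modules need for
self-contained, download-free experiments.  Bit-reproducible given the seed.

Catalog (FIXTURE_VERSION pins the parameterization):

* ``muller_brown`` — the four-Gaussian 2-D surface; three minima, two
  saddles; the reference system for network-recovery checks.
* ``morse_trimer`` — an H–X–H cluster whose H–H pair carries a Morse well
  plus an outer Gaussian well, giving a compact (bent) and an extended
  (near-linear) isomer with a genuine isomerization barrier.
* ``lj7`` — seven-atom Lennard-Jones cluster (global-minimum benchmarks).
* ``wall_channel`` — a two-basin 2-D surface (reactant A, deeper product B)
  enclosed by a steep radial wall.  The wall is the removable safeguard: a
  surrogate trained on search data never samples beyond it, so an
  unsafeguarded model invents a vast low-energy plateau out there — the
  leaky-hole failure a Δ-composed base prevents.  The biased base for this
  system under-binds the product basin, inverting the reaction
  thermodynamics: its equilibrium yield is small and rises with temperature,
  while the truth converts fully — the pattern a cheap semiempirical method
  shows against the reference in yield tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .afir import ExplorationSchedule, MinimizerOptions, ReactionNetwork, explore_network, save_network
from .geometry import Geometry, surface_point, write_xyz_frames
from .potentials import (
    BiasSpec,
    MullerBrown,
    PairClusterPotential,
    Potential,
    SurfaceWells,
    biased_base_potential,
)
from .surrogate import PathDataset, PathRecord, dataset_from_network

FIXTURE_VERSION = 1


@dataclass
class FixtureSpec:
    system: str
    noise_sigma: float = 0.0  # Gaussian energy noise on dataset records, kJ/mol
    rng_seed: int = 0
    counts: int = 0  # extra perturbed geometries appended to the dataset

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.counts < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Fixture:
    spec: FixtureSpec
    truth: Potential
    base: Potential | None
    seed_geometry: Geometry
    schedule: ExplorationSchedule
    network: ReactionNetwork
    dataset: PathDataset
    is_product: callable = lambda g: False
    is_reactant: callable = lambda g: False
    wall_onset_energy: float | None = None
    extras: dict = field(default_factory=dict)

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        save_network(self.network, os.path.join(out_dir, "network"))
        geoms, comments = [], []
        for r in self.dataset.records:
            g = r.geometry.copy()
            g.ref_energy = r.energy
            g.ref_gradient = r.gradient
            geoms.append(g)
            comments.append({"path_id": r.path_id, "discovery_index": r.discovery_index})
        write_xyz_frames(os.path.join(out_dir, "dataset.xyz"), geoms, comments=comments)


# ---------------------------------------------------------------------------
# System definitions


def _near(geometry: Geometry, center, radius: float) -> bool:
    return float(np.linalg.norm(geometry.coordinates[0, :2] - np.asarray(center))) < radius


def wall_channel_truth() -> SurfaceWells:
    return SurfaceWells(
        wells=[(-60.0, (-1.1, 0.0), 0.45), (-72.0, (1.1, 0.0), 0.45)],
        wall=(2.6, 300.0),
    )


def wall_channel_base() -> SurfaceWells:
    # product basin under-bound: wrong thermodynamics, intact wall
    return biased_base_potential(wall_channel_truth(), BiasSpec(depth_scales={1: 0.72}))


WALL_ONSET_ENERGY = 50.0  # kJ/mol; truth energies above this occur only on/past the wall


def morse_trimer_truth() -> PairClusterPotential:
    return PairClusterPotential(
        {
            (1, 2): {"kind": "morse", "D": 90.0, "a": 1.8, "r0": 1.8},
            (1, 1): {
                "kind": "morse_gauss",
                "D": 15.0, "a": 2.0, "r0": 1.9,
                "A": -12.0, "rg": 3.4, "w": 0.35,
            },
        }
    )


def morse_trimer_base() -> PairClusterPotential:
    return biased_base_potential(
        morse_trimer_truth(), BiasSpec(default_depth_scale=0.85, default_r0_shift=0.03)
    )


def morse_trimer_seed() -> Geometry:
    # bent isomer guess: H-X bonds 1.8 Å, H-H near the inner (Morse) well
    return Geometry(
        (1, 2, 1),
        np.array([[-0.95, 1.55, 0.0], [0.0, 0.0, 0.0], [0.95, 1.55, 0.0]]),
    )


def lj7_potential(epsilon: float = 25.0, sigma: float = 2.5) -> PairClusterPotential:
    return PairClusterPotential({(1, 1): {"kind": "lj", "epsilon": epsilon, "sigma": sigma}})


def lj7_seed(rng: np.random.Generator) -> Geometry:
    coords = rng.normal(scale=1.4, size=(7, 3)) * 1.0 + 2.5
    return Geometry((1,) * 7, coords)


# ---------------------------------------------------------------------------


def _schedule_for(system: str) -> ExplorationSchedule:
    if system == "muller_brown":
        return ExplorationSchedule(
            gammas=(200.0, 500.0), mode="directions", n_directions=8,
            n_frames=31, lup_sweeps=80, max_expansions=3,
            eq_energy_ceiling=-20.0,  # asymptotic plateau sits at 0
        )
    if system == "wall_channel":
        return ExplorationSchedule(
            gammas=(40.0, 75.0, 110.0), mode="directions", n_directions=8,
            n_frames=21, lup_sweeps=40, max_expansions=2,
        )
    if system == "morse_trimer":
        return ExplorationSchedule(
            gammas=(15.0, 40.0), mode="pairs", directions=("pull", "push"),
            n_frames=21, lup_sweeps=40, max_expansions=3,
            eq_energy_ceiling=-150.0,  # single H dissociation sits near −90
        )
    if system == "lj7":
        return ExplorationSchedule(
            gammas=(50.0,), mode="pairs", directions=("pull", "push"), max_pairs=6,
            n_frames=21, lup_sweeps=30, max_expansions=1,
            eq_energy_ceiling=-300.0,  # 6+1 dissociation channel cutoff
        )
    raise ValueError(f"unknown fixture system {system!r}")


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build a fixture: ground-truth exploration, dataset, and potentials."""
    rng = np.random.default_rng(spec.rng_seed)
    schedule = _schedule_for(spec.system)
    base: Potential | None = None
    wall_onset = None
    is_product = lambda g: False
    is_reactant = lambda g: False
    if spec.system == "muller_brown":
        truth: Potential = MullerBrown()
        seed = surface_point(-0.55, 1.44)
    elif spec.system == "wall_channel":
        truth = wall_channel_truth()
        base = wall_channel_base()
        seed = surface_point(-1.1, 0.0)
        wall_onset = WALL_ONSET_ENERGY
        is_product = lambda g: _near(g, (1.1, 0.0), 0.45)
        is_reactant = lambda g: _near(g, (-1.1, 0.0), 0.45)
    elif spec.system == "morse_trimer":
        truth = morse_trimer_truth()
        base = morse_trimer_base()
        seed = morse_trimer_seed()

        def is_product(g):  # extended isomer: H-H pair in the outer well
            return float(np.linalg.norm(g.coordinates[0] - g.coordinates[2])) > 2.6

        def is_reactant(g):
            return float(np.linalg.norm(g.coordinates[0] - g.coordinates[2])) <= 2.6

    elif spec.system == "lj7":
        truth = lj7_potential()
        seed = lj7_seed(rng)
    else:
        raise ValueError(f"unknown fixture system {spec.system!r}")

    network = explore_network(seed, truth, schedule, seed_rng=spec.rng_seed)
    network.metadata["fixture_version"] = FIXTURE_VERSION
    network.metadata["system"] = spec.system
    dataset = dataset_from_network(network, gradient_potential=truth)
    if spec.counts > 0 and dataset.n_records > 0:
        extra = []
        max_path = max(r.path_id for r in dataset.records)
        for k in range(spec.counts):
            r = dataset.records[int(rng.integers(dataset.n_records))]
            coords = r.geometry.coordinates + rng.normal(scale=0.08, size=r.geometry.coordinates.shape)
            if r.geometry.n_atoms == 1:
                coords[:, 2] = 0.0
            g = r.geometry.with_coordinates(coords)
            res = truth.evaluate(g)
            extra.append(PathRecord(g, res.energy, res.gradient, max_path + 1 + k, max_path + 1 + k))
        dataset = PathDataset(dataset.records + extra)
    if spec.noise_sigma > 0:
        noisy = []
        for r in dataset.records:
            noisy.append(
                PathRecord(
                    r.geometry,
                    r.energy + float(rng.normal(scale=spec.noise_sigma)),
                    r.gradient, r.path_id, r.discovery_index,
                )
            )
        dataset = PathDataset(noisy)
    return Fixture(
        spec=spec, truth=truth, base=base, seed_geometry=seed, schedule=schedule,
        network=network, dataset=dataset,
        is_product=is_product, is_reactant=is_reactant,
        wall_onset_energy=wall_onset,
        extras={"version": FIXTURE_VERSION},
    )


# ---------------------------------------------------------------------------
# Random kinetic networks (RCMC validation fixtures)


def random_rate_model(
    n_states: int,
    rng_seed: int,
    temperature: float = 300.0,
    barrier_range: tuple[float, float] = (5.0, 80.0),
    energy_range: tuple[float, float] = (0.0, 30.0),
    extra_edge_fraction: float = 0.4,
):
    """Connected random first-order network with detailed-balance Eyring rates.

    State energies are uniform in ``energy_range``; each edge's transition
    state sits ``barrier_range``-uniform above the higher endpoint, so both
    directed rates derive from one saddle and detailed balance holds.
    """
    from .kinetics import RateModel, eyring_rate

    rng = np.random.default_rng(rng_seed)
    energies = rng.uniform(*energy_range, size=n_states)
    edges = set()
    order = rng.permutation(n_states)
    for k in range(1, n_states):  # random spanning tree keeps it connected
        a = int(order[k])
        b = int(order[int(rng.integers(k))])
        edges.add((min(a, b), max(a, b)))
    n_extra = int(extra_edge_fraction * n_states)
    for _ in range(n_extra):
        a, b = rng.integers(n_states, size=2)
        if a != b:
            edges.add((min(int(a), int(b)), max(int(a), int(b))))
    K = np.zeros((n_states, n_states))
    for a, b in sorted(edges):
        e_ts = max(energies[a], energies[b]) + rng.uniform(*barrier_range)
        K[a, b] += eyring_rate(e_ts - energies[a], temperature)
        K[b, a] += eyring_rate(e_ts - energies[b], temperature)
    return RateModel(temperature, K, energies, source=f"random-{rng_seed}")
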