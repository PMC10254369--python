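"""Potential-energy-surface abstraction and analytic toy potentials.

Every potential implements a single contract: ``evaluate(geometry)`` returns
the energy (kJ/mol) and the analytic gradient (kJ/mol/Å, one 3-vector per
atom).  The same contract is used by the artificial-force terms, by trained
surrogate models, and is the adapter seam for plugging a real semiempirical
or ab initio backend later.

Shipped ground truths:

* :class:`MullerBrown` — the standard four-Gaussian 2-D model surface
  (parameters loaded from a versioned constants file so the oracle-derived
  minima and saddles are bit-reproducible);
* :class:`PairClusterPotential` — translation/rotation-invariant sums of
  Lennard-Jones, Morse, or double-Morse pair terms over atomic clusters;
* :class:`SurfaceWells` — Gaussian basins on a 2-D surface plus an optional
  outer repulsive wall (the removable-wall robustness fixture).

:func:`biased_base_potential` derives from any of these a deliberately
inaccurate but robust base potential — the role a fast semiempirical method
plays in production: it keeps the short-range repulsion and dissociation
physics while carrying a smooth, structure-dependent error of tens of
kJ/mol.  :class:`CompositePotential` implements the Δ-composition
``E_total = E_base + E_correction + shift``.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry, surface_point


class CompositionError(ValueError):
    """Geometry incompatible with the potential (wrong stoichiometry/shape)."""


class ConfigurationError(ValueError):
    """Potential parameters missing or invalid."""


@dataclass
class PotentialResult:
    energy: float  # kJ/mol
    gradient: np.ndarray  # (n_atoms, 3), kJ/mol/Å


class Potential:
    """Base class: subclasses implement :meth:`evaluate`."""

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        raise NotImplementedError

    def energy(self, geometry: Geometry) -> float:
        return self.evaluate(geometry).energy

    def energies(self, geometries) -> np.ndarray:
        return np.array([self.energy(g) for g in geometries])


def evaluate(potential: Potential, geometry: Geometry) -> PotentialResult:
    """Uniform evaluation entry point (energy + analytic gradient)."""
    return potential.evaluate(geometry)


def finite_difference_gradient(
    potential: Potential, geometry: Geometry, step: float = 1e-5, order: int = 2
) -> np.ndarray:
    """Central finite-difference gradient; the oracle for analytic gradients.

    ``order=2`` is the plain two-point stencil; ``order=4`` uses the
    five-point stencil, whose truncation error is O(h⁴) — needed when the
    function has large high-order derivatives (e.g. kernel interpolants).
    """
    coords = geometry.coordinates
    grad = np.zeros_like(coords)

    def energy_at(i, k, offset):
        shifted = coords.copy()
        shifted[i, k] += offset
        return potential.energy(geometry.with_coordinates(shifted))

    for i in range(coords.shape[0]):
        for k in range(3):
            if order == 2:
                grad[i, k] = (energy_at(i, k, step) - energy_at(i, k, -step)) / (2.0 * step)
            elif order == 4:
                grad[i, k] = (
                    -energy_at(i, k, 2 * step)
                    + 8.0 * energy_at(i, k, step)
                    - 8.0 * energy_at(i, k, -step)
                    + energy_at(i, k, -2 * step)
                ) / (12.0 * step)
            else:
                raise ValueError("order must be 2 or 4")
    return grad


# ---------------------------------------------------------------------------
# Müller–Brown surface


def _load_mb_params() -> dict:
    ref = importlib.resources.files("forcepath") / "data" / "muller_brown.json"
    return json.loads(ref.read_text())


class MullerBrown(Potential):
    """Four-Gaussian Müller–Brown model surface on (x, y).

    Operates on single-pseudo-atom geometries (see
    :func:`forcepath.geometry.surface_point`); the z coordinate is ignored
    and carries zero gradient.
    """

    def __init__(self) -> None:
        p = _load_mb_params()
        self.A = np.array(p["A"])
        self.a = np.array(p["a"])
        self.b = np.array(p["b"])
        self.c = np.array(p["c"])
        self.x0 = np.array(p["x0"])
        self.y0 = np.array(p["y0"])

    def evaluate_xy(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized evaluation: points (m, 2) -> (energies (m,), grads (m, 2))."""
        pts = np.atleast_2d(points)
        dx = pts[:, 0:1] - self.x0  # (m, 4)
        dy = pts[:, 1:2] - self.y0
        expo = self.a * dx**2 + self.b * dx * dy + self.c * dy**2
        # the fourth term's exponent is positive definite (the surface is
        # globally confining); cap it so far-field probes stay finite
        terms = self.A * np.exp(np.minimum(expo, 500.0))
        energy = terms.sum(axis=1)
        gx = (terms * (2.0 * self.a * dx + self.b * dy)).sum(axis=1)
        gy = (terms * (self.b * dx + 2.0 * self.c * dy)).sum(axis=1)
        return energy, np.stack([gx, gy], axis=1)

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        if geometry.n_atoms != 1:
            raise CompositionError("Müller–Brown expects a single surface pseudo-atom")
        e, g = self.evaluate_xy(geometry.coordinates[:1, :2])
        grad = np.zeros((1, 3))
        grad[0, :2] = g[0]
        return PotentialResult(float(e[0]), grad)


def muller_brown(point) -> PotentialResult:
    """Energy and analytic gradient of the Müller–Brown surface at a 2-vector."""
    return MullerBrown().evaluate(surface_point(point[0], point[1]))


# ---------------------------------------------------------------------------
# Pair-interaction clusters


def _pair_key(zi: int, zj: int) -> tuple[int, int]:
    return (min(zi, zj), max(zi, zj))


def _pair_energy_dEdr(spec: dict, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    kind = spec["kind"]
    if kind == "lj":
        eps, sigma = spec["epsilon"], spec["sigma"]
        sr6 = (sigma / r) ** 6
        e = 4.0 * eps * (sr6**2 - sr6)
        dedr = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
        return e, dedr
    if kind == "morse":
        D, a, r0 = spec["D"], spec["a"], spec["r0"]
        ex = np.exp(-a * (r - r0))
        e = D * (1.0 - ex) ** 2 - D
        dedr = 2.0 * a * D * (1.0 - ex) * ex
        return e, dedr
    if kind == "morse_gauss":
        # Morse well plus an outer Gaussian well: a double-minimum pair term
        # (bond-breaking analogue) while keeping the single repulsive wall
        D, a, r0 = spec["D"], spec["a"], spec["r0"]
        A, rg, w = spec["A"], spec["rg"], spec["w"]
        ex = np.exp(-a * (r - r0))
        e = D * (1.0 - ex) ** 2 - D
        dedr = 2.0 * a * D * (1.0 - ex) * ex
        g = A * np.exp(-((r - rg) ** 2) / (2.0 * w**2))
        e = e + g
        dedr = dedr + g * (-(r - rg) / w**2)
        return e, dedr
    raise ConfigurationError(f"unknown pair interaction kind {kind!r}")


class PairClusterPotential(Potential):
    """Sum of pair interactions over all atom pairs of a cluster.

    ``pair_params`` maps unordered element pairs (z_small, z_large) to a spec:
    ``{"kind": "lj", "epsilon", "sigma"}``, ``{"kind": "morse", "D", "a",
    "r0"}``, or ``{"kind": "double_morse", "wells": [(D, a, r0), ...]}``.
    Invariant under rigid translation/rotation and identical-atom permutation
    by construction; diverges (LJ) or rises to a large finite wall (Morse) as
    any pair distance goes to zero.
    """

    def __init__(self, pair_params: dict):
        self.pair_params = {_pair_key(*k): dict(v) for k, v in pair_params.items()}

    def _spec_for(self, zi: int, zj: int) -> dict:
        key = _pair_key(zi, zj)
        if key not in self.pair_params:
            raise ConfigurationError(f"no pair parameters for element pair {key}")
        return self.pair_params[key]

    def _pair_index(self, atomic_numbers) -> dict:
        """Group the upper-triangle pair list by interaction spec (cached per composition)."""
        key = tuple(atomic_numbers)
        cache = getattr(self, "_index_cache", None)
        if cache is None:
            cache = self._index_cache = {}
        if key not in cache:
            n = len(key)
            ii, jj = np.triu_indices(n, k=1)
            groups: dict[tuple[int, int], list[int]] = {}
            for k in range(ii.size):
                pk = _pair_key(key[ii[k]], key[jj[k]])
                self._spec_for(key[ii[k]], key[jj[k]])  # raise early if missing
                groups.setdefault(pk, []).append(k)
            cache[key] = (ii, jj, {pk: np.array(idx) for pk, idx in groups.items()})
        return cache[key]

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        coords = geometry.coordinates
        ii, jj, groups = self._pair_index(geometry.atomic_numbers)
        d = coords[ii] - coords[jj]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-12):
            raise CompositionError("coincident atoms")
        energy = 0.0
        dedr = np.zeros_like(r)
        for pk, idx in groups.items():
            e_k, dedr_k = _pair_energy_dEdr(self.pair_params[pk], r[idx])
            energy += float(e_k.sum())
            dedr[idx] = dedr_k
        pair_grad = (dedr / r)[:, None] * d
        grad = np.zeros_like(coords)
        np.add.at(grad, ii, pair_grad)
        np.add.at(grad, jj, -pair_grad)
        return PotentialResult(energy, grad)


def pair_cluster_potential(params: dict) -> PairClusterPotential:
    """Build a cluster potential from per-element-pair interaction parameters."""
    return PairClusterPotential(params)


# ---------------------------------------------------------------------------
# 2-D multi-well surfaces with a removable repulsive wall


class SurfaceWells(Potential):
    """Gaussian basins on a 2-D surface, optionally confined by an outer wall.

    energy(x, y) = Σ_k A_k exp(−|r − c_k|² / (2 σ_k²)) + wall(|r|)

    with wall(ρ) = H·max(0, ρ − R)⁴ (C³-smooth hinge).  Negative amplitudes
    are wells.  Removing the wall (``wall=None``) reproduces the
    unsafeguarded-extrapolation failure mode used by the robustness fixtures.
    """

    def __init__(self, wells, wall: tuple[float, float] | None = None):
        # wells: list of (amplitude kJ/mol, (cx, cy), sigma)
        self.wells = [(float(a), np.array(c, dtype=float), float(s)) for a, c, s in wells]
        self.wall = None if wall is None else (float(wall[0]), float(wall[1]))  # (R, H)

    def evaluate_xy(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(points).astype(float)
        energy = np.zeros(pts.shape[0])
        grad = np.zeros_like(pts)
        for amp, center, sigma in self.wells:
            d = pts - center
            e = amp * np.exp(-(d**2).sum(axis=1) / (2.0 * sigma**2))
            energy += e
            grad += (-e / sigma**2)[:, None] * d
        if self.wall is not None:
            R, H = self.wall
            rho = np.linalg.norm(pts, axis=1)
            s = np.maximum(0.0, rho - R)
            energy += H * s**4
            nz = rho > 1e-12
            coef = np.zeros_like(rho)
            coef[nz] = 4.0 * H * s[nz] ** 3 / rho[nz]
            grad += coef[:, None] * pts
        return energy, grad

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        if geometry.n_atoms != 1:
            raise CompositionError("surface potential expects a single surface pseudo-atom")
        e, g = self.evaluate_xy(geometry.coordinates[:1, :2])
        grad = np.zeros((1, 3))
        grad[0, :2] = g[0]
        return PotentialResult(float(e[0]), grad)


# ---------------------------------------------------------------------------
# Biased base potentials (the robust-but-inaccurate role)


@dataclass
class BiasSpec:
    """Systematic error applied to a ground-truth potential.

    ``depth_scales`` multiplies well depths (per element pair for clusters,
    per well index for surfaces); ``r0_shifts`` displaces pair equilibrium
    distances in Å.  Scales must stay positive so repulsive walls are
    preserved; the derived base potential remains finite-below-bounded, keeps
    short-range divergence and long-range dissociation, but differs from the
    truth by a smooth structure-dependent error.
    """

    depth_scales: dict = field(default_factory=dict)
    r0_shifts: dict = field(default_factory=dict)
    default_depth_scale: float = 1.0
    default_r0_shift: float = 0.0


def _bias_pair_spec(spec: dict, scale: float, shift: float) -> dict:
    out = dict(spec)
    if spec["kind"] == "lj":
        out["epsilon"] = spec["epsilon"] * scale
        out["sigma"] = spec["sigma"] + shift / 2 ** (1 / 6)
    elif spec["kind"] == "morse":
        out["D"] = spec["D"] * scale
        out["r0"] = spec["r0"] + shift
    elif spec["kind"] == "morse_gauss":
        out["D"] = spec["D"] * scale
        out["r0"] = spec["r0"] + shift
        out["A"] = spec["A"] * scale
        out["rg"] = spec["rg"] + shift
    return out


def biased_base_potential(truth: Potential, bias: BiasSpec) -> Potential:
    """Derive a robust-but-biased base potential from a ground truth.

    For cluster potentials, well depths are scaled and equilibrium distances
    shifted per element pair; for surface potentials, well amplitudes are
    scaled per well index while any outer wall is kept intact.
    """
    scales = list(bias.depth_scales.values()) + [bias.default_depth_scale]
    if any(s <= 0 for s in scales):
        raise ConfigurationError("depth scale must be positive (repulsive wall must be preserved)")
    if isinstance(truth, PairClusterPotential):
        new_params = {}
        for key, spec in truth.pair_params.items():
            scale = bias.depth_scales.get(key, bias.default_depth_scale)
            shift = bias.r0_shifts.get(key, bias.default_r0_shift)
            new_params[key] = _bias_pair_spec(spec, scale, shift)
        return PairClusterPotential(new_params)
    if isinstance(truth, SurfaceWells):
        wells = [
            (amp * bias.depth_scales.get(i, bias.default_depth_scale), c, s)
            for i, (amp, c, s) in enumerate(truth.wells)
        ]
        return SurfaceWells(wells, wall=truth.wall)
    raise ConfigurationError(f"cannot bias potential of type {type(truth).__name__}")


# ---------------------------------------------------------------------------
# Δ-composition


class CompositePotential(Potential):
    """E_total = E_base + E_correction + shift (gradients add likewise)."""

    def __init__(self, base: Potential, correction: Potential | None, energy_shift: float = 0.0):
        self.base = base
        self.correction = correction
        self.energy_shift = float(energy_shift)

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        res = self.base.evaluate(geometry)
        energy = res.energy + self.energy_shift
        grad = res.gradient.copy()
        if self.correction is not None:
            corr = self.correction.evaluate(geometry)
            energy += corr.energy
            grad += corr.gradient
        return PotentialResult(energy, grad)


def fit_energy_shift(target: Potential, potential: Potential, geometries) -> float:
    """Least-squares constant offset aligning *potential* to *target*.

    Returns the shift minimizing Σ (E_target − (E_potential + shift))², i.e.
    the mean energy difference over the reference geometry set.
    """
    diffs = [target.energy(g) - potential.energy(g) for g in geometries]
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Config-driven construction (CLI / YAML entry point)


def potential_from_config(config: dict) -> Potential:
    """Build a potential from a ``{kind: ..., params: {...}}`` mapping."""
    kind = config["kind"]
    params = config.get("params", {})
    if kind == "muller_brown":
        return MullerBrown()
    if kind == "pair_cluster":
        pairs = {tuple(map(int, k.split("-"))): v for k, v in params["pairs"].items()}
        return PairClusterPotential(pairs)
    if kind == "surface_wells":
        wall = tuple(params["wall"]) if params.get("wall") else None
        return SurfaceWells(params["wells"], wall=wall)
    if kind == "biased":
        truth = potential_from_config(params["truth"])
        spec = BiasSpec(
            depth_scales=params.get("depth_scales", {}),
            default_depth_scale=params.get("default_depth_scale", 1.0),
            r0_shifts=params.get("r0_shifts", {}),
            default_r0_shift=params.get("default_r0_shift", 0.0),
        )
        return biased_base_potential(truth, spec)
    if kind == "composite":
        base = potential_from_config(params["base"])
        corr = potential_from_config(params["correction"]) if params.get("correction") else None
        return CompositePotential(base, corr, params.get("energy_shift", 0.0))
    raise ConfigurationError(f"unknown potential kind {kind!r}")
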