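"""Pairwise-sorted interatomic-distance descriptors and Boltzmann group descriptors.

A structure is encoded by computing all N(N−1)/2 interatomic distances,
labelling each by the unordered pair of atomic numbers of its endpoints,
sorting the distances within each label block in ascending order, and
concatenating the blocks in canonical (Z_small, Z_large) lexicographic order.
The result is invariant under rigid motions and under permutation of
identical atoms, and needs no structural alignment.

Conformer ensembles sharing the same connectivity are summarized by the
Boltzmann-weighted sum of their member descriptors,

    X_p = Σ_i w_i X_i^p ,   w_i = exp(−E_i / k_B T) / Σ_j exp(−E_j / k_B T),

with E_i the potential energy of conformer i relative to the lowest energy in
the ensemble's network and T = 300 K by default.  The lowest-energy member
always carries the largest weight, so a group projects near its most stable
conformer on any downstream map.

Descriptors only compare across identical stoichiometry; mixing compositions
raises rather than silently padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import thermal_energy
from .geometry import Geometry

DEFAULT_TEMPERATURE = 300.0  # K


class DegenerateGeometryError(ValueError):
    """Two atoms closer than the resolvable distance floor."""


@dataclass
class DescriptorVector:
    """Sorted-distance descriptor with its concatenation layout.

    ``layout`` is an ordered list of ((Z_small, Z_large), count) pairs; within
    each block the ``values`` (Å) are non-decreasing.
    """

    values: np.ndarray
    layout: tuple[tuple[tuple[int, int], int], ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.layout = tuple((tuple(pair), int(count)) for pair, count in self.layout)

    def same_layout(self, other: "DescriptorVector") -> bool:
        return self.layout == other.layout


@dataclass
class GroupWeights:
    weights: np.ndarray
    temperature: float
    relative_energies: np.ndarray


def sorted_distance_descriptor(geometry: Geometry, min_distance: float = 1e-6) -> DescriptorVector:
    """Pairwise-sorted distance descriptor of a single structure."""
    n = geometry.n_atoms
    if n < 2:
        raise ValueError("descriptor requires at least 2 atoms")
    coords = geometry.coordinates
    zs = geometry.atomic_numbers
    buckets: dict[tuple[int, int], list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < min_distance:
                raise DegenerateGeometryError(
                    f"atoms {i} and {j} are {r:.2e} Å apart (< {min_distance} Å)"
                )
            key = (min(zs[i], zs[j]), max(zs[i], zs[j]))
            buckets.setdefault(key, []).append(r)
    layout = []
    values: list[float] = []
    for key in sorted(buckets):
        block = sorted(buckets[key])
        layout.append((key, len(block)))
        values.extend(block)
    return DescriptorVector(np.array(values), tuple(layout))


def boltzmann_weights(relative_energies, temperature: float = DEFAULT_TEMPERATURE) -> GroupWeights:
    """Normalized Boltzmann weights w_i ∝ exp(−E_i / k_B T).

    Energies are re-referenced to the group minimum internally, so any common
    offset cancels; the minimum-energy member always has the largest weight.
    """
    e = np.asarray(relative_energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    shifted = e - e.min()
    w = np.exp(-shifted / thermal_energy(temperature))
    w /= w.sum()
    return GroupWeights(w, float(temperature), e)


def group_descriptor(
    descriptors: list[DescriptorVector],
    relative_energies,
    temperature: float = DEFAULT_TEMPERATURE,
) -> DescriptorVector:
    """Boltzmann-weighted sum of member descriptors (one ensemble → one vector)."""
    if len(descriptors) == 0:
        raise ValueError("no descriptors")
    first = descriptors[0]
    for d in descriptors[1:]:
        if not d.same_layout(first):
            raise ValueError("descriptor layout mismatch (different stoichiometry)")
    gw = boltzmann_weights(relative_energies, temperature)
    if gw.weights.size != len(descriptors):
        raise ValueError("energies/descriptors length mismatch")
    stacked = np.stack([d.values for d in descriptors])
    return DescriptorVector(gw.weights @ stacked, first.layout)


# ---------------------------------------------------------------------------
# Descriptor strategies: a uniform vector/Jacobian interface used by surrogate
# models, equilibrium-state identification, and mapping.


class SortedDistanceDescriptor:
    """Strategy wrapper around :func:`sorted_distance_descriptor`.

    The Jacobian uses the sorting permutation frozen at the evaluation point:
    each descriptor entry is one pair distance r_ij, whose gradient is the
    standard unit-bond-vector expression.  Valid almost everywhere; kinks
    occur only where two same-label distances tie.
    """

    def vector(self, geometry: Geometry) -> np.ndarray:
        return sorted_distance_descriptor(geometry).values

    def vector_and_jacobian(self, geometry: Geometry) -> tuple[np.ndarray, np.ndarray]:
        n = geometry.n_atoms
        coords = geometry.coordinates
        zs = geometry.atomic_numbers
        entries: dict[tuple[int, int], list[tuple[float, int, int]]] = {}
        for i in range(n):
            for j in range(i + 1, n):
                r = float(np.linalg.norm(coords[i] - coords[j]))
                key = (min(zs[i], zs[j]), max(zs[i], zs[j]))
                entries.setdefault(key, []).append((r, i, j))
        values: list[float] = []
        rows: list[tuple[float, int, int]] = []
        for key in sorted(entries):
            block = sorted(entries[key])
            values.extend(v for v, _, _ in block)
            rows.extend(block)
        jac = np.zeros((len(rows), n, 3))
        for p, (r, i, j) in enumerate(rows):
            u = (coords[i] - coords[j]) / r
            jac[p, i] = u
            jac[p, j] = -u
        return np.array(values), jac.reshape(len(rows), n * 3)


class CoordinateDescriptor:
    """Raw in-plane coordinates as the descriptor (2-D surface systems).

    Surface toys are single-point systems with no interatomic distances, so
    the identity map on (x, y) is the natural feature space there.
    """

    def vector(self, geometry: Geometry) -> np.ndarray:
        return geometry.coordinates[0, :2].copy()

    def vector_and_jacobian(self, geometry: Geometry) -> tuple[np.ndarray, np.ndarray]:
        jac = np.zeros((2, geometry.n_atoms * 3))
        jac[0, 0] = 1.0
        jac[1, 1] = 1.0
        return self.vector(geometry), jac


def default_descriptor(geometry: Geometry):
    """Sorted distances for atomic systems; raw coordinates for surface points."""
    return SortedDistanceDescriptor() if geometry.n_atoms >= 2 else CoordinateDescriptor()


def descriptor_matrix(strategy, geometries) -> np.ndarray:
    return np.stack([strategy.vector(g) for g in geometries])
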