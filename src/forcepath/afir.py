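"""Artificial-force path tracing and reaction-path-network exploration.

The search follows the artificial-force paradigm: starting from an
equilibrium state (EQ, a local minimum), a smooth artificial force term is
added to the potential so that crossing a reaction barrier becomes a downhill
walk.  Minimizing the biased surface while recording the trajectory yields an
approximate reaction path; relaxing that path with the locally-updated-planes
(LUP) scheme — each interior frame descends within the hyperplane orthogonal
to the local path tangent — produces a refined path whose maximum-energy
frame serves as the approximate transition state.  Endpoints are re-minimized
on the unbiased surface and deduplicated into the network's EQ catalog by a
descriptor-distance + energy criterion.

Two force generators are provided:

* :class:`AfirBias` — the fragment-pair form for atomic clusters.  For
  fragments A, B the bias energy is ±α·ρ(Q) with the inverse-power weighted
  mean contact distance

      ρ(Q) = Σ_{i∈A, j∈B} ω_ij r_ij / Σ ω_ij,
      ω_ij = ((R_cov,i + R_cov,j) / r_ij)^p,   p = 6 by default,

  and α = γ / r̄₀ where γ is the model collision energy (kJ/mol) and r̄₀ the
  mean covalent contact distance of the fragment pair.  ``pull`` adds +α·ρ
  (minimization draws the fragments together); ``push`` adds −α·ρ.
* :class:`LinearBias` — a constant force along a chosen in-plane direction,
  the natural analogue for 2-D surface toys where no fragments exist.

Exploration is breadth-wise: expand an EQ by applying every force in the
schedule, trace, refine, register; repeat on newly found EQs either in FIFO
discovery order or, with kinetic navigation, in order of the population an
on-the-fly contracted kinetic simulation assigns to the unexpanded states.
Everything is deterministic given the exploration seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .constants import covalent_radius
from .descriptors import default_descriptor
from .geometry import Geometry, read_xyz_frames, write_xyz_frames
from .potentials import CompositePotential, Potential, PotentialResult


# ---------------------------------------------------------------------------
# Force terms


@dataclass
class FragmentPair:
    set_a: tuple[int, ...]
    set_b: tuple[int, ...]

    def __post_init__(self):
        self.set_a = tuple(sorted(int(i) for i in self.set_a))
        self.set_b = tuple(sorted(int(i) for i in self.set_b))
        if not self.set_a or not self.set_b:
            raise ValueError("fragments must be non-empty")
        if set(self.set_a) & set(self.set_b):
            raise ValueError("fragments must be disjoint")


@dataclass
class AfirForceSpec:
    gamma: float  # model collision energy, kJ/mol
    direction: str = "pull"  # pull: fragments drawn together; push: driven apart
    p: int = 6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.direction not in ("push", "pull"):
            raise ValueError("direction must be 'push' or 'pull'")
        if self.p < 1:
            raise ValueError("p must be >= 1")


class AfirBias(Potential):
    """Fragment-pair artificial force term (implements the potential contract)."""

    def __init__(self, fragments: FragmentPair, spec: AfirForceSpec):
        self.fragments = fragments
        self.spec = spec

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        coords = geometry.coordinates
        n = geometry.n_atoms
        for idx in self.fragments.set_a + self.fragments.set_b:
            if idx >= n:
                raise ValueError(f"fragment atom index {idx} out of range")
        if self.spec.gamma == 0.0:
            return PotentialResult(0.0, np.zeros_like(coords))
        p = self.spec.p
        pairs = [(i, j) for i in self.fragments.set_a for j in self.fragments.set_b]
        r = np.empty(len(pairs))
        c = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            r[k] = np.linalg.norm(coords[i] - coords[j])
            c[k] = covalent_radius(geometry.atomic_numbers[i]) + covalent_radius(
                geometry.atomic_numbers[j]
            )
        w = (c / r) ** p
        num = float(np.sum(w * r))
        den = float(np.sum(w))
        rho = num / den
        alpha = self.spec.gamma / float(np.mean(c))
        sign = 1.0 if self.spec.direction == "pull" else -1.0
        # d rho / d r_k via quotient rule; then chain to Cartesian coordinates
        dnum = (1.0 - p) * (c**p) * r ** (-p)
        dden = -p * (c**p) * r ** (-p - 1)
        drho = (dnum * den - num * dden) / den**2
        grad = np.zeros_like(coords)
        for k, (i, j) in enumerate(pairs):
            u = (coords[i] - coords[j]) / r[k]
            g = sign * alpha * drho[k] * u
            grad[i] += g
            grad[j] -= g
        return PotentialResult(sign * alpha * rho, grad)


def afir_bias(geometry: Geometry, fragments: FragmentPair, spec: AfirForceSpec) -> PotentialResult:
    """Bias energy and analytic gradient of the fragment-pair artificial force."""
    return AfirBias(fragments, spec).evaluate(geometry)


class LinearBias(Potential):
    """Constant in-plane force for surface systems: E = −α · d̂ · (x, y)."""

    LENGTH_SCALE = 1.0  # Å; converts the collision-energy gamma to a force

    def __init__(self, direction, gamma: float):
        d = np.asarray(direction, dtype=float)
        self.direction = d / np.linalg.norm(d)
        self.alpha = float(gamma) / self.LENGTH_SCALE

    def evaluate(self, geometry: Geometry) -> PotentialResult:
        xy = geometry.coordinates[0, :2]
        grad = np.zeros_like(geometry.coordinates)
        grad[0, :2] = -self.alpha * self.direction
        return PotentialResult(-self.alpha * float(self.direction @ xy), grad)


# ---------------------------------------------------------------------------
# Minimization and path tracing


@dataclass
class MinimizerOptions:
    gtol: float = 1e-6  # kJ/mol/Å, max-norm of the gradient
    max_steps: int = 5000
    trace_step: float = 0.02  # Å per recorded walk step
    trace_gtol: float = 1e-3
    trace_max_steps: int = 4000


def minimize_geometry(
    potential: Potential, geometry: Geometry, opts: MinimizerOptions | None = None
) -> tuple[Geometry, bool]:
    """Quasi-Newton minimization to an EQ; returns (geometry, converged)."""
    opts = opts or MinimizerOptions()
    shape = geometry.coordinates.shape

    def fun(x):
        res = potential.evaluate(geometry.with_coordinates(x.reshape(shape)))
        return res.energy, res.gradient.reshape(-1)

    out = scipy_minimize(
        fun,
        geometry.flat(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": opts.max_steps, "gtol": opts.gtol, "ftol": 0.0},
    )
    final = geometry.with_coordinates(out.x.reshape(shape))
    gnorm = float(np.max(np.abs(out.jac)))
    return final, bool(gnorm <= opts.gtol * 10)


@dataclass
class TraceResult:
    frames: list  # list[Geometry]
    converged: bool


def trace_afir_path(
    start: Geometry,
    potential: Potential,
    bias: Potential,
    opts: MinimizerOptions | None = None,
) -> TraceResult:
    """Minimize potential + bias from an EQ, recording a continuous trajectory.

    A normalized steepest-descent walk with backtracking keeps the recorded
    frames on a connected path (quasi-Newton iterates would jump); the walk
    ends at a biased-surface minimum or, failing convergence within the step
    budget, is flagged incomplete.
    """
    opts = opts or MinimizerOptions()
    biased = CompositePotential(potential, bias)
    shape = start.coordinates.shape
    x = start.flat().copy()
    frames = [start.with_coordinates(x.reshape(shape))]
    step = opts.trace_step
    res = biased.evaluate(frames[0])
    energy, grad = res.energy, res.gradient.reshape(-1)
    converged = False
    for _ in range(opts.trace_max_steps):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < opts.trace_gtol:
            converged = True
            break
        direction = -grad / gnorm
        s = step
        accepted = False
        for _ in range(12):
            x_new = x + s * direction
            res_new = biased.evaluate(start.with_coordinates(x_new.reshape(shape)))
            if res_new.energy <= energy + 1e-12:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            # line search collapsed: we sit at a biased minimum within the
            # walk's resolution; the quasi-Newton polish finishes the job
            converged = True
            break
        x = x_new
        energy, grad = res_new.energy, res_new.gradient.reshape(-1)
        frames.append(start.with_coordinates(x.reshape(shape)))
    if converged:
        # polish the biased minimum so the endpoint is well converged
        polished, ok = minimize_geometry(biased, frames[-1], opts)
        if ok:
            frames.append(polished)
    return TraceResult(frames, converged)


# ---------------------------------------------------------------------------
# Paths and LUP refinement


@dataclass
class ReactionPath:
    frames: list  # list[Geometry]
    energies: np.ndarray  # true-potential, force-free, kJ/mol
    ts_index: int
    endpoints: tuple[int, int]  # (eq_id_start, eq_id_end)
    discovery_index: int
    flag: str = "ok"  # "ok" | "incomplete"
    # Continuous-path barrier estimate: the discrete frame maximum undershoots
    # the true crossing energy by O(Δs²); a parabola through the three frames
    # around the maximum recovers it.
    ts_energy_interp: float | None = None

    @property
    def ts_energy(self) -> float:
        if self.ts_energy_interp is not None:
            return float(self.ts_energy_interp)
        return float(self.energies[self.ts_index])

    @property
    def barrier_fwd(self) -> float:
        return max(0.0, self.ts_energy - float(self.energies[0]))

    @property
    def barrier_bwd(self) -> float:
        return max(0.0, self.ts_energy - float(self.energies[-1]))


class RefinementError(RuntimeError):
    pass


def resample_path(coords: np.ndarray, n_frames: int) -> np.ndarray:
    """Equal-arc-length resampling of a polyline (m, d) -> (n_frames, d)."""
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 1e-12:
        return np.repeat(coords[:1], n_frames, axis=0)
    targets = np.linspace(0.0, total, n_frames)
    out = np.empty((n_frames, coords.shape[1]))
    for d in range(coords.shape[1]):
        out[:, d] = np.interp(targets, s, coords[:, d])
    return out


def lup_refine(
    frames: list,
    potential: Potential,
    n_sweeps: int = 100,
    step: float = 0.05,
    tol_disp: float = 1e-4,
    reminimize_endpoints: bool = True,
    opts: MinimizerOptions | None = None,
    sweep_log: list | None = None,
) -> ReactionPath:
    """Relax a frame sequence by locally updated planes.

    Each sweep displaces every interior frame downhill within the hyperplane
    orthogonal to the central-difference path tangent (with per-frame
    backtracking so the true energy never increases), then redistributes the
    frames to equal arc length.  Sweeps stop when the largest per-frame
    displacement falls below ``tol_disp`` Å.  Endpoints are re-minimized
    without constraint; the approximate transition state is the
    maximum-energy frame of the refined path.
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    template = frames[0]
    shape = template.coordinates.shape
    X = np.stack([f.flat() for f in frames])
    if reminimize_endpoints:
        for idx in (0, -1):
            g, _ = minimize_geometry(potential, template.with_coordinates(X[idx].reshape(shape)), opts)
            X[idx] = g.flat()

    def energy_at(row: np.ndarray) -> float:
        return potential.energy(template.with_coordinates(row.reshape(shape)))

    n = X.shape[0]
    energies = np.array([energy_at(X[i]) for i in range(n)])
    for _ in range(n_sweeps):
        pre_descent = energies.copy()
        max_disp = 0.0
        for i in range(1, n - 1):
            t = X[i + 1] - X[i - 1]
            tn = np.linalg.norm(t)
            if tn < 1e-12:
                raise RefinementError("path collapse: adjacent frames coincide")
            t /= tn
            res = potential.evaluate(template.with_coordinates(X[i].reshape(shape)))
            g = res.gradient.reshape(-1)
            g_perp = g - (g @ t) * t
            gp = np.linalg.norm(g_perp)
            if gp < 1e-12:
                continue
            s = step
            moved = False
            for _ in range(15):
                cand = X[i] - s * g_perp / max(gp, 1.0)
                e_cand = energy_at(cand)
                if e_cand <= energies[i] + 1e-12:
                    moved = True
                    break
                s *= 0.5
            if moved:
                max_disp = max(max_disp, float(np.linalg.norm(cand - X[i])))
                X[i] = cand
                energies[i] = e_cand
        if sweep_log is not None:
            # (pre-descent, post-descent) energies: the constrained-descent
            # stage never raises a frame; redistribution then re-spaces frames
            sweep_log.append((pre_descent, energies.copy()))
        # redistribute to equal arc length
        seg = np.linalg.norm(np.diff(X, axis=0), axis=1)
        if seg.sum() > 1e-12 and seg.min() < 1e-4 * seg.sum():
            X = resample_path(X, n)
            energies = np.array([energy_at(X[i]) for i in range(n)])
        else:
            X_new = resample_path(X, n)
            shift = float(np.max(np.linalg.norm(X_new - X, axis=1)))
            X = X_new
            energies = np.array([energy_at(X[i]) for i in range(n)])
            max_disp = max(max_disp, shift)
        if max_disp < tol_disp:
            break
    refined = [template.with_coordinates(X[i].reshape(shape)) for i in range(n)]
    ts_index = int(np.argmax(energies))
    ts_interp = None
    if 0 < ts_index < n - 1:
        e0, e1, e2 = energies[ts_index - 1], energies[ts_index], energies[ts_index + 1]
        curv = e0 - 2.0 * e1 + e2
        if curv < -1e-12:
            ts_interp = float(e1 - (e2 - e0) ** 2 / (8.0 * curv))
    return ReactionPath(
        refined, energies, ts_index, endpoints=(-1, -1), discovery_index=-1,
        ts_energy_interp=ts_interp,
    )


# ---------------------------------------------------------------------------
# Reaction network


@dataclass
class EqRecord:
    eq_id: int
    geometry: Geometry
    energy: float
    discovery_index: int
    descriptor: np.ndarray
    expanded: bool = False


class ReactionNetwork:
    """Graph of equilibrium states (nodes) and refined reaction paths (edges)."""

    def __init__(self, descriptor=None, metadata: dict | None = None):
        self.eqs: list[EqRecord] = []
        self.paths: list[ReactionPath] = []
        self.metadata: dict = metadata or {}
        self.descriptor = descriptor

    def eq(self, eq_id: int) -> EqRecord:
        return self.eqs[eq_id]

    @property
    def n_eqs(self) -> int:
        return len(self.eqs)

    def add_eq(self, geometry: Geometry, energy: float) -> int:
        if self.descriptor is None:
            self.descriptor = default_descriptor(geometry)
        vec = self.descriptor.vector(geometry)
        eq_id = len(self.eqs)
        self.eqs.append(EqRecord(eq_id, geometry, float(energy), eq_id, vec))
        return eq_id

    def add_path(self, path: ReactionPath) -> None:
        a, b = path.endpoints
        if not (0 <= a < self.n_eqs and 0 <= b < self.n_eqs):
            raise ValueError("path endpoints must be registered EQs")
        self.paths.append(path)

    def truncate(self, k: int) -> "ReactionNetwork":
        """Sub-network of the first k paths in discovery order (and their EQs)."""
        sub = ReactionNetwork(descriptor=self.descriptor, metadata=dict(self.metadata))
        keep = sorted(self.paths, key=lambda p: p.discovery_index)[:k]
        used = sorted({e for p in keep for e in p.endpoints})
        remap = {}
        for old in used:
            rec = self.eqs[old]
            new_id = sub.add_eq(rec.geometry, rec.energy)
            remap[old] = new_id
        for p in keep:
            sub.paths.append(
                ReactionPath(
                    p.frames, p.energies, p.ts_index,
                    (remap[p.endpoints[0]], remap[p.endpoints[1]]),
                    p.discovery_index, p.flag,
                    ts_energy_interp=p.ts_energy_interp,
                )
            )
        return sub


def identify_eq(
    candidate: Geometry,
    network: ReactionNetwork,
    potential: Potential,
    tol_desc: float = 0.1,
    tol_e: float = 1.0,
    opts: MinimizerOptions | None = None,
) -> int:
    """Match a minimized candidate against the EQ catalog or register it.

    Identity criterion: descriptor-space Euclidean distance < ``tol_desc`` Å
    AND energy difference < ``tol_e`` kJ/mol.  The candidate must be a
    converged minimum of the potential.
    """
    opts = opts or MinimizerOptions()
    res = potential.evaluate(candidate)
    if float(np.max(np.abs(res.gradient))) > opts.gtol * 100:
        raise ValueError("candidate is not minimized")
    if network.descriptor is None:
        network.descriptor = default_descriptor(candidate)
    vec = network.descriptor.vector(candidate)
    for rec in network.eqs:
        if vec.shape == rec.descriptor.shape:
            if (
                float(np.linalg.norm(vec - rec.descriptor)) < tol_desc
                and abs(res.energy - rec.energy) < tol_e
            ):
                return rec.eq_id
    return network.add_eq(candidate, res.energy)


# ---------------------------------------------------------------------------
# Exploration schedules


@dataclass
class ExplorationSchedule:
    """What forces to apply per EQ and how to refine the resulting paths."""

    gammas: tuple[float, ...]
    mode: str = "auto"  # "pairs" (atomic SC-style) | "directions" (surface) | "auto"
    directions: tuple[str, ...] = ("pull", "push")
    n_directions: int = 8  # surface mode: compass directions
    p: int = 6
    max_pairs: int | None = None  # atomic mode: random subset of atom pairs
    n_frames: int = 31
    lup_sweeps: int = 100
    lup_step: float = 0.05
    max_expansions: int = 10
    tol_desc: float = 0.1
    tol_e: float = 1.0
    # Dissociation cutoff: trace endpoints relaxing above this energy are
    # treated as escaped (plateau/dissociated channels) and not registered.
    eq_energy_ceiling: float | None = None
    minimizer: MinimizerOptions = field(default_factory=MinimizerOptions)

    def biases_for(self, geometry: Geometry, rng: np.random.Generator):
        mode = self.mode
        if mode == "auto":
            mode = "directions" if geometry.n_atoms == 1 else "pairs"
        biases = []
        if mode == "directions":
            for k in range(self.n_directions):
                theta = 2.0 * np.pi * k / self.n_directions
                d = (np.cos(theta), np.sin(theta))
                for gamma in self.gammas:
                    biases.append((LinearBias(d, gamma), f"dir{k}-g{gamma:g}"))
        else:
            n = geometry.n_atoms
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            if self.max_pairs is not None and len(pairs) > self.max_pairs:
                idx = rng.choice(len(pairs), size=self.max_pairs, replace=False)
                pairs = [pairs[int(i)] for i in sorted(idx)]
            # deterministic tie-break: lexicographic on (i, j, direction, gamma)
            for i, j in pairs:
                for direction in self.directions:
                    for gamma in self.gammas:
                        spec = AfirForceSpec(gamma, direction, self.p)
                        frag = FragmentPair((i,), (j,))
                        biases.append((AfirBias(frag, spec), f"{i}-{j}-{direction}-g{gamma:g}"))
        return biases


def explore_network(
    seed: Geometry,
    potential: Potential,
    schedule: ExplorationSchedule,
    navigation: str = "none",
    seed_rng: int = 0,
    temperature: float = 300.0,
    t_navigation: float = 1.0,
) -> ReactionNetwork:
    """Systematic artificial-force exploration from a seed structure.

    Expands EQs breadth-wise (FIFO) or by kinetic navigation, applying every
    scheduled force at each expansion; every trace is refined by LUP and
    registered with its discovery index.  Fully deterministic given
    ``seed_rng``.
    """
    rng = np.random.default_rng(seed_rng)
    opts = schedule.minimizer
    seed_min, ok = minimize_geometry(potential, seed, opts)
    if not ok:
        raise ValueError("seed geometry could not be minimized")
    network = ReactionNetwork(descriptor=default_descriptor(seed_min))
    network.metadata = {
        "potential": type(potential).__name__,
        "navigation": navigation,
        "seed_rng": int(seed_rng),
        "gammas": list(schedule.gammas),
        "incomplete_traces": 0,
        "failed_endpoint_minimizations": 0,
        "escaped_traces": 0,
    }
    network.add_eq(seed_min, potential.energy(seed_min))
    expansions = 0
    while expansions < schedule.max_expansions:
        eq_rec = _select_next(network, navigation, temperature, t_navigation)
        if eq_rec is None:
            break
        for bias, label in schedule.biases_for(eq_rec.geometry, rng):
            trace = trace_afir_path(eq_rec.geometry, potential, bias, opts)
            if not trace.converged:
                network.metadata["incomplete_traces"] += 1
            endpoint, end_ok = minimize_geometry(potential, trace.frames[-1], opts)
            if not end_ok:
                network.metadata["failed_endpoint_minimizations"] += 1
                continue
            end_energy = potential.energy(endpoint)
            if schedule.eq_energy_ceiling is not None and end_energy > schedule.eq_energy_ceiling:
                network.metadata["escaped_traces"] += 1
                continue
            # truncate the walk at its first arrival in the endpoint's basin:
            # the biased walk may overshoot (e.g. climb an outer wall) after
            # passing through the product minimum
            raw = [eq_rec.geometry] + trace.frames
            end_flat = endpoint.flat()
            arrival = next(
                (k for k, f in enumerate(raw) if k > 0 and np.linalg.norm(f.flat() - end_flat) < 0.1),
                len(raw) - 1,
            )
            coords = np.stack([f.flat() for f in raw[: arrival + 1]] + [end_flat])
            if float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum()) < 1e-3:
                continue  # force too weak to move anywhere: no path
            shape = eq_rec.geometry.coordinates.shape
            sampled = resample_path(coords, schedule.n_frames)
            frames = [eq_rec.geometry.with_coordinates(r.reshape(shape)) for r in sampled]
            if trace.converged:
                try:
                    refined = lup_refine(
                        frames, potential,
                        n_sweeps=schedule.lup_sweeps, step=schedule.lup_step, opts=opts,
                    )
                except RefinementError:
                    # path contracted to a point: no reaction happened
                    network.metadata.setdefault("collapsed_paths", 0)
                    network.metadata["collapsed_paths"] += 1
                    continue
            else:
                # runaway traces are kept raw: they are excluded from kinetics
                # anyway, and plane-constrained relaxation of a pathological
                # walk is wasted work
                energies = np.array([potential.energy(f) for f in frames])
                refined = ReactionPath(frames, energies, int(np.argmax(energies)), (-1, -1), -1)
            start_id = identify_eq(
                refined.frames[0], network, potential, schedule.tol_desc, schedule.tol_e, opts
            )
            end_id = identify_eq(
                refined.frames[-1], network, potential, schedule.tol_desc, schedule.tol_e, opts
            )
            path = ReactionPath(
                refined.frames, refined.energies, refined.ts_index,
                (start_id, end_id), len(network.paths),
                "ok" if trace.converged else "incomplete",
                ts_energy_interp=refined.ts_energy_interp,
            )
            if _is_duplicate(network, path):
                continue
            network.add_path(path)
        eq_rec.expanded = True
        expansions += 1
    return network


def _select_next(network: ReactionNetwork, navigation: str, temperature: float, t: float):
    unexpanded = [e for e in network.eqs if not e.expanded]
    if not unexpanded:
        return None
    if navigation == "kinetic" and network.paths:
        from .kinetics import kinetic_navigation_select

        expanded_ids = {e.eq_id for e in network.eqs if e.expanded}
        eq_id = kinetic_navigation_select(network, temperature, t, expanded_ids)
        return network.eq(eq_id)
    return min(unexpanded, key=lambda e: e.discovery_index)


def _is_duplicate(network: ReactionNetwork, path: ReactionPath) -> bool:
    for other in network.paths:
        if other.endpoints == path.endpoints and len(other.energies) == len(path.energies):
            if np.allclose(other.energies, path.energies, atol=1e-9, rtol=0.0):
                return True
    return False


# ---------------------------------------------------------------------------
# Network JSON serialization (frames stored as extended-XYZ alongside)


def save_network(network: ReactionNetwork, out_dir: str) -> str:
    """Write network.json + eqs.xyz + paths.xyz into *out_dir*; returns json path."""
    os.makedirs(out_dir, exist_ok=True)
    eq_geoms = []
    for rec in network.eqs:
        g = rec.geometry.copy()
        g.ref_energy = rec.energy
        eq_geoms.append(g)
    write_xyz_frames(
        os.path.join(out_dir, "eqs.xyz"), eq_geoms,
        comments=[{"eq_id": rec.eq_id} for rec in network.eqs],
    )
    all_frames, comments, path_entries = [], [], []
    cursor = 0
    for i, p in enumerate(sorted(network.paths, key=lambda q: q.discovery_index)):
        for k, f in enumerate(p.frames):
            g = f.copy()
            g.ref_energy = float(p.energies[k])
            all_frames.append(g)
            comments.append({"path_id": i, "frame": k})
        path_entries.append(
            {
                "id": i,
                "from": p.endpoints[0],
                "to": p.endpoints[1],
                "barrier_fwd": p.barrier_fwd,
                "barrier_bwd": p.barrier_bwd,
                "ts_energy": p.ts_energy,
                "ts_index": p.ts_index,
                "frames_ref": f"paths.xyz#{cursor}:{cursor + len(p.frames)}",
                "discovery_index": p.discovery_index,
                "flag": p.flag,
            }
        )
        cursor += len(p.frames)
    write_xyz_frames(os.path.join(out_dir, "paths.xyz"), all_frames, comments=comments)
    doc = {
        "eqs": [
            {
                "id": rec.eq_id,
                "energy": rec.energy,
                "xyz_ref": f"eqs.xyz#{rec.eq_id}",
                "discovery_index": rec.discovery_index,
            }
            for rec in network.eqs
        ],
        "paths": path_entries,
        "metadata": network.metadata,
    }
    json_path = os.path.join(out_dir, "network.json")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return json_path


def load_network(out_dir: str) -> ReactionNetwork:
    with open(os.path.join(out_dir, "network.json")) as fh:
        doc = json.load(fh)
    eq_frames = read_xyz_frames(os.path.join(out_dir, "eqs.xyz"))
    path_frames = read_xyz_frames(os.path.join(out_dir, "paths.xyz"))
    network = ReactionNetwork(metadata=doc.get("metadata", {}))
    for entry in sorted(doc["eqs"], key=lambda e: e["id"]):
        geom, _ = eq_frames[entry["id"]]
        network.add_eq(geom, entry["energy"])
    for entry in sorted(doc["paths"], key=lambda e: e["id"]):
        ref = entry["frames_ref"].split("#")[1]
        a, b = (int(t) for t in ref.split(":"))
        frames = [g for g, _ in path_frames[a:b]]
        energies = np.array([g.ref_energy for g in frames])
        network.add_path(
            ReactionPath(
                frames, energies, entry["ts_index"],
                (entry["from"], entry["to"]), entry["discovery_index"], entry["flag"],
                ts_energy_interp=entry["ts_energy"],
            )
        )
    return network
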