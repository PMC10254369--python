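"""First-order network kinetics: Eyring rates, master equation, and contraction.

Each refined path contributes a forward and a backward elementary process.
Rate constants follow transition-state theory on the electronic-energy
barrier of the approximate transition state (transmission coefficient 1, no
vibrational partition functions — a hook for free-energy corrections is the
``ddG`` argument itself):

    k = (k_B·T / h) · exp(−ΔΔG / (R·T)),
    ΔΔG_fwd = E(TS) − E(from),  ΔΔG_bwd = E(TS) − E(to),

with barriers clamped to be no smaller than the endpoint energy difference.
Parallel paths between the same EQ pair add their rates.

The resulting master equation dp/dt = Kᵀp is stiff (rates span many orders
of magnitude).  Two solvers are provided:

* :func:`ode_oracle` — direct numerical integration with an implicit
  stiff-capable integrator; the reference route.
* :func:`rcmc_contract` — rate-constant-matrix contraction: processes much
  faster than the observation window 1/t are contracted into superstates
  whose internal populations are Boltzmann-distributed, with the rates out of
  a superstate combined by the members' equilibrium weights; the small,
  non-stiff contracted master equation is then propagated exactly by a matrix
  exponential, and superstates are expanded back to per-EQ populations.

Kinetic navigation ranks unexpanded EQs by the population the contracted
simulation assigns them, steering the search toward kinetically accessible
states first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .constants import GAS_CONSTANT_KJ, eyring_prefactor, thermal_energy


def eyring_rate(ddG: float, temperature: float) -> float:
    """Transition-state-theory rate constant (1/s) from a barrier in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if ddG < 0:
        raise ValueError("barrier must be >= 0 (clamp to the endpoint energy gap)")
    return eyring_prefactor(temperature) * float(
        np.exp(-ddG / (GAS_CONSTANT_KJ * temperature))
    )


@dataclass
class RateModel:
    temperature: float  # K
    rate_matrix: np.ndarray  # (n, n); [i, j] = k(i -> j), 1/s
    energies: np.ndarray  # per-EQ electronic energy, kJ/mol
    source: str = ""

    def __post_init__(self):
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(self.rate_matrix < 0) or not np.all(np.isfinite(self.rate_matrix)):
            raise ValueError("rates must be finite and non-negative")

    @property
    def n_states(self) -> int:
        return self.rate_matrix.shape[0]


@dataclass
class KineticState:
    populations: np.ndarray
    time: float
    contracted_map: dict = field(default_factory=dict)  # eq_id -> superstate id


def build_rate_model(network, temperature: float, skip_flagged: bool = True) -> RateModel:
    """Rate model from a reaction network's refined paths.

    Flagged (incomplete) paths are excluded; parallel unflagged paths between
    the same ordered pair sum their rates.
    """
    n = network.n_eqs
    K = np.zeros((n, n))
    energies = np.array([rec.energy for rec in network.eqs])
    used = 0
    for path in network.paths:
        if skip_flagged and path.flag != "ok":
            continue
        a, b = path.endpoints
        if a == b:
            continue  # self-loops carry no inter-state kinetics
        e_ts = path.ts_energy
        fwd = max(e_ts - energies[a], 0.0, energies[b] - energies[a])
        bwd = max(e_ts - energies[b], 0.0, energies[a] - energies[b])
        K[a, b] += eyring_rate(fwd, temperature)
        K[b, a] += eyring_rate(bwd, temperature)
        used += 1
    if used == 0:
        raise ValueError("network has no unflagged paths")
    return RateModel(temperature, K, energies, source=network.metadata.get("potential", ""))


def _generator(K: np.ndarray) -> np.ndarray:
    """Master-equation generator A with dp/dt = A p (columns sum to zero)."""
    A = K.T.copy()
    A[np.diag_indices_from(A)] -= K.sum(axis=1)
    return A


def ode_oracle(
    model: RateModel, initial, t_end: float, rtol: float = 1e-6, atol: float = 1e-9
) -> KineticState:
    """Integrate the master equation with an implicit stiff solver (Radau).

    The default tolerances resolve populations to ~1e-6; tighter absolute
    tolerances force the error control onto sub-1e-10 components of a system
    whose eigenvalues span ~12 orders of magnitude and can stall the stepper.
    """
    p0 = np.asarray(initial, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial populations must sum to 1")
    A = _generator(model.rate_matrix)
    sol = solve_ivp(
        lambda t, p: A @ p,
        (0.0, float(t_end)),
        p0,
        method="Radau",
        jac=lambda t, p: A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    p = sol.y[:, -1]
    drift = abs(p.sum() - 1.0)
    if drift > 1e-5:
        raise RuntimeError(f"stiff integration lost probability mass ({drift:.2e})")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return KineticState(p, float(t_end))


def rcmc_contract(
    model: RateModel,
    t_target: float,
    initial,
    contract_factor: float = 25.0,
    separation: float = 20.0,
) -> KineticState:
    """Rate-constant-matrix contraction at observation time ``t_target``.

    Iteratively contracts the currently fastest eligible inter-superstate
    process into a superstate (members equilibrate internally by Boltzmann
    weights at the model temperature; outgoing rates combine with those
    weights).  A process is eligible when (i) both of its directional
    effective rates exceed ``contract_factor``/t_target — a genuinely
    bidirectional fast equilibrium, so the merged pair reaches its internal
    Boltzmann ratio well inside the observation window (one-way drains and
    flows mediated by slow uphill links are left uncontracted), and (ii) it
    is at least ``separation`` times faster than any competing escape out of
    the two states being merged.  The contracted, possibly still stiff
    master equation is then propagated exactly to t_target by a matrix
    exponential and superstates expanded back with their internal Boltzmann
    weights.  Ties between equally fast processes break on the lowest state
    indices.
    """
    p0 = np.asarray(initial, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial populations must sum to 1")
    n = model.n_states
    kT = thermal_energy(model.temperature)
    boltz = np.exp(-(model.energies - model.energies.min()) / kT)
    groups: list[list[int]] = [[i] for i in range(n)]
    threshold = contract_factor / float(t_target)

    def group_weights(members):
        w = boltz[members]
        return w / w.sum()

    def effective_rates(groups):
        m = len(groups)
        Keff = np.zeros((m, m))
        for gi, mem_i in enumerate(groups):
            w = group_weights(np.array(mem_i))
            for gj, mem_j in enumerate(groups):
                if gi == gj:
                    continue
                block = model.rate_matrix[np.ix_(mem_i, mem_j)]
                Keff[gi, gj] = float(w @ block.sum(axis=1))
        return Keff

    Keff = effective_rates(groups)
    while len(groups) > 1:
        sym = np.minimum(Keff, Keff.T)  # bidirectional (equilibration) rate
        merged = False
        order = np.argsort(-sym, axis=None)
        for flat in order:
            gi, gj = np.unravel_index(int(flat), sym.shape)
            if gi >= gj:
                continue
            if sym[gi, gj] < threshold:
                break  # nothing eligible remains
            k_fast = max(Keff[gi, gj], Keff[gj, gi])
            competing = 0.0
            for g in (gi, gj):
                for h in range(len(groups)):
                    if h not in (gi, gj):
                        competing = max(competing, Keff[g, h])
            if k_fast < separation * competing:
                continue  # not cleanly separated from parallel escapes
            groups[gi] = sorted(groups[gi] + groups[gj])
            del groups[gj]
            Keff = effective_rates(groups)
            merged = True
            break
        if not merged:
            break

    # coarse initial populations and exact propagation of the slow dynamics
    P0 = np.array([p0[mem].sum() for mem in groups])
    A = _generator(Keff)
    P = expm(A * float(t_target)) @ P0
    P = np.clip(P, 0.0, None)
    P /= P.sum()
    p = np.zeros(n)
    contracted_map = {}
    for gid, mem in enumerate(groups):
        w = group_weights(np.array(mem))
        for wk, state in zip(w, mem):
            p[state] = P[gid] * wk
            contracted_map[state] = gid
    if abs(p.sum() - 1.0) > 1e-9:
        raise RuntimeError("population conservation violated after expansion")
    return KineticState(p, float(t_target), contracted_map)


def yield_report(state: KineticState, product_eq_ids) -> float:
    """Percentage of population in the product EQ set."""
    ids = sorted(set(int(i) for i in product_eq_ids))
    n = state.populations.shape[0]
    for i in ids:
        if not 0 <= i < n:
            raise ValueError(f"unknown EQ id {i}")
    return 100.0 * float(state.populations[ids].sum()) if ids else 0.0


def kinetic_navigation_select(
    network,
    temperature: float,
    t: float,
    expanded,
) -> int:
    """Unexpanded EQ with the largest contracted-simulation population.

    The simulation starts from the seed EQ (discovery index 0) on the current
    partial network; ties break on the lowest discovery index.
    """
    unexpanded = [rec.eq_id for rec in network.eqs if rec.eq_id not in set(expanded)]
    if not unexpanded:
        raise ValueError("no unexpanded EQ")
    if len(network.eqs) == 1 or not network.paths:
        return unexpanded[0]
    model = build_rate_model(network, temperature)
    p0 = np.zeros(network.n_eqs)
    p0[0] = 1.0
    state = rcmc_contract(model, t, p0)
    best = max(unexpanded, key=lambda i: (state.populations[i], -network.eq(i).discovery_index))
    return int(best)
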