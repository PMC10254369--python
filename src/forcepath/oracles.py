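"""Independent reference computations used to validate the search machinery.

These routines deliberately avoid the path-tracing/LUP code: stationary
points come from dense-grid scans polished by Newton iterations on the
analytic gradient, with Hessians from central finite differences.  They are
the cross-checks, never the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import basinhopping, minimize as scipy_minimize, root

from .geometry import Geometry, surface_point
from .potentials import Potential


def _surface_grad(potential, p):
    return potential.evaluate_xy(np.asarray(p)[None])[1][0]


def _surface_energy(potential, p):
    return float(potential.evaluate_xy(np.asarray(p)[None])[0][0])


def _surface_hessian(potential, p, h: float = 1e-5) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    H = np.zeros((2, 2))
    for k in range(2):
        dp = np.zeros(2)
        dp[k] = h
        H[:, k] = (_surface_grad(potential, p + dp) - _surface_grad(potential, p - dp)) / (2 * h)
    return 0.5 * (H + H.T)


def surface_stationary_points(
    potential,
    bounds=((-2.0, 1.5), (-1.0, 2.5)),
    n_grid: int = 60,
    gtol: float = 1e-10,
) -> dict:
    """All minima and first-order saddles of a 2-D surface inside *bounds*.

    Dense-grid seeding + Newton (vector root of the gradient) + Hessian
    classification; duplicates merged at 1e-4 resolution.
    """
    xs = np.linspace(*bounds[0], n_grid)
    ys = np.linspace(*bounds[1], n_grid)
    found: dict[tuple, tuple] = {}
    for x in xs:
        for y in ys:
            sol = root(lambda p: _surface_grad(potential, p), np.array([x, y]), tol=1e-12)
            if not sol.success:
                continue
            p = sol.x
            if not (bounds[0][0] - 0.3 <= p[0] <= bounds[0][1] + 0.3):
                continue
            if not (bounds[1][0] - 0.3 <= p[1] <= bounds[1][1] + 0.3):
                continue
            if np.linalg.norm(_surface_grad(potential, p)) > gtol:
                continue
            key = (round(float(p[0]), 4), round(float(p[1]), 4))
            if key in found:
                continue
            evals = np.linalg.eigvalsh(_surface_hessian(potential, p))
            if evals[0] > 1e-8:
                kind = "min"
            elif evals[0] < -1e-8 and evals[1] > 1e-8:
                kind = "saddle"
            else:
                continue
            found[key] = (kind, p.copy(), _surface_energy(potential, p))
    minima = sorted(
        [(v[1], v[2]) for v in found.values() if v[0] == "min"], key=lambda t: t[1]
    )
    saddles = sorted(
        [(v[1], v[2]) for v in found.values() if v[0] == "saddle"], key=lambda t: t[1]
    )
    return {"minima": minima, "saddles": saddles}


def surface_basin(potential, point, minima, max_steps: int = 20000, step: float = 5e-3) -> int:
    """Index of the minimum reached by steepest descent from *point*."""
    p = np.asarray(point, dtype=float).copy()
    for _ in range(max_steps):
        g = _surface_grad(potential, p)
        gn = np.linalg.norm(g)
        if gn < 1e-8:
            break
        p -= step * g / max(gn, 1.0)
    dists = [np.linalg.norm(p - m) for m, _ in minima]
    return int(np.argmin(dists))


def barrier_catalog(potential, stationary: dict | None = None) -> list[tuple[int, int, float]]:
    """(basin_i, basin_j, saddle_energy) for each first-order saddle, with
    basins assigned by steepest descent off the saddle along its unstable mode."""
    st = stationary or surface_stationary_points(potential)
    out = []
    for p, e in st["saddles"]:
        H = _surface_hessian(potential, p)
        evals, evecs = np.linalg.eigh(H)
        v = evecs[:, 0]
        i = surface_basin(potential, p + 1e-3 * v, st["minima"])
        j = surface_basin(potential, p - 1e-3 * v, st["minima"])
        out.append((min(i, j), max(i, j), float(e)))
    return sorted(out)


def cluster_global_minimum(
    potential: Potential,
    template: Geometry,
    n_starts: int = 400,
    spread: float = 1.5,
    rng_seed: int = 0,
) -> tuple[Geometry, float]:
    """Lowest minimum from many random-start local minimizations."""
    rng = np.random.default_rng(rng_seed)
    shape = template.coordinates.shape

    def fun(x):
        res = potential.evaluate(template.with_coordinates(x.reshape(shape)))
        return res.energy, res.gradient.reshape(-1)

    best_x, best_e = None, np.inf
    for _ in range(n_starts):
        x0 = rng.normal(scale=spread, size=shape).reshape(-1)
        out = scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                             options={"maxiter": 2000, "gtol": 1e-8, "ftol": 0.0})
        if out.fun < best_e:
            best_e, best_x = float(out.fun), out.x.copy()
    return template.with_coordinates(best_x.reshape(shape)), best_e


def cluster_basin_hopping(
    potential: Potential,
    template: Geometry,
    n_iter: int = 150,
    rng_seed: int = 0,
) -> tuple[Geometry, float]:
    """scipy basin-hopping as an independent global-minimum oracle."""
    shape = template.coordinates.shape

    def fun(x):
        res = potential.evaluate(template.with_coordinates(x.reshape(shape)))
        return res.energy, res.gradient.reshape(-1)

    x0 = template.flat()
    if np.linalg.norm(x0) < 1e-6:  # degenerate template: random start
        x0 = np.random.default_rng(rng_seed).normal(scale=1.5, size=x0.shape)
    out = basinhopping(
        fun,
        x0,
        niter=n_iter,
        minimizer_kwargs={"jac": True, "method": "L-BFGS-B"},
        seed=rng_seed,
        stepsize=0.8,
    )
    return template.with_coordinates(out.x.reshape(shape)), float(out.fun)
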