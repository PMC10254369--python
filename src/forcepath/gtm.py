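"""Generative Topographic Mapping of descriptor space.

GTM fits a smooth 2-D manifold through high-dimensional descriptor space: a
regular K×K grid of latent nodes u_k ∈ [−1, 1]² is mapped through M² radial
basis functions, y(u) = Wᵀφ(u), and each node carries an isotropic Gaussian
of inverse variance β in data space.  Training is expectation–maximization on
the resulting constrained mixture; with the Gaussian weight prior (the
``reg`` parameter) the ascended objective is the penalized log-likelihood,
which is non-decreasing by construction and recorded per iteration.

Columns are standardized internally (constant columns dropped); the mapping
is initialized from the top-2 principal directions, so iteration 0 is a
deterministic PCA reference state.

Landscapes color the latent grid by responsibility-weighted averages: mean
property per node (energy landscapes), class fraction per node (class
landscapes), or old/new occupancy (exploration-coverage landscapes, whose
summary statistic is the fraction of populated nodes holding only new
structures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp


@dataclass
class GTMModel:
    latent_grid: np.ndarray  # (K², 2) node coordinates in [−1, 1]²
    basis_centers: np.ndarray  # (M², 2)
    basis_width: float
    weights: np.ndarray  # (M²+1, D) mapping incl. bias row
    beta: float  # inverse variance
    x_mean: np.ndarray
    x_scale: np.ndarray
    kept_columns: np.ndarray  # indices into the raw descriptor
    loglik_trace: list = field(default_factory=list)
    training_meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.latent_grid.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        expected = self.training_meta.get("n_input_columns", int(self.kept_columns.max()) + 1)
        if X.ndim != 2 or X.shape[1] != expected:
            raise ValueError("descriptor dimension mismatch")
        Xk = X[:, self.kept_columns]
        return (Xk - self.x_mean) / self.x_scale

    def node_images(self) -> np.ndarray:
        return _phi(self.latent_grid, self.basis_centers, self.basis_width) @ self.weights

    def map_latent(self, U: np.ndarray) -> np.ndarray:
        """Continuous manifold image y(u) for arbitrary latent points."""
        return _phi(np.atleast_2d(U), self.basis_centers, self.basis_width) @ self.weights

    def to_json(self) -> str:
        doc = {
            "format_version": 1,
            "latent_grid": self.latent_grid.tolist(),
            "basis_centers": self.basis_centers.tolist(),
            "basis_width": self.basis_width,
            "weights": self.weights.tolist(),
            "beta": self.beta,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "loglik_trace": list(self.loglik_trace),
            "training_meta": self.training_meta,
        }
        return json.dumps(doc, sort_keys=True)


@dataclass
class Landscape:
    node_xy: np.ndarray  # (K², 2)
    node_values: np.ndarray  # mean property / class fraction / coverage code
    node_density: np.ndarray  # cumulated responsibility per node
    kind: str
    extra: dict = field(default_factory=dict)


def _phi(U: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    d2 = ((U[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-0.5 * d2 / width**2)
    return np.hstack([phi, np.ones((U.shape[0], 1))])


def _square_grid(side: int) -> np.ndarray:
    xs = np.linspace(-1.0, 1.0, side)
    gx, gy = np.meshgrid(xs, xs, indexing="xy")
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def fit_gtm(
    X: np.ndarray,
    K: int = 15,
    M: int = 8,
    width: float = 1.0,
    reg: float = 1e-3,
    n_iter: int = 100,
    rng_seed: int = 0,
    tol: float = 1e-7,
) -> GTMModel:
    """Fit a GTM by (MAP) expectation–maximization.

    ``K`` is the latent grid side (K² nodes), ``M`` the RBF-center grid side
    (M² centers) with common width ``width`` × center spacing, ``reg`` the
    Gaussian weight-prior strength.  Initialization is deterministic (PCA);
    the seed is kept for reproducibility metadata and any future stochastic
    variant.  The recorded objective trace is non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix must be finite")
    std = X.std(axis=0)
    kept = np.where(std > 1e-12)[0]
    if kept.size < 2:
        raise ValueError("degenerate data: fewer than 2 informative columns")
    x_mean = X[:, kept].mean(axis=0)
    x_scale = std[kept]
    Xs = (X[:, kept] - x_mean) / x_scale
    N, D = Xs.shape

    latent = _square_grid(K)
    centers = _square_grid(M)
    spacing = 2.0 / (M - 1) if M > 1 else 2.0
    sigma = width * spacing
    Phi = _phi(latent, centers, sigma)

    # PCA initialization (deterministic sign convention)
    cov = Xs.T @ Xs / N
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    targets = latent * np.sqrt(np.maximum(evals[:2], 1e-12))  # (K², 2)
    Y_init = targets @ evecs[:, :2].T
    W, *_ = np.linalg.lstsq(Phi, Y_init, rcond=None)
    Y = Phi @ W
    inter = np.linalg.norm(np.diff(Y[: K], axis=0), axis=1)
    beta_inv = max(
        float(evals[2]) if D > 2 else 0.0,
        float(np.mean(inter) ** 2) / 4.0 if inter.size else 1e-2,
        1e-6,
    )
    beta = 1.0 / beta_inv

    def objective(log_post_unnorm):
        loglik = float(logsumexp(log_post_unnorm, axis=1).sum())
        return loglik - 0.5 * reg * float((W**2).sum())

    trace: list[float] = []
    model_meta = {
        "K": K, "M": M, "width": width, "reg": reg, "rng_seed": rng_seed,
        "n_input_columns": X.shape[1],
    }
    for iteration in range(max(n_iter, 0)):
        d2 = ((Xs[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
        log_unnorm = (
            -0.5 * beta * d2 + 0.5 * D * np.log(beta / (2.0 * np.pi)) - np.log(latent.shape[0])
        )
        trace.append(objective(log_unnorm))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            break
        R = np.exp(log_unnorm - logsumexp(log_unnorm, axis=1, keepdims=True))
        G = R.sum(axis=0)
        A = Phi.T * G @ Phi + (reg / beta) * np.eye(Phi.shape[1])
        B = Phi.T @ (R.T @ Xs)
        W = np.linalg.solve(A, B)
        Y = Phi @ W
        d2 = ((Xs[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
        beta = N * D / float((R * d2).sum())
    # final objective for the updated parameters
    d2 = ((Xs[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    log_unnorm = (
        -0.5 * beta * d2 + 0.5 * D * np.log(beta / (2.0 * np.pi)) - np.log(latent.shape[0])
    )
    trace.append(objective(log_unnorm))
    model_meta["iterations"] = len(trace) - 1
    model_meta["final_loglik"] = trace[-1]
    return GTMModel(
        latent, centers, sigma, W, float(beta), x_mean, x_scale, kept,
        loglik_trace=trace, training_meta=model_meta,
    )


def responsibilities(model: GTMModel, X: np.ndarray) -> np.ndarray:
    """Row-stochastic posterior node probabilities for each data row."""
    Xs = model.standardize(X)
    Y = model.node_images()
    d2 = ((Xs[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    log_unnorm = -0.5 * model.beta * d2
    return np.exp(log_unnorm - logsumexp(log_unnorm, axis=1, keepdims=True))


def project(model: GTMModel, X: np.ndarray) -> np.ndarray:
    """Responsibility-weighted mean latent position per data row."""
    return responsibilities(model, X) @ model.latent_grid


def reconstruction_rms(
    model: GTMModel, X: np.ndarray, n_newton: int = 25, fine_grid: int = 45
) -> float:
    """RMS orthogonal reconstruction error (standardized units).

    For each point, the nearest point on the continuous manifold surface is
    located (fine latent grid + damped Gauss–Newton) and the residual is
    projected onto the orthogonal complement of the manifold's tangent plane
    there — the analogue of PCA's orthogonal reconstruction error.  In-plane
    mismatch (how densely the manifold tiles its own surface) is a density
    property and deliberately not measured here.
    """
    Xs = model.standardize(X)
    fine = _square_grid(fine_grid) * 1.1  # slight overhang past the node grid
    Yf = model.map_latent(fine)
    starts = np.argmin(((Xs[:, None, :] - Yf[None, :, :]) ** 2).sum(axis=2), axis=1)

    def image(u):
        return (_phi(u[None, :], model.basis_centers, model.basis_width) @ model.weights)[0]

    total = 0.0
    for n in range(Xs.shape[0]):
        u = fine[starts[n]].copy()
        x = Xs[n]
        err = float(((x - image(u)) ** 2).sum())
        for _ in range(n_newton):
            phi_u = _phi(u[None, :], model.basis_centers, model.basis_width)
            # dφ_m/du = φ_m · (c_m − u)/σ²  (bias column has zero derivative)
            diffc = model.basis_centers - u[None, :]
            dphi = phi_u[0, :-1, None] * diffc / model.basis_width**2  # (M², 2)
            J = model.weights[:-1].T @ dphi  # (D, 2)
            r = x - image(u)
            JtJ = J.T @ J + 1e-10 * np.eye(2)
            du = np.linalg.solve(JtJ, J.T @ r)
            norm = float(np.linalg.norm(du))
            if norm < 1e-13:
                break
            if norm > 0.25:  # keep the step inside the basis support
                du *= 0.25 / norm
            # damped acceptance: only move downhill
            step = 1.0
            for _ in range(20):
                u_try = np.clip(u + step * du, -1.5, 1.5)
                err_try = float(((x - image(u_try)) ** 2).sum())
                if err_try < err:
                    u, err = u_try, err_try
                    break
                step *= 0.5
            else:
                break
        # orthogonal component of the residual w.r.t. the tangent plane at u
        phi_u = _phi(u[None, :], model.basis_centers, model.basis_width)
        diffc = model.basis_centers - u[None, :]
        dphi = phi_u[0, :-1, None] * diffc / model.basis_width**2
        J = model.weights[:-1].T @ dphi
        r = x - image(u)
        coef, *_ = np.linalg.lstsq(J, r, rcond=None)
        r_orth = r - J @ coef
        total += float((r_orth**2).sum())
    return float(np.sqrt(total / Xs.shape[0]))


EMPTY_NODE_DENSITY = 1e-3


def property_landscape(model: GTMModel, X: np.ndarray, values) -> Landscape:
    """Responsibility-weighted mean property per latent node."""
    v = np.asarray(values, dtype=float)
    if v.shape[0] != np.asarray(X).shape[0]:
        raise ValueError("values length must match data rows")
    R = responsibilities(model, X)
    density = R.sum(axis=0)
    node_values = np.full(model.n_nodes, np.nan)
    populated = density > EMPTY_NODE_DENSITY
    node_values[populated] = (R.T @ v)[populated] / density[populated]
    return Landscape(model.latent_grid, node_values, density, "energy")


def class_landscape(model: GTMModel, X: np.ndarray, labels, positive=None) -> Landscape:
    """Per-node fraction of the positive class (responsibility-weighted)."""
    labels = np.asarray(labels)
    if positive is None:
        positive = sorted(set(labels.tolist()))[0]
    ind = (labels == positive).astype(float)
    land = property_landscape(model, X, ind)
    land.kind = "class"
    land.extra["positive"] = positive
    return land


def coverage_landscape(model: GTMModel, X_old: np.ndarray, X_new: np.ndarray) -> Landscape:
    """Old/new occupancy per node for exploration-coverage analysis.

    Node codes: 0 empty, 1 old-only, 2 new-only, 3 mixed.  The summary
    statistic ``new_only_fraction`` is the share of populated nodes populated
    exclusively by new structures.
    """
    d_old = (
        responsibilities(model, X_old).sum(axis=0)
        if np.asarray(X_old).size
        else np.zeros(model.n_nodes)
    )
    d_new = (
        responsibilities(model, X_new).sum(axis=0)
        if np.asarray(X_new).size
        else np.zeros(model.n_nodes)
    )
    has_old = d_old > EMPTY_NODE_DENSITY
    has_new = d_new > EMPTY_NODE_DENSITY
    codes = np.zeros(model.n_nodes)
    codes[has_old & ~has_new] = 1.0
    codes[~has_old & has_new] = 2.0
    codes[has_old & has_new] = 3.0
    populated = int((has_old | has_new).sum())
    new_only = int((~has_old & has_new).sum())
    return Landscape(
        model.latent_grid, codes, d_old + d_new, "coverage",
        extra={
            "new_only_fraction": new_only / populated if populated else 0.0,
            "density_old": d_old,
            "density_new": d_new,
        },
    )


def landscape_to_csv(landscape: Landscape, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "node_x": landscape.node_xy[:, 0],
            "node_y": landscape.node_xy[:, 1],
            "value": landscape.node_values,
            "density": landscape.node_density,
            "kind": landscape.kind,
        }
    ).to_csv(path, index=False)
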