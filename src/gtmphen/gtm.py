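"""Generative Topographic Mapping (GTM), implemented from scratch.

The model assumes the observed data ``x_n`` (rows of an ``N x D`` matrix)
were generated from a 2-D latent space through a smooth nonlinear mapping.
The latent prior is a uniform sum of delta functions over a regular ``k x k``
grid of nodes ``u_l`` spanning ``[-1, 1]^2``::

    p(u) = (1/K) sum_l delta(u - u_l),        K = k**2

Each node is pushed through an RBF-parameterised mapping
``y(u; W) = W @ phi(u)`` into data space, where it becomes the centre of a
spherical Gaussian with precision ``beta`` (inverse variance).  The data
density is therefore a constrained Gaussian mixture::

    p(x | W, beta) = (1/K) sum_l N(x | y(u_l; W), beta^{-1} I)

and the log-likelihood ``L(W, beta) = sum_n ln p(x_n | W, beta)`` is
maximised by EM.  A weight-decay prior on ``W`` with strength ``lambda``
penalises the objective by ``-(lambda/2) ||W||_F^2`` and enters the M-step
normal equations as ``(lambda/beta) I``.

Node indexing is row-major from the top-left corner of the lattice, so map
layers built on top of the model are bit-comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "LatentGrid",
    "RBFBasis",
    "GTMModel",
    "Responsibilities",
    "FitTrace",
    "build_latent_grid",
    "build_rbf_basis",
    "initialize",
    "e_step",
    "m_step",
    "fit",
    "reference_vectors",
    "assign_micro",
    "penalised_objective",
    "save_model",
    "load_model",
]

_BETA_INV_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentGrid:
    """Regular square lattice of latent nodes over [-1, 1]^2.

    ``nodes`` has shape (K, 2), row-major from the top-left corner: node 0 is
    (-1, +1), the last node is (+1, -1).
    """

    side: int
    nodes: np.ndarray

    @property
    def K(self) -> int:
        return self.nodes.shape[0]

    def node_row_col(self, index: int) -> tuple[int, int]:
        return divmod(index, self.side)


@dataclass(frozen=True)
class RBFBasis:
    """Gaussian radial basis on the latent square, plus a constant bias column.

    ``phi`` is the K x (M+1) design matrix evaluated at the latent nodes:
    ``phi[l, j] = exp(-||u_l - c_j||^2 / (2 width^2))`` for the M RBF columns
    and 1 for the final bias column.
    """

    centres: np.ndarray          # (M, 2)
    width: float
    phi: np.ndarray              # (K, M+1)

    @property
    def M(self) -> int:
        return self.centres.shape[0]

    def design(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the basis at arbitrary latent points, shape (n, M+1)."""
        points = np.atleast_2d(points)
        if self.M:
            d2 = cdist(points, self.centres, "sqeuclidean")
            act = np.exp(-d2 / (2.0 * self.width**2))
        else:
            act = np.empty((points.shape[0], 0))
        return np.hstack([act, np.ones((points.shape[0], 1))])


@dataclass
class GTMModel:
    grid: LatentGrid
    basis: RBFBasis
    W: np.ndarray                # (D, M+1)
    beta: float                  # noise PRECISION of the spherical components
    lam: float = 1.0             # weight-decay strength

    @property
    def D(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.grid.K


@dataclass
class Responsibilities:
    """N x K posterior membership matrix: R[n, l] is the probability that
    node l generated subject n.  Rows are probability vectors."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)


@dataclass
class FitTrace:
    objective_per_iteration: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _square_lattice(side: int) -> np.ndarray:
    """Row-major lattice over [-1,1]^2, top-left first; side=1 gives (0,0)."""
    if side == 1:
        return np.array([[0.0, 0.0]])
    coords = np.linspace(-1.0, 1.0, side)
    xx, yy = np.meshgrid(coords, coords[::-1])  # rows top->bottom
    return np.column_stack([xx.ravel(), yy.ravel()])


def build_latent_grid(side: int) -> LatentGrid:
    """Regular ``side x side`` grid of latent nodes; corners at (+-1, +-1)."""
    if side < 2:
        raise ValueError(f"latent grid side must be >= 2, got {side}")
    return LatentGrid(side=side, nodes=_square_lattice(side))


def build_rbf_basis(
    grid: LatentGrid, rbf_side: int, width_factor: float = 1.0
) -> RBFBasis:
    """Gaussian RBF centres on an ``rbf_side x rbf_side`` lattice over [-1,1]^2.

    The common width is ``width_factor`` times the spacing between adjacent
    centres.  ``rbf_side=0`` yields a bias-only (constant) basis, useful for
    degenerate single-Gaussian checks.
    """
    if rbf_side < 0:
        raise ValueError("rbf_side must be >= 0")
    if width_factor <= 0:
        raise ValueError("width_factor must be positive")
    if rbf_side == 0:
        centres = np.empty((0, 2))
        width = 1.0
    else:
        centres = _square_lattice(rbf_side)
        spacing = 2.0 / (rbf_side - 1) if rbf_side > 1 else 2.0
        width = width_factor * spacing
    basis = RBFBasis(centres=centres, width=float(width), phi=np.empty((0, 0)))
    phi = basis.design(grid.nodes)
    return RBFBasis(centres=centres, width=float(width), phi=phi)


def _lattice_neighbour_pairs(side: int) -> np.ndarray:
    """Index pairs of horizontally/vertically adjacent lattice nodes."""
    pairs = []
    for r in range(side):
        for c in range(side):
            l = r * side + c
            if c + 1 < side:
                pairs.append((l, l + 1))
            if r + 1 < side:
                pairs.append((l, l + side))
    return np.array(pairs, dtype=int)


def initialize(
    data: np.ndarray,
    grid: LatentGrid,
    basis: RBFBasis,
    method: str = "pca",
    seed: int = 0,
    lam: float = 1.0,
) -> GTMModel:
    """Initial weights and noise precision.

    ``pca`` (default): W solves the least-squares problem mapping the basis
    onto the plane of the first two principal components, with the latent
    lattice coordinates scaled to the corresponding PC score spread;
    ``beta^{-1}`` starts at the larger of the third principal eigenvalue and
    half the mean squared distance between neighbouring initial reference
    vectors.  ``random``: seeded standard-normal W scaled by 0.1, beta = 1.
    """
    data = np.asarray(data, dtype=float)
    N, D = data.shape
    if method == "random":
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((D, basis.phi.shape[1])) * 0.1
        return GTMModel(grid=grid, basis=basis, W=W, beta=1.0, lam=lam)
    if method != "pca":
        raise ValueError(f"unknown init method {method!r}")
    if D < 2:
        raise ValueError("pca initialisation requires D >= 2")
    mean = data.mean(axis=0)
    Xc = data - mean
    cov = (Xc.T @ Xc) / N
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError(
            "data are effectively rank-1; pca initialisation is degenerate "
            "- use method='random'"
        )
    scale = np.sqrt(evals[:2])
    targets = mean + (grid.nodes * scale) @ evecs[:, :2].T       # (K, D)
    W, *_ = np.linalg.lstsq(basis.phi, targets, rcond=None)
    W = W.T                                                       # (D, M+1)
    Y = basis.phi @ W.T
    pairs = _lattice_neighbour_pairs(grid.side)
    if pairs.size:
        nn2 = np.mean(np.sum((Y[pairs[:, 0]] - Y[pairs[:, 1]]) ** 2, axis=1))
    else:
        nn2 = 1.0
    third = evals[2] if D > 2 else 0.0
    beta_inv = max(third, 0.5 * nn2, _BETA_INV_FLOOR)
    return GTMModel(grid=grid, basis=basis, W=W, beta=1.0 / beta_inv, lam=lam)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def reference_vectors(model: GTMModel) -> np.ndarray:
    """K x D matrix whose row l is y(u_l; W) = W @ phi(u_l)."""
    return model.basis.phi @ model.W.T


def e_step(model: GTMModel, data: np.ndarray) -> tuple[Responsibilities, float]:
    """Posterior responsibilities and the data log-likelihood.

    ``R[n, l] \\propto exp(-beta/2 ||x_n - y_l||^2)`` with rows normalised;
    the log-likelihood sums ``ln[(1/K) sum_l (beta/2pi)^{D/2}
    exp(-beta/2 ||x_n - y_l||^2)]`` over subjects, evaluated with
    log-sum-exp stabilisation.
    """
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("data must be finite (no NaN/inf); preprocess first")
    Y = reference_vectors(model)
    D = data.shape[1]
    d2 = cdist(data, Y, "sqeuclidean")                 # (N, K)
    log_kernel = -0.5 * model.beta * d2
    lse = logsumexp(log_kernel, axis=1)
    R = np.exp(log_kernel - lse[:, None])
    const = 0.5 * D * (np.log(model.beta) - np.log(2.0 * np.pi)) - np.log(model.K)
    ll = float(np.sum(lse + const))
    return Responsibilities(R=R), ll


def penalised_objective(model: GTMModel, log_likelihood: float) -> float:
    """Log-likelihood minus the weight-decay penalty (lambda/2)||W||^2."""
    return log_likelihood - 0.5 * model.lam * float(np.sum(model.W**2))


def m_step(model: GTMModel, data: np.ndarray, resp: Responsibilities) -> GTMModel:
    """One maximisation step: update W by regularised weighted least squares,
    then beta from the responsibility-weighted mean squared residual.

    Solves ``(Phi^T G Phi + (lambda/beta) I) W_new^T = Phi^T R^T X`` with
    ``G = diag`` of the column sums of R, then
    ``beta_new^{-1} = (1/(N D)) sum_{n,l} R[n,l] ||x_n - y_l^new||^2``,
    floored to avoid divergence on degenerate data.
    """
    data = np.asarray(data, dtype=float)
    R = resp.R
    N, D = data.shape
    phi = model.basis.phi
    G = R.sum(axis=0)                                  # (K,)
    A = phi.T @ (phi * G[:, None])
    if model.lam > 0:
        A = A + (model.lam / model.beta) * np.eye(A.shape[0])
    B = phi.T @ (R.T @ data)
    try:
        if model.lam == 0 and np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        Wt = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular M-step normal matrix; use a regularisation weight lambda > 0"
        ) from err
    W_new = Wt.T
    Y = phi @ Wt
    d2 = cdist(data, Y, "sqeuclidean")
    beta_inv = float(np.sum(R * d2)) / (N * D)
    beta_inv = max(beta_inv, _BETA_INV_FLOOR)
    return GTMModel(grid=model.grid, basis=model.basis, W=W_new,
                    beta=1.0 / beta_inv, lam=model.lam)


def fit(
    data: np.ndarray,
    side: int = 15,
    rbf_side: int = 14,
    lam: float = 1.0,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    width_factor: float = 1.0,
    init: str = "pca",
) -> tuple[GTMModel, FitTrace]:
    """Fit a GTM by EM on complete, standardized data.

    Defaults follow the selected configuration of the motivating analysis:
    a 15 x 15 latent grid (225 nodes), 196 RBFs on a 14 x 14 grid, and
    regularisation weight 1.  Iterates until the relative change in the
    penalised objective falls below ``tol`` or ``max_iter`` EM updates have
    run; non-convergence is reported on the trace, not raised.
    """
    data = np.asarray(data, dtype=float)
    grid = build_latent_grid(side)
    basis = build_rbf_basis(grid, rbf_side, width_factor)
    try:
        model = initialize(data, grid, basis, method=init, seed=seed, lam=lam)
    except ValueError:
        if init != "pca":
            raise
        model = initialize(data, grid, basis, method="random", seed=seed, lam=lam)
    trace = FitTrace(seed=seed)
    resp, ll = e_step(model, data)
    prev = penalised_objective(model, ll)
    trace.objective_per_iteration.append(prev)
    for it in range(1, max_iter + 1):
        model = m_step(model, data, resp)
        resp, ll = e_step(model, data)
        obj = penalised_objective(model, ll)
        trace.objective_per_iteration.append(obj)
        trace.iterations = it
        if abs(obj - prev) < tol * (abs(prev) + 1e-12):
            trace.converged = True
            break
        prev = obj
    return model, trace


def assign_micro(model: GTMModel, data: np.ndarray) -> np.ndarray:
    """Hard micro-cluster labels: the argmax-responsibility node per subject
    (ties broken by the lowest node index)."""
    resp, _ = e_step(model, data)
    return np.argmax(resp.R, axis=1)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_model(model: GTMModel, path: str | Path, extra: dict | None = None) -> None:
    """Serialise a model (plus optional extras, e.g. standardisation
    parameters) to a single JSON file; round-trips bit-exactly."""
    payload = {
        "side": model.grid.side,
        "rbf_side": int(np.sqrt(model.basis.M)) if model.basis.M else 0,
        "width": model.basis.width,
        "lambda": model.lam,
        "beta": model.beta,
        "W": model.W.tolist(),
    }
    if extra:
        payload["extra"] = extra
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[GTMModel, dict]:
    payload = json.loads(Path(path).read_text())
    side = payload["side"]
    grid = LatentGrid(side=side, nodes=_square_lattice(side)) if side == 1 \
        else build_latent_grid(side)
    rbf_side = payload["rbf_side"]
    if rbf_side == 0:
        centres = np.empty((0, 2))
    else:
        centres = _square_lattice(rbf_side)
    basis = RBFBasis(centres=centres, width=payload["width"], phi=np.empty((0, 0)))
    basis = RBFBasis(centres=centres, width=payload["width"],
                     phi=basis.design(grid.nodes))
    model = GTMModel(grid=grid, basis=basis, W=np.asarray(payload["W"], dtype=float),
                     beta=payload["beta"], lam=payload["lambda"])
    return model, payload.get("extra", {})
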