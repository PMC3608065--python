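"""Log-barrier interior-point solvers for non-negative fitting.

Three problems share the machinery:

* non-negative least squares      min_{b>=0} ||y - Phi b||_2^2
* non-negative least absolute
  deviation (via an LP)           min_{b>=0} ||y - Phi b||_1
* weighted non-negative lasso     min_{b>=0} ||y - Phi b||_2^2 + lam * w'b

Inequality constraints are replaced by -log barrier terms of decreasing
weight 1/gamma; each barrier stage is minimized by Newton's method.  The
Newton systems are symmetric positive definite with the sparsity of the
template Gram matrix, which — after ordering columns by support position —
is a band matrix; they are solved by banded Cholesky factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky_banded, cho_solve_banded

__all__ = [
    "SolverConfig",
    "FitResult",
    "SolverError",
    "nnls_logbarrier",
    "nnlad_logbarrier",
    "weighted_nn_lasso",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Barrier schedule and Newton-iteration controls.

    gamma0/mult/gamma_max define the barrier weight sequence (about eight
    stages at the defaults); newton_tol is a relative gradient-norm
    tolerance per stage.  factorization selects banded (default) or dense
    Cholesky for the Newton systems — both give identical solutions, the
    banded path exploits the template band structure.
    """

    gamma0: float = 10.0
    mult: float = 10.0
    gamma_max: float = 1e8
    newton_tol: float = 1e-8
    max_newton: int = 100
    ls_shrink: float = 0.5
    ls_decrease: float = 1e-4
    init_scale: float = 1e-3
    kkt_tol: float = 1e-6
    factorization: str = "banded"  # or "dense"

    def __post_init__(self):
        if not (self.gamma0 > 0 and self.mult > 1 and self.gamma_max > self.gamma0):
            raise ValueError("require gamma0 > 0, mult > 1, gamma_max > gamma0")


@dataclass
class FitResult:
    """Non-negative fit: coefficients, objective on the original scale
    (||r||_q^q, plus the penalty for the lasso), and a KKT certificate."""

    beta: np.ndarray
    objective: float
    q: int
    kkt_residual: float
    stages: int
    converged: bool
    lam: float = 0.0
    stage_objectives: list = None


def _as_csc(phi) -> sp.csc_matrix:
    if hasattr(phi, "columns") and sp.issparse(getattr(phi, "columns", None)):
        phi = phi.columns
    if sp.issparse(phi):
        return phi.tocsc()
    return sp.csc_matrix(np.asarray(phi, dtype=float))


def _validate(phi: sp.csc_matrix, y: np.ndarray):
    if not np.all(np.isfinite(phi.data)) or not np.all(np.isfinite(y)):
        raise SolverError("non-finite values in the design or data")
    if phi.data.size and phi.data.min() < 0:
        raise SolverError("the template design must be non-negative")
    if phi.shape[0] != y.size:
        raise SolverError("design and data dimensions disagree")
    norms = np.sqrt(np.asarray(phi.multiply(phi).sum(axis=0)).ravel())
    if np.any(norms == 0):
        raise SolverError("design contains zero-norm columns")


class _SupportOrder:
    """Column permutation by support start, plus the resulting bandwidth of
    the Gram matrix (columns with contiguous supports overlap only within
    the band)."""

    def __init__(self, phi: sp.csc_matrix):
        p = phi.shape[1]
        starts = np.empty(p)
        ends = np.empty(p)
        for j in range(p):
            rows = phi.indices[phi.indptr[j] : phi.indptr[j + 1]]
            starts[j] = rows[0]
            ends[j] = rows[-1]
        self.perm = np.lexsort((ends, starts))
        self.inv = np.argsort(self.perm)
        s, e = starts[self.perm], ends[self.perm]
        bw = 0
        # supports are intervals: column i overlaps j > i while s[j] <= e[i]
        jmax = np.searchsorted(s, e, side="right") - 1
        bw = int(np.max(jmax - np.arange(p))) if p else 0
        self.bandwidth = max(bw, 0)


class _SPDSolver:
    """Solve (G_like + diag(d)) x = b by banded or dense Cholesky, where
    G_like has the (permuted) Gram sparsity."""

    def __init__(self, phi: sp.csc_matrix, config: SolverConfig):
        self.order = _SupportOrder(phi)
        self.phi_p = phi[:, self.order.perm].tocsc()
        self.p = phi.shape[1]
        self.mode = config.factorization
        if self.mode not in ("banded", "dense"):
            raise ValueError(f"unknown factorization mode {self.mode!r}")

    def gram(self, row_weights: np.ndarray | None = None) -> sp.csc_matrix:
        if row_weights is None:
            return (self.phi_p.T @ self.phi_p).tocsc()
        w = sp.diags(row_weights)
        return (self.phi_p.T @ (w @ self.phi_p)).tocsc()

    def _to_banded(self, H: sp.csc_matrix) -> np.ndarray:
        k = self.order.bandwidth
        ab = np.zeros((k + 1, self.p))
        coo = H.tocoo()
        mask = coo.row >= coo.col
        r, c, v = coo.row[mask], coo.col[mask], coo.data[mask]
        ab[r - c, c] = v
        return ab

    def solve(self, G: sp.csc_matrix, diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """Solve (G + diag) x = rhs; rhs/x are in permuted column order."""
        if self.mode == "dense":
            H = G.toarray()
            H[np.diag_indices_from(H)] += diag
            try:
                return cho_solve(cho_factor(H, lower=True), rhs)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-12 * np.trace(H) / self.p
                return cho_solve(cho_factor(H, lower=True), rhs)
        ab = self._to_banded(G)
        ab[0, :] += diag
        try:
            cb = cholesky_banded(ab, lower=True)
        except np.linalg.LinAlgError:
            ab[0, :] += 1e-12 * ab[0, :].sum() / self.p
            try:
                cb = cholesky_banded(ab, lower=True)
            except np.linalg.LinAlgError as exc:
                raise SolverError("Cholesky factorization failed") from exc
        return cho_solve_banded((cb, True), rhs)

    def permute(self, v: np.ndarray) -> np.ndarray:
        return v[self.order.perm]

    def unpermute(self, v: np.ndarray) -> np.ndarray:
        return v[self.order.inv]


def _barrier_qp(
    phi: sp.csc_matrix, y: np.ndarray, lin: np.ndarray, config: SolverConfig
) -> tuple[np.ndarray, int]:
    """Minimize 0.5||y - Phi b||^2 + lin'b over b >= 0 by the log-barrier
    method; returns (beta, stages)."""
    solver = _SPDSolver(phi, config)
    A = solver.phi_p
    aty = A.T @ y
    lin_p = solver.permute(lin)
    G = solver.gram()
    p = phi.shape[1]
    scale = max(float(np.max(np.abs(aty))), 1e-12)
    beta = np.full(p, scale * config.init_scale)
    gamma = config.gamma0
    stages = 0
    stage_objectives = []
    while True:
        for _ in range(config.max_newton):
            r = A @ beta - y
            grad = A.T @ r + lin_p - 1.0 / (gamma * beta)
            if np.linalg.norm(grad, np.inf) <= config.newton_tol * max(scale, 1.0):
                break
            d = solver.solve(G, 1.0 / (gamma * beta**2), -grad)
            # step to the boundary, then Armijo backtracking
            neg = d < 0
            tmax = 1.0
            if np.any(neg):
                tmax = min(1.0, 0.99 * float(np.min(-beta[neg] / d[neg])))
            f0 = 0.5 * float(r @ r) + float(lin_p @ beta) - np.sum(np.log(beta)) / gamma
            gd = float(grad @ d)
            t = tmax
            while t > 1e-16:
                b1 = beta + t * d
                r1 = A @ b1 - y
                f1 = 0.5 * float(r1 @ r1) + float(lin_p @ b1) - np.sum(np.log(b1)) / gamma
                if f1 <= f0 + config.ls_decrease * t * gd:
                    break
                t *= config.ls_shrink
            beta = beta + t * d
        stages += 1
        r = A @ beta - y
        stage_objectives.append(float(r @ r) + 2.0 * float(lin_p @ beta))
        if gamma >= config.gamma_max:
            break
        gamma = min(gamma * config.mult, config.gamma_max)
    return solver.unpermute(beta), stages, stage_objectives


def nnls_logbarrier(phi, y, config: SolverConfig | None = None) -> FitResult:
    """Non-negative least squares by the log-barrier interior-point method.

    Reports the objective ||y - Phi beta||_2^2 and a KKT certificate
    (dual feasibility Phi'(Phi b - y) >= -tol and complementarity
    b_j * grad_j <= tol, both relative to the data scale).
    """
    config = config or SolverConfig()
    A = _as_csc(phi)
    y = np.asarray(y, dtype=float)
    _validate(A, y)
    beta, stages, stage_objs = _barrier_qp(A, y, np.zeros(A.shape[1]), config)
    r = A @ beta - y
    grad = A.T @ r
    scale = max(float(np.max(np.abs(A.T @ y))), 1e-12)
    kkt = max(float(np.max(-grad, initial=0.0)), float(np.max(beta * np.abs(grad)))) / scale
    return FitResult(
        beta=beta,
        objective=float(r @ r),
        q=2,
        kkt_residual=kkt,
        stages=stages,
        converged=kkt <= config.kkt_tol,
        stage_objectives=stage_objs,
    )


def weighted_nn_lasso(phi, y, lam: float, weights=None, config: SolverConfig | None = None) -> FitResult:
    """Weighted non-negative lasso min_{b>=0} ||y-Phi b||^2 + lam * w'b.

    The linear penalty only shifts the gradient of the NNLS barrier
    problem; lam = 0 reduces exactly to ``nnls_logbarrier``.  Column
    weights (e.g. the truncated local noise level at each anchor) rescale
    the amount of l1-regularization.
    """
    config = config or SolverConfig()
    A = _as_csc(phi)
    y = np.asarray(y, dtype=float)
    _validate(A, y)
    if lam < 0:
        raise SolverError("lam must be >= 0")
    p = A.shape[1]
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    if w.size != p or np.any(w <= 0):
        raise SolverError("weights must be positive, one per column")
    # minimizing 0.5||r||^2 + (lam/2) w'b has the same argmin as ||r||^2 + lam w'b
    beta, stages, stage_objs = _barrier_qp(A, y, 0.5 * lam * w, config)
    r = A @ beta - y
    grad = 2.0 * (A.T @ r) + lam * w
    scale = max(float(np.max(np.abs(A.T @ y))), 1e-12)
    kkt = max(float(np.max(-grad, initial=0.0)), float(np.max(beta * np.abs(grad)))) / scale
    return FitResult(
        beta=beta,
        objective=float(r @ r) + lam * float(w @ beta),
        q=2,
        kkt_residual=kkt,
        stages=stages,
        converged=kkt <= config.kkt_tol,
        lam=float(lam),
        stage_objectives=stage_objs,
    )


def nnlad_logbarrier(phi, y, config: SolverConfig | None = None) -> FitResult:
    """Non-negative least absolute deviation via its LP reformulation.

    min 1'r  subject to  Phi b - y + r >= 0,  y - Phi b + r >= 0,
    r >= 0, b >= 0, solved with log-barrier terms on all constraints.  The
    (r, b) Newton system is reduced by block elimination: the r-block is
    diagonal, so only a system with the scaled-Gram sparsity remains for
    the b-direction, solved by banded Cholesky.
    """
    config = config or SolverConfig()
    A_full = _as_csc(phi)
    y = np.asarray(y, dtype=float)
    _validate(A_full, y)
    solver = _SPDSolver(A_full, config)
    A = solver.phi_p
    n, p = A.shape
    aty = A.T @ y
    scale = max(float(np.max(np.abs(aty))), 1e-12)
    beta = np.full(p, scale * config.init_scale)
    e = A @ beta - y
    r = 1.5 * np.abs(e) + 1e-3 * max(float(np.max(np.abs(y))), 1e-12)
    gamma = config.gamma0
    stages = 0
    stage_objectives = []

    def barrier_obj(r_, xp, xm, b_):
        return float(np.sum(r_)) - (
            np.sum(np.log(xp)) + np.sum(np.log(xm)) + np.sum(np.log(r_)) + np.sum(np.log(b_))
        ) / gamma

    while True:
        for _ in range(config.max_newton):
            e = A @ beta - y
            xp = e + r
            xm = r - e
            inv_p, inv_m, inv_r, inv_b = 1.0 / xp, 1.0 / xm, 1.0 / r, 1.0 / beta
            grad_r = 1.0 - (inv_p + inv_m + inv_r) / gamma
            grad_b = -(A.T @ (inv_p - inv_m) + inv_b) / gamma
            gnorm = max(np.linalg.norm(grad_r, np.inf), np.linalg.norm(grad_b, np.inf))
            if gnorm <= config.newton_tol:
                break
            a2, b2 = inv_p**2, inv_m**2
            h_r = (a2 + b2 + inv_r**2) / gamma  # diagonal r-block
            diff = a2 - b2
            # Schur complement: (1/gamma)(Phi' diag(wgt) Phi + diag(1/b^2))
            wgt = (a2 + b2) - diff**2 / (a2 + b2 + inv_r**2)
            G = solver.gram(wgt / gamma)
            rhs = -grad_b + (A.T @ (diff * grad_r / (gamma * h_r)))
            d_b = solver.solve(G, inv_b**2 / gamma, rhs)
            Ad = A @ d_b
            d_r = -(grad_r + diff * Ad / gamma) / h_r
            # largest step keeping r, b, xi+ and xi- strictly positive
            tmax = 1.0
            for val, dv in ((beta, d_b), (r, d_r), (xp, Ad + d_r), (xm, d_r - Ad)):
                neg = dv < 0
                if np.any(neg):
                    tmax = min(tmax, 0.99 * float(np.min(-val[neg] / dv[neg])))
            f0 = barrier_obj(r, xp, xm, beta)
            gd = float(grad_r @ d_r) + float(grad_b @ d_b)
            t = tmax
            while t > 1e-16:
                b1 = beta + t * d_b
                r1 = r + t * d_r
                e1 = A @ b1 - y
                xp1, xm1 = e1 + r1, r1 - e1
                if np.all(xp1 > 0) and np.all(xm1 > 0) and np.all(r1 > 0) and np.all(b1 > 0):
                    f1 = barrier_obj(r1, xp1, xm1, b1)
                    if f1 <= f0 + config.ls_decrease * t * gd:
                        break
                t *= config.ls_shrink
            beta = beta + t * d_b
            r = r + t * d_r
        stages += 1
        stage_objectives.append(float(np.sum(np.abs(A @ beta - y))))
        if gamma >= config.gamma_max:
            break
        gamma = min(gamma * config.mult, config.gamma_max)

    beta_out = solver.unpermute(beta)
    resid = _as_csc(phi) @ beta_out - y
    objective = float(np.sum(np.abs(resid)))
    # interior-point certificate: for a barrier problem with m inequality
    # constraints, objective - optimum <= m / gamma at the stage optimum
    gap = (3 * n + p) / gamma
    kkt = gap / max(objective, max(float(np.max(np.abs(y))), 1e-12) * 1e-6)
    return FitResult(
        beta=beta_out,
        objective=objective,
        q=1,
        kkt_residual=kkt,
        stages=stages,
        converged=kkt <= config.kkt_tol,
        stage_objectives=stage_objectives,
    )
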