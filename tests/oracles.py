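"""Independent reference implementations used only to check the package.

Each oracle deliberately avoids the code paths of the implementation:
plain-python convolution for isotope distributions, arbitrary-precision
arithmetic for the EMG, linear programming for LAD and non-negative
least-absolute-deviation fits, the Lawson-Hanson active-set algorithm for
non-negative least squares, and exhaustive grid search for the merge step.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, nnls as lawson_hanson_nnls

# elemental data restated independently (IUPAC)
_ABUNDANCE = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}
_MONO = {"C": 12.0, "H": 1.007825032, "N": 14.003074005, "O": 15.994914620, "S": 31.972071174}
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254


def averagine_bruteforce(mass: float) -> np.ndarray:
    """Averagine isotope distribution by one-atom-at-a-time list convolution."""
    counts = {}
    for el in ("C", "N", "O", "S"):
        counts[el] = int(round(mass / _AVERAGINE_MASS * _AVERAGINE[el]))
    heavy = sum(_MONO[el] * n for el, n in counts.items())
    counts["H"] = max(int(round((mass - heavy) / _MONO["H"])), 0)
    dist = [1.0]
    for el, n in counts.items():
        base = _ABUNDANCE[el]
        for _ in range(n):
            out = [0.0] * (len(dist) + len(base) - 1)
            for i, a in enumerate(dist):
                for j, b in enumerate(base):
                    out[i + j] += a * b
            dist = out
    arr = np.array(dist)
    return arr / arr.max()


def emg_mpmath(d: float, alpha: float, sigma: float, mu: float, dps: int = 50) -> float:
    """High-precision EMG evaluation at distance d from the center."""
    import mpmath as mp

    with mp.workdps(dps):
        a, s, m, u = mp.mpf(alpha), mp.mpf(sigma), mp.mpf(mu), mp.mpf(mu) - mp.mpf(d)
        t = s / a + u / s
        val = (1 / a) * mp.e ** (s**2 / (2 * a**2) + u / a) * (1 - mp.ncdf(t))
        return float(val)


def lad_lp(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LAD regression via the LP  min 1'(u+v)  s.t.  X c + u - v = y."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    assert res.status == 0
    return res.x[:p]


def nnls_oracle_objective(Phi: np.ndarray, y: np.ndarray) -> float:
    """||y - Phi b*||_2^2 at the active-set NNLS optimum."""
    _, rnorm = lawson_hanson_nnls(Phi, y)
    return rnorm**2


def nnlad_oracle_objective(Phi: np.ndarray, y: np.ndarray) -> float:
    """||y - Phi b*||_1 at the LP optimum over b >= 0."""
    n, p = Phi.shape
    A_ub = np.vstack(
        [np.hstack([Phi, -np.eye(n)]), np.hstack([-Phi, -np.eye(n)])]
    )
    b_ub = np.concatenate([y, -y])
    c = np.concatenate([np.zeros(p), np.ones(n)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(0, None)] * (p + n), method="highs")
    assert res.status == 0
    return res.fun


def nn_lasso_oracle_objective(Phi: np.ndarray, y: np.ndarray, lam: float, w: np.ndarray) -> float:
    """min_{b>=0} ||y-Phi b||^2 + lam w'b via its QP KKT system, solved by
    NNLS on an augmented design (exact for lam >= 0)."""
    # ||y-Phi b||^2 + lam w'b = ||y_aug - Phi_aug b||^2 + const with a
    # completed square only when w'b enters linearly; instead solve by
    # projected gradient to high precision.
    p = Phi.shape[1]
    L = np.linalg.norm(Phi, 2) ** 2 * 2
    b = np.zeros(p)
    g_lin = lam * w
    for _ in range(200000):
        grad = 2 * Phi.T @ (Phi @ b - y) + g_lin
        b_new = np.maximum(b - grad / L, 0.0)
        if np.max(np.abs(b_new - b)) < 1e-14 * max(1.0, np.max(np.abs(b))):
            b = b_new
            break
        b = b_new
    r = y - Phi @ b
    return float(r @ r + lam * w @ b)


def random_sparse_instance(rng: np.random.Generator, n: int = 40, p: int = 60, noise: float = 0.1):
    """Random non-negative design with sparse non-negative truth plus noise."""
    Phi = rng.uniform(0, 1, (n, p)) * (rng.uniform(0, 1, (n, p)) < 0.3)
    for j in range(p):
        if Phi[:, j].sum() == 0:
            Phi[rng.integers(n), j] = rng.uniform(0.5, 1)
    beta = np.zeros(p)
    idx = rng.choice(p, 5, replace=False)
    beta[idx] = rng.uniform(0.5, 2, 5)
    y = Phi @ beta + rng.normal(0, noise, n)
    return Phi, y, beta


def merge_grid_oracle(anchors, coefs, sigma, lo, hi, n_m=801, n_b=401):
    """Exhaustive 2-d lattice search for the best single Gaussian peak
    approximating a weighted sum of Gaussian peaks (same sigma)."""
    anchors = np.asarray(anchors, float)
    coefs = np.asarray(coefs, float)
    grid = np.arange(lo, hi, sigma / 40.0)
    target = np.zeros_like(grid)
    for a, b in zip(anchors, coefs):
        target += b * np.exp(-0.5 * ((grid - a) / sigma) ** 2)
    ms = np.linspace(anchors.min() - sigma, anchors.max() + sigma, n_m)
    bs = np.linspace(0.2 * coefs.sum(), 1.5 * coefs.sum(), n_b)
    best = (np.inf, None, None)
    for m in ms:
        shape = np.exp(-0.5 * ((grid - m) / sigma) ** 2)
        # optimal b for this m in closed form, then nearest lattice point
        objs = ((bs[:, None] * shape[None, :] - target[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(objs))
        if objs[k] < best[0]:
            best = (objs[k], m, bs[k])
    return best  # (objective on lattice, m, b)
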