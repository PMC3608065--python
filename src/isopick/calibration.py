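"""Automatic peak-shape calibration.

Well-resolved peaks are detected in the spectrum, each is fitted by the
chosen single-peak model via nonlinear least squares, and the resulting
per-peak parameter estimates are aggregated into m/z-dependent trends by
robust least-absolute-deviation regression, so that shape parameters can be
evaluated at any template anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .peakshape import (
    ParameterError,
    PeakShapeKind,
    PeakShapeParams,
    Spectrum,
    single_peak_profile,
)

__all__ = [
    "CalibrationError",
    "PeakRegion",
    "RegionFit",
    "ShapeParamModel",
    "detect_peak_regions",
    "fit_peak_region",
    "fit_param_trend",
    "lad_fit",
]

PARAM_FLOOR = 1e-4  # Th, lower clip for sigma and alpha


class CalibrationError(RuntimeError):
    """Raised when too few well-resolved peaks are found; supply fixed shape
    parameters instead."""


@dataclass(frozen=True)
class PeakRegion:
    """Contiguous index range around one well-resolved peak."""

    start: int
    stop: int  # inclusive
    apex_index: int
    apex_mz: float
    apex_intensity: float

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass
class RegionFit:
    region: PeakRegion
    theta_hat: PeakShapeParams | None
    apex_mz: float
    height: float
    rss: float
    rel_rss: float
    converged: bool


def _grow_side(y: np.ndarray, apex: int, step: int, floor: float, max_violations: int) -> tuple[int, bool]:
    """Extend from the apex while the intensity descends; returns the last
    index of the run and whether the stop was a full decay to the floor
    (True) rather than a valley/boundary (False)."""
    i = apex
    violations = 0
    n = y.size
    while True:
        j = i + step
        if j < 0 or j >= n:
            return i, y[i] <= floor
        if y[j] <= floor:
            return j, True
        if y[j] > y[i]:
            violations += 1
            if violations > max_violations:
                return i, False
        i = j


def detect_peak_regions(
    spectrum: Spectrum,
    quantile: float = 0.75,
    valley_frac: float = 0.05,
    min_points: int = 8,
    min_separation: float = 0.3,
    min_regions: int = 5,
    max_violations: int = 1,
) -> list[PeakRegion]:
    """Detect disjoint regions of well-resolved peaks.

    An apex must exceed the given intensity quantile of the spectrum; its
    region extends while the intensity descends monotonically (tolerating
    ``max_violations`` per side) and must decay to ``valley_frac`` of the
    apex on both sides before any rise — peaks interrupted by a valley are
    not well resolved.  Retained apexes closer than ``min_separation`` (Th)
    to each other are discarded pairwise.
    """
    y = spectrum.intensity
    mz = spectrum.mz
    thr = float(np.quantile(y, quantile))
    base = float(np.quantile(y, 0.25))  # baseline proxy: decay is judged above it
    apexes = [
        i
        for i in range(1, len(y) - 1)
        if y[i] > thr and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]
    regions: list[PeakRegion] = []
    for i in apexes:
        floor = base + valley_frac * (y[i] - base)
        left, ok_l = _grow_side(y, i, -1, floor, max_violations)
        right, ok_r = _grow_side(y, i, +1, floor, max_violations)
        if not (ok_l and ok_r):
            continue
        lo, hi = min(left, i), max(right, i)
        if hi - lo + 1 < min_points or not (lo < i < hi):
            continue
        regions.append(PeakRegion(lo, hi, i, float(mz[i]), float(y[i])))
    # pairwise isolation filter on retained apexes
    drop = set()
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if abs(regions[a].apex_mz - regions[b].apex_mz) < min_separation or (
                regions[a].stop >= regions[b].start and regions[b].stop >= regions[a].start
            ):
                drop.add(a)
                drop.add(b)
    regions = [r for k, r in enumerate(regions) if k not in drop]
    regions.sort(key=lambda r: r.apex_mz)
    if len(regions) < min_regions:
        raise CalibrationError(
            f"only {len(regions)} well-resolved peak regions found "
            f"(need {min_regions}); supply fixed shape parameters instead"
        )
    return regions


def _fwhm_sigma(xs: np.ndarray, ys: np.ndarray) -> float:
    """Moment-free width guess from the full width at half maximum."""
    half = ys.max() / 2.0
    above = np.nonzero(ys >= half)[0]
    if above.size >= 2:
        fwhm = xs[above[-1]] - xs[above[0]]
        if fwhm > 0:
            return float(fwhm / 2.3548)
    return float((xs[-1] - xs[0]) / 6.0)


def fit_peak_region(
    spectrum: Spectrum, region: PeakRegion, kind: PeakShapeKind
) -> RegionFit:
    """Nonlinear least-squares fit of a single free-height peak to one region.

    A multiplicative height is fitted alongside the shape parameters (the
    EMG density is not unit-height) and discarded afterwards; the reported
    apex is the mode of the fitted shape.
    """
    kind = PeakShapeKind(kind)
    xs = spectrum.mz[region.start : region.stop + 1]
    ys = spectrum.intensity[region.start : region.stop + 1]
    s0 = _fwhm_sigma(xs, ys)
    span = xs[-1] - xs[0]
    total = float(np.sum(ys**2))

    if kind is PeakShapeKind.GAUSSIAN:

        def resid(p):
            h, c, s = p
            return ys - h * np.exp(-0.5 * ((xs - c) / s) ** 2)

        p0 = [region.apex_intensity, region.apex_mz, s0]
        lb = [0.0, xs[0] - span, 1e-6]
        ub = [np.inf, xs[-1] + span, 10 * span]
    else:

        def resid(p):
            h, c, a, s, m = p
            from .peakshape import eval_emg

            return ys - h * eval_emg(xs, c, PeakShapeParams(sigma=s, alpha=a, mu=m))

        p0 = [region.apex_intensity * s0, region.apex_mz, s0 / 2.0, s0, 0.0]
        lb = [0.0, xs[0] - span, 1e-6, 1e-6, -span]
        ub = [np.inf, xs[-1] + span, 10 * span, 10 * span, span]

    try:
        sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=2000)
    except (ValueError, FloatingPointError):
        return RegionFit(region, None, region.apex_mz, 0.0, np.inf, np.inf, False)
    rss = float(np.sum(sol.fun**2))
    rel = rss / total if total > 0 else np.inf
    ok = bool(sol.success) and np.isfinite(rss)
    # a width beyond the region span means there is no curvature evidence
    # of a peak (e.g. flat noise fitted by a near-constant wide Gaussian)
    sigma_idx = 2 if kind is PeakShapeKind.GAUSSIAN else 3
    if ok and sol.x[sigma_idx] >= span:
        ok = False
    if kind is PeakShapeKind.GAUSSIAN:
        h, c, s = sol.x
        theta = PeakShapeParams(sigma=float(s)) if ok else None
        apex = float(c)
    else:
        h, c, a, s, m = sol.x
        theta = PeakShapeParams(sigma=float(s), alpha=float(a), mu=float(m)) if ok else None
        # refine apex to the fitted mode
        if ok:
            grid = np.linspace(c + m - 4 * s, c + m + 4 * s + 8 * a, 801)
            vals = single_peak_profile(grid, c, kind, theta, normalized=False)
            apex = float(grid[np.argmax(vals)])
        else:
            apex = region.apex_mz
    return RegionFit(region, theta, apex, float(h), rss, rel, ok)


def lad_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-absolute-deviation coefficients (median regression).

    A single constant column reduces exactly to the median; otherwise the
    LAD solution is computed by quantile regression at the median.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[1] == 1 and np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0:
        return np.array([float(np.median(y)) / X[0, 0]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ParameterError("degenerate (collinear) basis in LAD trend fit")
    # exact interpolation: a zero-residual least-squares fit is the LAD optimum
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.max(np.abs(resid)) <= 1e-10 * max(np.max(np.abs(y)), 1.0):
        return np.asarray(coef, dtype=float)
    from statsmodels.regression.quantile_regression import QuantReg

    res = QuantReg(y, X).fit(q=0.5, max_iter=5000)
    return np.asarray(res.params, dtype=float)


@dataclass
class ShapeParamModel:
    """m/z-dependent peak-shape parameters as linear basis trends.

    Each parameter component (sigma, and for EMG alpha and mu) is a linear
    combination of basis functions of m/z; evaluation clips sigma and alpha
    below at a small positive floor.
    """

    kind: PeakShapeKind
    components: dict  # name -> (list of basis callables, coefficient array)
    fit_pairs: list = field(default_factory=list)  # (apex_mz, RegionFit) diagnostics

    @classmethod
    def constant(cls, kind: PeakShapeKind, params: PeakShapeParams) -> "ShapeParamModel":
        """Fixed, user-supplied shape parameters (no m/z dependence)."""
        kind = PeakShapeKind(kind)
        comps = {"sigma": ([lambda x: 1.0], np.array([params.sigma]))}
        if kind is PeakShapeKind.EMG:
            comps["alpha"] = ([lambda x: 1.0], np.array([params.alpha]))
            comps["mu"] = ([lambda x: 1.0], np.array([params.mu]))
        return cls(kind=kind, components=comps)

    def _eval_component(self, name: str, x: float) -> float:
        basis, coef = self.components[name]
        return float(sum(c * g(x) for c, g in zip(coef, basis)))

    def eval_params(self, x: float) -> PeakShapeParams:
        sigma = max(self._eval_component("sigma", x), PARAM_FLOOR)
        if self.kind is PeakShapeKind.EMG:
            alpha = max(self._eval_component("alpha", x), PARAM_FLOOR)
            mu = self._eval_component("mu", x)
            return PeakShapeParams(sigma=sigma, alpha=alpha, mu=mu)
        return PeakShapeParams(sigma=sigma)


DEFAULT_BASIS: list[Callable[[float], float]] = [lambda x: 1.0, lambda x: x]


def fit_param_trend(
    fits: Sequence[RegionFit],
    kind: PeakShapeKind,
    basis: dict | None = None,
    mode: str = "linear",
    max_rel_rss: float = 0.2,
) -> ShapeParamModel:
    """Robust LAD trends of the peak-shape parameters over m/z.

    Fits with relative residual sum of squares above ``max_rel_rss`` or
    non-converged fits are excluded.  ``mode='constant'`` aggregates each
    component by its median; the default linear mode fits {1, x} trends.
    """
    kind = PeakShapeKind(kind)
    good = [f for f in fits if f.converged and f.theta_hat is not None and f.rel_rss <= max_rel_rss]
    names = ["sigma"] if kind is PeakShapeKind.GAUSSIAN else ["alpha", "sigma", "mu"]
    if basis is None:
        basis = {}
    comps = {}
    xs = np.array([f.apex_mz for f in good])
    for name in names:
        funcs = basis.get(name)
        if funcs is None:
            funcs = [lambda x: 1.0] if mode == "constant" else list(DEFAULT_BASIS)
        if len(good) < len(funcs) + 1:
            raise CalibrationError(
                f"too few converged region fits ({len(good)}) for the "
                f"{name} trend with {len(funcs)} basis functions"
            )
        vals = np.array([getattr(f.theta_hat, name) for f in good], dtype=float)
        X = np.column_stack([[g(x) for x in xs] for g in funcs])
        coef = lad_fit(X, vals)
        comps[name] = (funcs, coef)
    return ShapeParamModel(kind=kind, components=comps, fit_pairs=[(f.apex_mz, f) for f in good])
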