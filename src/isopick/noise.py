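"""Local noise level, template placement and the goodness-of-fit map.

The local noise level (LNL) is the median intensity in a sliding m/z
window; being a median, it is robust and equivariant under monotone
intensity transforms.  Templates are placed wherever the signal exceeds
the LNL by a configurable factor.  The goodness-of-fit map fits the
spectrum by *single* peaks placed at every datum and converts windowed
residual sums into a statistic capped at 0.5 that down-weights irregular
noise regions in the final signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .peakshape import (
    ParameterError,
    Spectrum,
    peak_support_halfwidth,
    single_peak_profile,
)
from .solvers import SolverConfig, nnlad_logbarrier, nnls_logbarrier

__all__ = [
    "NoiseModel",
    "GofMap",
    "local_noise_level",
    "select_placements",
    "goodness_of_fit_map",
]


@dataclass
class NoiseModel:
    """Sliding-window median noise level per datum, with its truncated
    version LNL+ = max(LNL, global floor), floor = 1/4 median of all LNL."""

    h: float
    lnl: np.ndarray
    lnl_plus: np.ndarray
    global_floor: float


def _window_bounds(mz: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(mz, mz - h, side="left")
    hi = np.searchsorted(mz, mz + h, side="right")
    return lo, hi


def local_noise_level(spectrum: Spectrum, h: float = 2.5) -> NoiseModel:
    """Median intensity in the window [x-h, x+h] around each datum; windows
    are truncated at the spectrum boundaries."""
    if not (h > 0):
        raise ParameterError(f"window half-width h must be > 0, got {h}")
    mz, y = spectrum.mz, spectrum.intensity
    lo, hi = _window_bounds(mz, h)
    lnl = np.array([np.median(y[a:b]) for a, b in zip(lo, hi)])
    floor = 0.25 * float(np.median(lnl))
    return NoiseModel(h=h, lnl=lnl, lnl_plus=np.maximum(lnl, floor), global_floor=floor)


def select_placements(
    spectrum: Spectrum, noise: NoiseModel, factor_place: float = 1.5, charges=(1, 2, 3, 4)
) -> list[tuple[int, float]]:
    """One template placement per charge state at every datum whose intensity
    exceeds factor_place times the local noise level."""
    if not (factor_place > 0):
        raise ParameterError("factor_place must be > 0")
    charges = sorted(int(c) for c in charges)
    if not charges:
        raise ParameterError("charges must be non-empty")
    idx = np.nonzero(spectrum.intensity > factor_place * noise.lnl)[0]
    return [(c, float(spectrum.mz[i])) for i in idx for c in charges]


@dataclass
class GofMap:
    """Residuals of the single-peak fit and the windowed goodness-of-fit
    statistic GOF+ <= cap per datum."""

    residuals: np.ndarray
    gof_plus: np.ndarray
    q: int
    cap: float = 0.5


def goodness_of_fit_map(
    spectrum: Spectrum,
    shape_model,
    q: int = 2,
    h: float = 2.5,
    solver_config: SolverConfig | None = None,
    stride: int = 1,
    cap: float = 0.5,
    mode: str = "min",
) -> GofMap:
    """Windowed goodness of fit of a single-peak dictionary.

    A max-normalized single peak is placed at every datum (``stride`` > 1
    subsamples the placements for very long spectra), fitted to the
    intensities under non-negativity with the same norm q as the template
    fit, and GOF+(x) = min(1 - sum_w |r|^q / sum_w |y|^q, cap) computed
    over the same windows as the local noise level.  Windows with zero
    signal get the neutral value ``cap``.
    """
    if q not in (1, 2):
        raise ParameterError("q must be 1 or 2")
    mz, y = spectrum.mz, spectrum.intensity
    n = len(spectrum)
    data, indices, indptr = [], [], [0]
    for i in range(0, n, max(int(stride), 1)):
        center = mz[i]
        params = shape_model.eval_params(center)
        hw = peak_support_halfwidth(shape_model.kind, params)
        i0 = int(np.searchsorted(mz, center - hw, side="left"))
        i1 = int(np.searchsorted(mz, center + hw, side="right"))
        col = single_peak_profile(mz[i0:i1], center, shape_model.kind, params)
        data.append(col)
        indices.append(np.arange(i0, i1))
        indptr.append(indptr[-1] + (i1 - i0))
    design = sp.csc_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
        shape=(n, len(indptr) - 1),
    )
    fit = (nnls_logbarrier if q == 2 else nnlad_logbarrier)(design, y, solver_config)
    resid = y - design @ fit.beta

    lo, hi = _window_bounds(mz, h)
    cr = np.concatenate([[0.0], np.cumsum(np.abs(resid) ** q)])
    cy = np.concatenate([[0.0], np.cumsum(np.abs(y) ** q)])
    sr = cr[hi] - cr[lo]
    sy = cy[hi] - cy[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 1.0 - sr / sy
    raw = np.where(sy > 0, raw, cap)
    gof = np.minimum(raw, cap) if mode == "min" else np.maximum(raw, cap)
    return GofMap(residuals=resid, gof_plus=gof, q=q, cap=cap)
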