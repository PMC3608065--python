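"""Peak-shape functions, averagine isotope distributions and template assembly.

A spectrum is modelled as a non-negative combination of *templates*: each
template is the superposition of single-peak functions (Gaussian or
exponentially modified Gaussian) placed at the isotopic positions of a
hypothetical peptide of a given charge, weighted by the averagine isotope
distribution and max-normalized so that its coefficient can be read as the
intensity of the pattern's most intense peak.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import erfcx, erfc

from ._chem import (
    AVERAGINE_COMPOSITION,
    AVERAGINE_MASS,
    CARBAMIDOMETHYL_MASS,
    ISOTOPE_ABUNDANCE,
    MONO_MASS,
    PROTON_MASS,
    RESIDUE_MASS,
    WATER_MASS,
)

__all__ = [
    "Spectrum",
    "PeakShapeKind",
    "PeakShapeParams",
    "IsotopeDistribution",
    "Template",
    "TemplateMatrix",
    "eval_gaussian",
    "eval_emg",
    "single_peak_profile",
    "averagine_distribution",
    "build_template",
    "template_profile",
    "assemble_template_matrix",
    "peptide_monoisotopic_mz",
]

_SQRT2 = math.sqrt(2.0)


class ParameterError(ValueError):
    """Invalid model or shape parameter."""


@dataclass(frozen=True)
class Spectrum:
    """Ordered profile-mode spectrum: m/z grid and non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise ParameterError("mz and intensity must be 1-d arrays of equal length")
        if mz.size < 2:
            raise ParameterError("a spectrum needs at least two data points")
        if not np.all(np.isfinite(mz)) or not np.all(np.isfinite(inten)):
            raise ParameterError("spectrum contains non-finite values")
        if np.any(np.diff(mz) <= 0):
            raise ParameterError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ParameterError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    @property
    def median_spacing(self) -> float:
        return float(np.median(np.diff(self.mz)))


class PeakShapeKind(str, enum.Enum):
    GAUSSIAN = "gaussian"
    EMG = "emg"


@dataclass(frozen=True)
class PeakShapeParams:
    """Single-peak shape parameters: Gaussian width ``sigma`` and, for the
    EMG, the exponential tailing scale ``alpha`` and shift ``mu`` (all in Th;
    ``alpha``/``mu`` are ignored for a pure Gaussian)."""

    sigma: float
    alpha: float | None = None
    mu: float = 0.0

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.alpha is not None and not (self.alpha > 0):
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class IsotopeDistribution:
    """Relative isotopic abundances (max-normalized to 1)."""

    weights: np.ndarray
    most_intense_index: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0):
            raise ParameterError("isotope weights must be non-negative")
        if int(np.argmax(w)) != self.most_intense_index:
            raise ParameterError("most_intense_index does not attain the maximum")


def eval_gaussian(x, center: float, sigma: float) -> np.ndarray:
    """Unit-height Gaussian exp(-(x-center)^2 / (2 sigma^2))."""
    if not (sigma > 0):
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    d = (x - center) / sigma
    return np.exp(-0.5 * d * d)


def eval_emg(x, center: float, params: PeakShapeParams) -> np.ndarray:
    """Exponentially modified Gaussian density with a right exponential tail.

    psi(x) = (1/alpha) exp(sigma^2/(2 alpha^2) + (mu - d)/alpha)
             * (1 - F(sigma/alpha + (mu - d)/sigma)),   d = x - center,

    with F the standard normal CDF.  Evaluated through the scaled
    complementary error function so the exponential prefactor never
    overflows, even for sigma/alpha up to 1e4.
    """
    if params.alpha is None or not (params.alpha > 0):
        raise ParameterError("EMG evaluation requires alpha > 0")
    sigma, alpha, mu = params.sigma, params.alpha, params.mu
    x = np.asarray(x, dtype=float)
    u = mu - (x - center)
    t = sigma / alpha + u / sigma
    z = t / _SQRT2
    out = np.empty_like(u)
    # 1 - F(t) = erfc(z)/2 = erfcx(z) exp(-z^2)/2; combining with the
    # exponential prefactor A gives A - z^2 = -u^2/(2 sigma^2) exactly.
    pos = z > -25.0
    if np.any(pos):
        up = u[pos]
        out[pos] = (0.5 / alpha) * erfcx(z[pos]) * np.exp(-0.5 * (up / sigma) ** 2)
    if np.any(~pos):
        # far right tail: erfc(z) ~ 2, direct formula is safe (exponent < 0)
        un = u[~pos]
        a_exp = 0.5 * (sigma / alpha) ** 2 + un / alpha
        out[~pos] = (0.5 / alpha) * np.exp(a_exp) * erfc(z[~pos])
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("EMG evaluation produced non-finite values")
    return out


def _emg_max(params: PeakShapeParams) -> float:
    """Numerical maximum of the (non-normalized) EMG density."""
    sigma, alpha, mu = params.sigma, params.alpha, params.mu
    lo = mu - 6.0 * sigma
    hi = mu + 6.0 * sigma + 12.0 * alpha
    grid = np.linspace(lo, hi, 4001)
    vals = eval_emg(grid, 0.0, params)
    i = int(np.argmax(vals))
    # one refinement pass around the coarse argmax
    lo2 = grid[max(i - 1, 0)]
    hi2 = grid[min(i + 1, grid.size - 1)]
    fine = np.linspace(lo2, hi2, 201)
    return float(np.max(eval_emg(fine, 0.0, params)))


def single_peak_profile(
    x,
    center: float,
    kind: PeakShapeKind,
    params: PeakShapeParams,
    normalized: bool = True,
) -> np.ndarray:
    """Evaluate one peak of the chosen shape, optionally max-normalized to 1."""
    kind = PeakShapeKind(kind)
    if kind is PeakShapeKind.GAUSSIAN:
        return eval_gaussian(x, center, params.sigma)
    vals = eval_emg(x, center, params)
    if normalized:
        vals = vals / _emg_max(params)
    return vals


def peak_support_halfwidth(kind: PeakShapeKind, params: PeakShapeParams) -> float:
    """Half-width beyond which a single peak is numerically negligible."""
    kind = PeakShapeKind(kind)
    if kind is PeakShapeKind.GAUSSIAN:
        return 6.0 * params.sigma
    return 6.0 * params.sigma + 12.0 * (params.alpha or 0.0) + abs(params.mu)


def _element_distribution(abundance: list[float], count: int) -> np.ndarray:
    """Isotope distribution of `count` atoms by repeated squaring."""
    result = np.array([1.0])
    base = np.asarray(abundance, dtype=float)
    k = count
    while k > 0:
        if k & 1:
            result = np.convolve(result, base)
        base = np.convolve(base, base)
        k >>= 1
    return result


def averagine_element_counts(mass: float) -> dict[str, int]:
    """Integer elemental composition of the averagine pseudo-peptide of the
    given monoisotopic mass; hydrogen is adjusted to match the target mass."""
    if not (mass > 0):
        raise ParameterError(f"mass must be > 0, got {mass}")
    scale = mass / AVERAGINE_MASS
    counts = {
        el: int(round(scale * n))
        for el, n in AVERAGINE_COMPOSITION.items()
        if el != "H"
    }
    heavy = sum(MONO_MASS[el] * n for el, n in counts.items())
    counts["H"] = max(int(round((mass - heavy) / MONO_MASS["H"])), 0)
    return counts


def averagine_distribution(
    mass: float, max_peaks: int | None = None, trim_rel: float = 0.01
) -> IsotopeDistribution:
    """Averagine isotope distribution at a given neutral monoisotopic mass.

    The elemental composition is scaled to ``mass``, element counts rounded
    to integers (hydrogen adjusted to hit the target mass), the elemental
    isotope distributions convolved, and trailing peaks below
    ``trim_rel`` times the maximum trimmed.  Weights are reported relative
    to the most intense peak (max = 1).
    """
    counts = averagine_element_counts(mass)
    dist = np.array([1.0])
    for el, n in counts.items():
        if n > 0:
            dist = np.convolve(dist, _element_distribution(ISOTOPE_ABUNDANCE[el], n))
    dist = dist / dist.max()
    keep = np.nonzero(dist >= trim_rel)[0]
    last = int(keep[-1]) if keep.size else 0
    dist = dist[: last + 1]
    if max_peaks is not None:
        dist = dist[:max_peaks]
    dist = dist / dist.max()
    return IsotopeDistribution(weights=dist, most_intense_index=int(np.argmax(dist)))


@dataclass(frozen=True)
class Template:
    """Isotope-pattern template: averagine-weighted peaks spaced kappa/charge
    apart, anchored at (and max-normalized around) the most intense peak."""

    charge: int
    anchor_mz: float
    peak_centers: np.ndarray
    weights: IsotopeDistribution
    kind: PeakShapeKind
    params: PeakShapeParams
    kappa: float
    normalization: float = 1.0

    @property
    def support(self) -> tuple[float, float]:
        hw = peak_support_halfwidth(self.kind, self.params)
        return float(self.peak_centers[0] - hw), float(self.peak_centers[-1] + hw)


def _template_raw(template: Template, x: np.ndarray) -> np.ndarray:
    vals = np.zeros_like(np.asarray(x, dtype=float))
    for w, c in zip(template.weights.weights, template.peak_centers):
        vals += w * single_peak_profile(x, c, template.kind, template.params)
    return vals


def template_profile(template: Template, x) -> np.ndarray:
    """Evaluate the max-normalized template on ``x``."""
    return _template_raw(template, np.asarray(x, dtype=float)) / template.normalization


def build_template(
    charge: int,
    anchor_mz: float,
    kind: PeakShapeKind,
    params: PeakShapeParams,
    kappa: float = 1.00235,
    trim_rel: float = 0.01,
) -> Template:
    """Build the isotope-pattern template of a given charge anchored at the
    most intense isotopic peak.

    The neutral mass is taken as charge * anchor - charge * proton; isotope
    weights come from the averagine model; peak centers sit at
    anchor + kappa*k/charge with k indexed relative to the most intense peak
    (negative k toward the monoisotopic peak when that is not the most
    intense one).
    """
    if charge < 1:
        raise ParameterError(f"charge must be >= 1, got {charge}")
    if not (anchor_mz > 0):
        raise ParameterError(f"anchor_mz must be > 0, got {anchor_mz}")
    kind = PeakShapeKind(kind)
    mass = charge * anchor_mz - charge * PROTON_MASS
    dist = averagine_distribution(mass, trim_rel=trim_rel)
    k = np.arange(dist.weights.size) - dist.most_intense_index
    centers = anchor_mz + kappa * k / charge
    tpl = Template(
        charge=int(charge),
        anchor_mz=float(anchor_mz),
        peak_centers=centers,
        weights=dist,
        kind=kind,
        params=params,
        kappa=float(kappa),
    )
    # normalize the continuous profile to unit maximum on a fine grid
    lo, hi = tpl.support
    step = params.sigma / 50.0
    grid = np.arange(lo, hi + step, step)
    norm = float(np.max(_template_raw(tpl, grid)))
    object.__setattr__(tpl, "normalization", norm)
    return tpl


@dataclass
class TemplateMatrix:
    """Sparse non-negative design of sampled templates, ordered by charge
    block then anchor position."""

    columns: sp.csc_matrix
    block_index: list  # (charge, anchor_mz) per column
    charges: list
    templates: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.columns.shape

    def anchors(self) -> np.ndarray:
        return np.array([a for (_, a) in self.block_index])

    def column_charges(self) -> np.ndarray:
        return np.array([c for (c, _) in self.block_index], dtype=int)


def assemble_template_matrix(
    spectrum: Spectrum,
    placements,
    shape_model,
    kappa: float = 1.00235,
    trim_rel: float = 0.01,
    sparse_floor: float = 1e-8,
) -> TemplateMatrix:
    """Sample one template per (charge, anchor) placement on the spectrum grid.

    ``shape_model`` must expose ``kind`` and ``eval_params(x)`` (see the
    calibration module).  Entries are kept on the contiguous index range
    between the first and last value >= ``sparse_floor`` times the column
    maximum, so every column support is contiguous and the Gram matrix is
    banded after anchor ordering.
    """
    placements = list(placements)
    if not placements:
        raise ParameterError("placements must be non-empty")
    mz = spectrum.mz
    lo_mz, hi_mz = mz[0], mz[-1]
    for c, a in placements:
        if not (lo_mz <= a <= hi_mz):
            raise ParameterError(
                f"anchor {a} outside the spectrum range [{lo_mz}, {hi_mz}]"
            )
    placements = sorted(placements, key=lambda p: (p[0], p[1]))
    n = len(spectrum)
    data, indices, indptr = [], [], [0]
    block_index, templates = [], []
    for charge, anchor in placements:
        params = shape_model.eval_params(anchor)
        tpl = build_template(charge, anchor, shape_model.kind, params, kappa, trim_rel)
        s_lo, s_hi = tpl.support
        i0 = int(np.searchsorted(mz, s_lo, side="left"))
        i1 = int(np.searchsorted(mz, s_hi, side="right"))
        xs = mz[i0:i1]
        col = template_profile(tpl, xs)
        cmax = col.max() if col.size else 0.0
        nz = np.nonzero(col >= sparse_floor * cmax)[0]
        if nz.size == 0:
            j0, j1 = 0, 0
        else:
            j0, j1 = int(nz[0]), int(nz[-1]) + 1
        data.append(col[j0:j1])
        indices.append(np.arange(i0 + j0, i0 + j1))
        indptr.append(indptr[-1] + (j1 - j0))
        block_index.append((int(charge), float(anchor)))
        templates.append(tpl)
    matrix = sp.csc_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
        shape=(n, len(placements)),
    )
    charges = sorted({c for c, _ in block_index})
    return TemplateMatrix(matrix, block_index, charges, templates)


def peptide_monoisotopic_mz(
    sequence: str, charge: int, carbamidomethyl: bool = False
) -> float:
    """Monoisotopic m/z of a protonated peptide: (sum of residue masses +
    water + charge protons) / charge.  Cysteines are unmodified unless
    ``carbamidomethyl`` is set."""
    if charge < 1:
        raise ParameterError(f"charge must be >= 1, got {charge}")
    total = WATER_MASS
    for ch in sequence:
        try:
            total += RESIDUE_MASS[ch]
        except KeyError:
            raise ParameterError(f"unknown amino-acid residue {ch!r}") from None
        if carbamidomethyl and ch == "C":
            total += CARBAMIDOMETHYL_MASS
    return (total + charge * PROTON_MASS) / charge
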