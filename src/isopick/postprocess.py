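"""Merging of split templates, signal-to-noise scoring and thresholding.

A limited sampling rate and peak-model mismatch make the fit distribute
the weight of one true pattern over several adjacent templates ("peak
splitting").  Positive coefficients of the same charge are therefore
grouped within a ppm tolerance and each group is collapsed into a single
continuous-location feature by least squares over the most intense single
peaks.  Features are scored by ratio = GOF+ * beta / LNL+ and retained if
the ratio exceeds the user threshold; an optional peptide-mass filter
keeps only masses near the empirical peptide mass centers
1.000485 * m_n + 0.029 over integer nominal masses m_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._chem import PROTON_MASS
from .peakshape import (
    Spectrum,
    TemplateMatrix,
    averagine_distribution,
    single_peak_profile,
    peak_support_halfwidth,
)
from .noise import GofMap, NoiseModel
from .solvers import FitResult

__all__ = [
    "TemplateGroup",
    "MergedFeature",
    "ScoredFeature",
    "Peaklist",
    "group_templates",
    "merge_group",
    "score_features",
    "apply_threshold",
    "peptide_mass_filter",
]

# Interior-point coefficients are never exactly zero: at barrier weight
# gamma an inactive template keeps beta_j ~ 1/(gamma * gradient_j), well
# below 1e-6 of the largest coefficient, while genuine contributions stay
# orders of magnitude above it.
ZERO_TOL_REL = 1e-6


@dataclass
class TemplateGroup:
    charge: int
    anchors: np.ndarray
    coefficients: np.ndarray
    group_id: int


@dataclass
class MergedFeature:
    charge: int
    location: float  # m/z of the most intense peak
    coefficient: float
    group: TemplateGroup
    merged_from: int = 1
    fallback: bool = False


@dataclass
class ScoredFeature:
    charge: int
    location: float
    coefficient: float
    ratio: float
    gof_plus: float
    lnl_plus: float
    monoisotopic_mz: float
    neutral_mass: float
    merged_from: int = 1


@dataclass
class Peaklist:
    features: list
    threshold: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def group_templates(
    fit: FitResult, matrix: TemplateMatrix, ppm_tol: float = 100.0
) -> list[TemplateGroup]:
    """Chain positive-coefficient anchors of the same charge into groups of
    adjacent positions (gap <= ppm_tol relative to the anchor)."""
    if not (ppm_tol > 0):
        raise ValueError("ppm_tol must be > 0")
    beta = np.asarray(fit.beta, dtype=float)
    zero_tol = ZERO_TOL_REL * float(beta.max(initial=0.0))
    anchors = matrix.anchors()
    charges = matrix.column_charges()
    groups: list[TemplateGroup] = []
    gid = 0
    for c in sorted(set(charges.tolist())):
        mask = (charges == c) & (beta > zero_tol)
        if not np.any(mask):
            continue
        a = anchors[mask]
        b = beta[mask]
        order = np.argsort(a)
        a, b = a[order], b[order]
        start = 0
        for i in range(1, a.size + 1):
            if i == a.size or (a[i] - a[i - 1]) > ppm_tol * a[i - 1] / 1e6:
                groups.append(TemplateGroup(int(c), a[start:i], b[start:i], gid))
                gid += 1
                start = i
    return groups


def merge_group(
    group: TemplateGroup,
    shape_model,
    data_spacing: float | None = None,
) -> MergedFeature:
    """Collapse one group into a single (location, weight) by least squares.

    The coefficient-weighted sum of the members' most intense single peaks
    is approximated by one peak with continuous location; the integral
    criterion is sampled on a grid of spacing min(sigma/20, data
    spacing/4) over the group's support +- 5 sigma.  Singleton groups pass
    through unchanged.
    """
    a, b = group.anchors, group.coefficients
    if a.size == 0:
        raise ValueError("cannot merge an empty group")
    if a.size == 1:
        return MergedFeature(group.charge, float(a[0]), float(b[0]), group)
    center = float(np.sum(a * b) / np.sum(b))
    params = shape_model.eval_params(center)
    kind = shape_model.kind
    sigma = params.sigma
    step = sigma / 20.0
    if data_spacing is not None:
        step = min(step, data_spacing / 4.0)
    hw = 5.0 * sigma + peak_support_halfwidth(kind, params)
    grid = np.arange(a.min() - hw, a.max() + hw + step, step)
    target = np.zeros_like(grid)
    for aj, bj in zip(a, b):
        target += bj * single_peak_profile(grid, aj, kind, params)

    def resid(p):
        m, w = p
        return w * single_peak_profile(grid, m, kind, params) - target

    try:
        sol = least_squares(resid, [center, float(np.sum(b))], max_nfev=1000)
        if not sol.success or sol.x[1] <= 0:
            raise RuntimeError("merge optimizer failed")
        return MergedFeature(
            group.charge, float(sol.x[0]), float(sol.x[1]), group, merged_from=int(a.size)
        )
    except (RuntimeError, ValueError):
        j = int(np.argmax(b))
        return MergedFeature(
            group.charge, float(a[j]), float(b[j]), group, merged_from=int(a.size), fallback=True
        )


def score_features(
    features: list,
    noise: NoiseModel,
    gof: GofMap,
    spectrum: Spectrum,
    kappa: float = 1.00235,
    trim_rel: float = 0.01,
) -> list[ScoredFeature]:
    """Assign ratio = GOF+ * beta / LNL+ (both looked up at the datum
    nearest the merged location) and convert the most-intense-peak location
    to the monoisotopic m/z via the averagine most-intense index."""
    mz = spectrum.mz
    out = []
    for f in features:
        i = int(np.clip(np.searchsorted(mz, f.location), 0, mz.size - 1))
        if i > 0 and abs(mz[i - 1] - f.location) < abs(mz[i] - f.location):
            i -= 1
        lnl_plus = float(noise.lnl_plus[i])
        gof_plus = float(gof.gof_plus[i])
        ratio = gof_plus * f.coefficient / lnl_plus if lnl_plus > 0 else np.inf
        mass = f.charge * f.location - f.charge * PROTON_MASS
        k_max = averagine_distribution(mass, trim_rel=trim_rel).most_intense_index
        mono = f.location - k_max * kappa / f.charge
        out.append(
            ScoredFeature(
                charge=f.charge,
                location=f.location,
                coefficient=f.coefficient,
                ratio=float(ratio),
                gof_plus=gof_plus,
                lnl_plus=lnl_plus,
                monoisotopic_mz=float(mono),
                neutral_mass=float(f.charge * mono - f.charge * PROTON_MASS),
                merged_from=f.merged_from,
            )
        )
    return out


def apply_threshold(features: list, t: float, metadata: dict | None = None) -> Peaklist:
    """Keep features whose signal-to-noise ratio is at least t, sorted by
    monoisotopic m/z.  No re-fitting is involved: selection is a pure
    filter on the single fit."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    kept = sorted(
        (f for f in features if f.ratio >= t), key=lambda f: f.monoisotopic_mz
    )
    return Peaklist(features=list(kept), threshold=float(t), metadata=metadata or {})


def _nearest_mass_center_ppm(mass: float) -> float:
    """ppm deviation to the nearest peptide mass center 1.000485*m_n + 0.029."""
    m_n = round((mass - 0.029) / 1.000485)
    best = np.inf
    for k in (m_n - 1, m_n, m_n + 1):
        center = 1.000485 * k + 0.029
        best = min(best, abs(mass - center))
    return best / mass * 1e6


def peptide_mass_filter(peaklist: Peaklist, tol_ppm: float = 200.0) -> Peaklist:
    """Retain features whose neutral monoisotopic mass lies within tol_ppm
    of the nearest empirical peptide mass center."""
    kept = [
        f for f in peaklist.features if _nearest_mass_center_ppm(f.neutral_mass) < tol_ppm
    ]
    meta = dict(peaklist.metadata)
    meta["peptide_mass_filter_ppm"] = tol_ppm
    return Peaklist(features=kept, threshold=peaklist.threshold, metadata=meta)
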