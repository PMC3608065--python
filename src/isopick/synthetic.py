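"""Synthetic spectra with known ground truth, and peaklist evaluation.

The generator emulates mixtures of peptides measured in profile mode: each
pattern is a max-normalized averagine template scaled by a height, summed
on a regular m/z grid with an optional constant baseline, additive
Gaussian noise (standard deviation relative to the largest pattern
height) and optional multiplicative log-normal noise.  Evaluation matches
a peaklist against the truth greedily one-to-one within a ppm tolerance
and reports recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._chem import PROTON_MASS
from .peakshape import (
    ParameterError,
    PeakShapeKind,
    PeakShapeParams,
    Spectrum,
    averagine_distribution,
    build_template,
    peptide_monoisotopic_mz,
    template_profile,
)

__all__ = [
    "GroundTruthPattern",
    "TruthEntry",
    "EvalResult",
    "pattern_anchor",
    "simulate_spectrum",
    "evaluate_peaklist",
]


@dataclass(frozen=True)
class GroundTruthPattern:
    """One isotope pattern to simulate: a neutral monoisotopic mass (or a
    peptide sequence), a charge state, and the height of the most intense
    peak."""

    charge: int
    height: float
    mass: float | None = None
    sequence: str | None = None

    def __post_init__(self):
        if self.charge < 1 or not (self.height > 0):
            raise ParameterError("require charge >= 1 and height > 0")
        if (self.mass is None) == (self.sequence is None):
            raise ParameterError("give exactly one of mass or sequence")

    def neutral_mass(self) -> float:
        if self.mass is not None:
            return self.mass
        mz = peptide_monoisotopic_mz(self.sequence, self.charge)
        return self.charge * mz - self.charge * PROTON_MASS


@dataclass(frozen=True)
class TruthEntry:
    charge: int
    height: float
    mass: float
    monoisotopic_mz: float
    anchor_mz: float


def pattern_anchor(pattern: GroundTruthPattern, kappa: float = 1.00235, trim_rel: float = 0.01) -> TruthEntry:
    """Anchor (most intense peak) and monoisotopic m/z of a pattern."""
    mass = pattern.neutral_mass()
    c = pattern.charge
    mono_mz = (mass + c * PROTON_MASS) / c
    k_max = averagine_distribution(mass, trim_rel=trim_rel).most_intense_index
    return TruthEntry(
        charge=c,
        height=pattern.height,
        mass=mass,
        monoisotopic_mz=mono_mz,
        anchor_mz=mono_mz + kappa * k_max / c,
    )


def simulate_spectrum(
    patterns,
    mz_range: tuple[float, float],
    spacing: float = 0.06,
    kind: PeakShapeKind = PeakShapeKind.GAUSSIAN,
    params: PeakShapeParams | None = None,
    shape_trend=None,
    additive_sd: float = 0.0,
    multiplicative_sd: float = 0.0,
    baseline: float = 0.0,
    kappa: float = 1.00235,
    trim_rel: float = 0.01,
    seed: int | None = None,
) -> tuple[Spectrum, list[TruthEntry]]:
    """Simulate a profile spectrum from ground-truth patterns.

    ``additive_sd`` is relative to the largest pattern height; ``baseline``
    is an absolute constant offset; ``shape_trend`` may be a callable
    m/z -> PeakShapeParams overriding the fixed ``params``.  Deterministic
    for a fixed seed.
    """
    if not (spacing > 0):
        raise ParameterError("spacing must be > 0")
    patterns = list(patterns)
    lo, hi = mz_range
    x = np.arange(lo, hi + spacing / 2, spacing)
    y = np.full_like(x, float(baseline))
    truth = []
    for p in patterns:
        entry = pattern_anchor(p, kappa, trim_rel)
        if not (lo <= entry.anchor_mz <= hi):
            raise ParameterError(
                f"pattern anchor {entry.anchor_mz:.4f} outside the m/z range {mz_range}"
            )
        sp_params = shape_trend(entry.anchor_mz) if shape_trend is not None else params
        if sp_params is None:
            raise ParameterError("either params or shape_trend must be given")
        tpl = build_template(p.charge, entry.anchor_mz, kind, sp_params, kappa, trim_rel)
        y = y + p.height * template_profile(tpl, x)
        truth.append(entry)
    rng = np.random.default_rng(seed)
    max_height = max((p.height for p in patterns), default=1.0)
    if multiplicative_sd > 0:
        y = y * rng.lognormal(mean=0.0, sigma=multiplicative_sd, size=y.size)
    if additive_sd > 0:
        y = y + rng.normal(scale=additive_sd * max_height, size=y.size)
    y = np.clip(y, 0.0, None)
    truth.sort(key=lambda e: e.monoisotopic_mz)
    return Spectrum(mz=x, intensity=y), truth


@dataclass
class EvalResult:
    recall: float
    precision: float
    matched: np.ndarray  # flag per peaklist entry
    n_list: int
    n_truth: int


def evaluate_peaklist(peaklist, truth, delta_ppm: float = 100.0) -> EvalResult:
    """Greedy one-to-one matching of peaklist entries to truth masses.

    An entry is a true positive when a truth pattern of the same charge
    lies within ``delta_ppm`` of its monoisotopic m/z; pairs are assigned
    in order of increasing relative distance.  Precision is defined as 0
    for an empty peaklist.
    """
    if not (delta_ppm > 0):
        raise ParameterError("delta_ppm must be > 0")
    entries = list(peaklist.features if hasattr(peaklist, "features") else peaklist)
    truth = list(truth)
    pairs = []
    for i, f in enumerate(entries):
        for j, tr in enumerate(truth):
            if f.charge != tr.charge:
                continue
            ppm = abs(f.monoisotopic_mz - tr.monoisotopic_mz) / tr.monoisotopic_mz * 1e6
            if ppm <= delta_ppm:
                pairs.append((ppm, i, j))
    pairs.sort()
    used_i, used_j = set(), set()
    matched = np.zeros(len(entries), dtype=bool)
    for _, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matched[i] = True
    n_list, n_truth = len(entries), len(truth)
    recall = float(matched.sum()) / n_truth if n_truth else 1.0
    precision = float(matched.sum()) / n_list if n_list else 0.0
    return EvalResult(recall, precision, matched, n_list, n_truth)
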