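"""Model/Results interface to the full picking pipeline.

`PatternModel` holds a spectrum and the method configuration; `fit()`
executes calibration, noise estimation, template placement, the
non-negative fit, merging and scoring, and returns a `PatternFitResults`
carrying the scored features, stage diagnostics and accessors for
thresholded peaklists, a summary table and a plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationError,
    ShapeParamModel,
    detect_peak_regions,
    fit_param_trend,
    fit_peak_region,
)
from .noise import goodness_of_fit_map, local_noise_level, select_placements
from .peakshape import (
    PeakShapeKind,
    PeakShapeParams,
    Spectrum,
    assemble_template_matrix,
)
from .postprocess import (
    Peaklist,
    apply_threshold,
    group_templates,
    merge_group,
    peptide_mass_filter,
    score_features,
)
from .solvers import SolverConfig, nnlad_logbarrier, nnls_logbarrier

__all__ = ["PatternModel", "PatternFitResults"]

logger = logging.getLogger("isopick")


class PatternModel:
    """Template-matching model for one profile spectrum.

    Parameters
    ----------
    spectrum : Spectrum
        Profile-mode observation (ordered m/z, non-negative intensities).
    charges : iterable of int
        Charge states considered when placing templates.
    peak_shape : {"gaussian", "emg"}
        Single-peak model used in templates and calibration.
    q : {1, 2}
        Fitting norm: 2 = non-negative least squares, 1 = non-negative
        least absolute deviation.
    window_h : float
        Half-width (Th) of the sliding window for the local noise level
        and the goodness-of-fit statistic.
    factor_place : float
        Templates are placed where intensity > factor_place * LNL.
    merge_ppm : float
        Adjacency tolerance for merging split templates.
    kappa : float
        Isotopic spacing constant (Da), in [1.002, 1.008].
    shape_params : PeakShapeParams, optional
        Fixed shape parameters; bypasses calibration when given, and
        serves as fallback if calibration fails.
    trend_mode : {"linear", "constant"}
        Basis for the shape-parameter trends over m/z.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        charges=(1, 2, 3, 4),
        peak_shape: PeakShapeKind = PeakShapeKind.GAUSSIAN,
        q: int = 2,
        window_h: float = 2.5,
        factor_place: float = 1.5,
        merge_ppm: float = 100.0,
        kappa: float = 1.00235,
        trim_rel: float = 0.01,
        shape_params: PeakShapeParams | None = None,
        trend_mode: str = "linear",
        gof_stride: int = 1,
        solver: SolverConfig | None = None,
        detect_options: dict | None = None,
    ):
        self.spectrum = spectrum
        self.charges = tuple(sorted(int(c) for c in charges))
        self.peak_shape = PeakShapeKind(peak_shape)
        if q not in (1, 2):
            raise ValueError("q must be 1 or 2")
        self.q = int(q)
        self.window_h = float(window_h)
        self.factor_place = float(factor_place)
        self.merge_ppm = float(merge_ppm)
        self.kappa = float(kappa)
        self.trim_rel = float(trim_rel)
        self.shape_params = shape_params
        self.trend_mode = trend_mode
        self.gof_stride = int(gof_stride)
        self.solver = solver or SolverConfig()
        self.detect_options = detect_options or {}

    @classmethod
    def from_file(cls, path, format: str | None = None, **kwargs) -> "PatternModel":
        from .io import read_spectrum

        return cls(read_spectrum(path, format=format), **kwargs)

    def calibrate(self) -> ShapeParamModel:
        """Estimate m/z-dependent shape parameters from well-resolved peaks;
        falls back to the user-supplied fixed parameters on failure."""
        try:
            regions = detect_peak_regions(self.spectrum, **self.detect_options)
            fits = [fit_peak_region(self.spectrum, r, self.peak_shape) for r in regions]
            model = fit_param_trend(fits, self.peak_shape, mode=self.trend_mode)
            logger.info("calibration: %d regions, %d converged fits", len(regions), len(model.fit_pairs))
            return model
        except CalibrationError:
            if self.shape_params is not None:
                logger.warning("calibration failed; using user-supplied shape parameters")
                return ShapeParamModel.constant(self.peak_shape, self.shape_params)
            raise

    def fit(self) -> "PatternFitResults":
        """Run the full pipeline and return the fitted results object."""
        if self.shape_params is not None:
            shape_model = ShapeParamModel.constant(self.peak_shape, self.shape_params)
        else:
            shape_model = self.calibrate()
        noise = local_noise_level(self.spectrum, self.window_h)
        placements = select_placements(self.spectrum, noise, self.factor_place, self.charges)
        logger.info("placement: %d templates (%d charge states)", len(placements), len(self.charges))
        diagnostics = {
            "n_points": len(self.spectrum),
            "n_placements": len(placements),
            "n_charges": len(self.charges),
        }
        if not placements:
            return PatternFitResults(self, [], shape_model, noise, None, None, None, diagnostics)
        matrix = assemble_template_matrix(
            self.spectrum, placements, shape_model, self.kappa, self.trim_rel
        )
        solve = nnls_logbarrier if self.q == 2 else nnlad_logbarrier
        fitres = solve(matrix, self.spectrum.intensity, self.solver)
        from .postprocess import ZERO_TOL_REL

        diagnostics["n_positive"] = int(
            np.sum(fitres.beta > ZERO_TOL_REL * fitres.beta.max(initial=0.0))
        )
        logger.info("fit: objective %.6g, %d positive coefficients", fitres.objective, diagnostics["n_positive"])
        gof = goodness_of_fit_map(
            self.spectrum, shape_model, self.q, self.window_h, self.solver, self.gof_stride
        )
        groups = group_templates(fitres, matrix, self.merge_ppm)
        spacing = self.spectrum.median_spacing
        merged = [merge_group(g, shape_model, spacing) for g in groups]
        scored = score_features(merged, noise, gof, self.spectrum, self.kappa, self.trim_rel)
        diagnostics["n_groups"] = len(groups)
        diagnostics["n_features"] = len(scored)
        logger.info("postprocess: %d groups -> %d features", len(groups), len(scored))
        return PatternFitResults(
            self, scored, shape_model, noise, gof, fitres, matrix, diagnostics
        )

    def config_dict(self) -> dict:
        cfg = {
            "charges": list(self.charges),
            "peak_shape": self.peak_shape.value,
            "q": self.q,
            "window_h": self.window_h,
            "factor_place": self.factor_place,
            "merge_ppm": self.merge_ppm,
            "kappa": self.kappa,
            "trim_rel": self.trim_rel,
            "trend_mode": self.trend_mode,
        }
        if self.shape_params is not None:
            cfg["sigma"] = self.shape_params.sigma
            if self.shape_params.alpha is not None:
                cfg["alpha"] = self.shape_params.alpha
                cfg["mu"] = self.shape_params.mu
        return cfg


@dataclass
class PatternFitResults:
    """Scored features and diagnostics from one pipeline run."""

    model: PatternModel
    features: list
    shape_model: ShapeParamModel
    noise: object
    gof: object
    fit_result: object
    template_matrix: object
    diagnostics: dict = field(default_factory=dict)

    @property
    def features_frame(self) -> pd.DataFrame:
        cols = [
            "monoisotopic_mz",
            "charge",
            "neutral_mass",
            "coefficient",
            "ratio",
            "lnl_plus",
            "gof_plus",
            "location",
            "merged_from",
        ]
        rows = [[getattr(f, c) for c in cols] for f in self.features]
        frame = pd.DataFrame(rows, columns=cols)
        return frame.sort_values("monoisotopic_mz", ignore_index=True) if len(frame) else frame

    def peaklist(self, threshold: float = 5.0, mass_filter: bool = False, mass_filter_ppm: float = 200.0) -> Peaklist:
        """Threshold the scored features into a final peaklist."""
        pl = apply_threshold(self.features, threshold, metadata=self.model.config_dict())
        if mass_filter:
            pl = peptide_mass_filter(pl, mass_filter_ppm)
        return pl

    def summary(self, threshold: float = 5.0) -> str:
        """Human-readable account of the fit and the score distribution."""
        lines = ["isopick template-matching fit", "=" * 34]
        for k, v in self.diagnostics.items():
            lines.append(f"{k:>22s}: {v}")
        ratios = np.array([f.ratio for f in self.features])
        if ratios.size:
            qs = np.percentile(ratios, [50, 75, 90, 99])
            lines.append(
                "   ratio quantiles 50/75/90/99: "
                + "/".join(f"{v:.3g}" for v in qs)
            )
            lines.append(f"{'features >= t=%g' % threshold:>22s}: {int(np.sum(ratios >= threshold))}")
        frame = self.features_frame
        if len(frame):
            kept = frame[frame["ratio"] >= threshold]
            lines.append("")
            lines.append(kept.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
        return "\n".join(lines)

    def plot(self, threshold: float = 5.0, ax=None):
        """Spectrum with fitted features marked at their monoisotopic m/z."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        s = self.model.spectrum
        ax.plot(s.mz, s.intensity, lw=0.7, color="0.4", label="spectrum")
        if self.noise is not None:
            ax.plot(s.mz, self.noise.lnl_plus, lw=0.8, color="tab:orange", label="LNL+")
        for f in self.features:
            if f.ratio >= threshold:
                ax.axvline(f.monoisotopic_mz, color="tab:red", lw=0.8, alpha=0.6)
                ax.annotate(
                    f"{f.charge}+",
                    (f.location, f.coefficient),
                    textcoords="offset points",
                    xytext=(2, 2),
                    fontsize=8,
                )
        ax.set_xlabel("m/z (Th)")
        ax.set_ylabel("intensity")
        ax.legend(loc="best", fontsize=8)
        return ax
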