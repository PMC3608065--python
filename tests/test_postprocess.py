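"""Grouping, merging, scoring, thresholding and the peptide-mass filter."""

import numpy as np
import pytest

from isopick.calibration import ShapeParamModel
from isopick.noise import GofMap, NoiseModel
from isopick.peakshape import (
    PeakShapeParams,
    Spectrum,
    TemplateMatrix,
    assemble_template_matrix,
    build_template,
    template_profile,
)
from isopick.postprocess import (
    MergedFeature,
    ScoredFeature,
    TemplateGroup,
    apply_threshold,
    group_templates,
    merge_group,
    peptide_mass_filter,
    score_features,
    Peaklist,
)
from isopick.solvers import FitResult, SolverConfig, nnls_logbarrier

from .oracles import merge_grid_oracle


def _matrix_for(anchors_charges, spectrum, model):
    return assemble_template_matrix(spectrum, anchors_charges, model)


def _fit(beta):
    return FitResult(np.asarray(beta, float), 0.0, 2, 0.0, 1, True)


def _wide_spectrum():
    x = np.arange(495.0, 515.0, 0.02)
    return Spectrum(x, np.ones_like(x))


class TestGrouping:
    def test_no_positive_coefficients(self, gauss_model):
        m = _matrix_for([(1, 500.0)], _wide_spectrum(), gauss_model)
        assert group_templates(_fit([0.0]), m, 100.0) == []

    def test_within_tolerance_one_group(self, gauss_model):
        m = _matrix_for([(1, 500.0), (1, 500.020)], _wide_spectrum(), gauss_model)
        groups = group_templates(_fit([1.0, 0.5]), m, 100.0)  # gap 40 ppm
        assert len(groups) == 1
        assert groups[0].anchors.size == 2

    def test_beyond_tolerance_two_groups(self, gauss_model):
        m = _matrix_for([(1, 500.0), (1, 500.100)], _wide_spectrum(), gauss_model)
        groups = group_templates(_fit([1.0, 0.5]), m, 100.0)  # gap 200 ppm
        assert len(groups) == 2

    def test_charges_never_mix(self, gauss_model):
        m = _matrix_for([(1, 500.0), (2, 500.010)], _wide_spectrum(), gauss_model)
        groups = group_templates(_fit([1.0, 1.0]), m, 100.0)
        assert len(groups) == 2
        assert {g.charge for g in groups} == {1, 2}


class TestMerge:
    def test_singleton_passthrough(self, gauss_model):
        g = TemplateGroup(2, np.array([500.5]), np.array([1.3]), 0)
        merged = merge_group(g, gauss_model)
        assert merged.location == 500.5 and merged.coefficient == 1.3

    def test_symmetric_pair_merges_to_midpoint(self, gauss_model):
        delta = 0.005  # << sigma = 0.05
        g = TemplateGroup(1, np.array([500.0 - delta, 500.0 + delta]), np.array([0.7, 0.7]), 0)
        merged = merge_group(g, gauss_model)
        assert merged.location == pytest.approx(500.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, gauss_model):
        sigma = 0.05
        anchors = np.array([500.0, 500.0 + 0.3 * sigma])
        coefs = np.array([0.6, 0.4])
        merged = merge_group(TemplateGroup(1, anchors, coefs, 0), gauss_model)
        obj, m_star, b_star = merge_grid_oracle(
            anchors, coefs, sigma, anchors[0] - 6 * sigma, anchors[1] + 6 * sigma
        )
        assert merged.location == pytest.approx(m_star, abs=sigma / 400)
        assert merged.coefficient == pytest.approx(b_star, rel=5e-3)
        # the continuous optimum is at least as good as any lattice point
        grid = np.arange(anchors[0] - 6 * sigma, anchors[1] + 6 * sigma, sigma / 40)
        target = sum(
            b * np.exp(-0.5 * ((grid - a) / sigma) ** 2) for a, b in zip(anchors, coefs)
        )
        ours = np.sum(
            (merged.coefficient * np.exp(-0.5 * ((grid - merged.location) / sigma) ** 2) - target) ** 2
        )
        assert ours <= obj * (1 + 1e-9)


class TestPeakSplittingRepair:
    def test_flanking_templates_collapse_to_truth(self, gauss_model):
        # apex sampled midway between grid points; two templates at the
        # flanking data both receive weight and merge back to the truth
        spacing = 0.02
        x = np.arange(995.0, 1006.0 + spacing / 2, spacing)
        sigma = 0.05
        anchor_true = 1000.0 + spacing / 2
        tpl = build_template(1, anchor_true, "gaussian", PeakShapeParams(sigma=sigma))
        y = 1.0 * template_profile(tpl, x)
        spec = Spectrum(x, y)
        i = int(np.searchsorted(x, anchor_true))
        matrix = assemble_template_matrix(spec, [(1, x[i - 1]), (1, x[i])], gauss_model)
        fit = nnls_logbarrier(matrix, y, SolverConfig(gamma_max=1e10))
        assert np.all(fit.beta > 0.1)  # both flanking templates carry weight
        groups = group_templates(fit, matrix, 100.0)
        assert len(groups) == 1
        merged = merge_group(groups[0], gauss_model, spacing)
        assert abs(merged.location - anchor_true) < 0.1 * spacing
        assert merged.coefficient == pytest.approx(1.0, rel=0.02)


class TestScoring:
    def _score_env(self, n=50):
        x = np.linspace(100.0, 105.0, n)
        spec = Spectrum(x, np.ones(n))
        noise = NoiseModel(h=1.0, lnl=np.full(n, 2.0), lnl_plus=np.full(n, 2.0), global_floor=0.5)
        gof = GofMap(residuals=np.zeros(n), gof_plus=np.full(n, 0.5), q=2)
        return spec, noise, gof

    def test_ratio_arithmetic(self, gauss_model):
        spec, noise, gof = self._score_env()
        feature = MergedFeature(2, 102.0, 10.0, None)
        scored = score_features([feature], noise, gof, spec)[0]
        assert scored.ratio == pytest.approx(0.5 * 10.0 / 2.0)

    def test_low_mass_monoisotopic_equals_location(self, gauss_model):
        spec, noise, gof = self._score_env()
        # neutral mass ~700 Da at charge 2: monoisotopic peak is the anchor
        feature = MergedFeature(2, 351.2, 5.0, None)
        scored = score_features([feature], noise, gof, spec)[0]
        assert scored.monoisotopic_mz == pytest.approx(351.2)
        assert scored.neutral_mass == pytest.approx(2 * 351.2 - 2 * 1.0072765, abs=1e-6)

    def test_high_mass_shifts_to_monoisotopic(self, gauss_model):
        spec, noise, gof = self._score_env()
        # neutral ~2000 Da: most intense isotopic peak is k=1
        feature = MergedFeature(1, 2001.0, 5.0, None)
        scored = score_features([feature], noise, gof, spec, kappa=1.00235)[0]
        assert scored.monoisotopic_mz == pytest.approx(2001.0 - 1.00235)


class TestThreshold:
    def _features(self, ratios):
        return [
            ScoredFeature(1, 100.0 + i, 1.0, r, 0.5, 1.0, 100.0 + i, 99.0 + i)
            for i, r in enumerate(ratios)
        ]

    def test_zero_keeps_all_inf_keeps_none(self):
        feats = self._features([0.5, 2.0, 10.0])
        assert len(apply_threshold(feats, 0.0)) == 3
        assert len(apply_threshold(feats, np.inf)) == 0

    def test_monotone_in_threshold(self):
        feats = self._features([0.1, 0.5, 1.0, 2.0, 5.0, 50.0])
        sizes = [len(apply_threshold(feats, t)) for t in (0.0, 0.3, 1.0, 3.0, 10.0, 100.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_sorted_by_mz(self):
        feats = self._features([5.0, 5.0, 5.0])[::-1]
        out = apply_threshold(feats, 1.0)
        mzs = [f.monoisotopic_mz for f in out]
        assert mzs == sorted(mzs)


class TestMassFilter:
    def _peaklist(self, masses):
        feats = [
            ScoredFeature(1, m, 1.0, 5.0, 0.5, 1.0, m, m, 1)
            for m in masses
        ]
        for f, m in zip(feats, masses):
            f.neutral_mass = m
        return Peaklist(features=feats, threshold=5.0)

    def test_on_center_kept(self):
        # 1.000485 * 700 + 0.029 = 700.3685 exactly
        out = peptide_mass_filter(self._peaklist([700.3685]), 200.0)
        assert len(out) == 1

    def test_off_center_removed(self):
        out = peptide_mass_filter(self._peaklist([700.85]), 200.0)
        assert len(out) == 0

    def test_infinite_tolerance_identity(self):
        pl = self._peaklist([700.3685, 700.85, 1234.5])
        assert len(peptide_mass_filter(pl, np.inf)) == 3
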