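"""Peak shapes, averagine distributions, templates and the design matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isopick.peakshape import (
    ParameterError,
    PeakShapeKind,
    PeakShapeParams,
    Spectrum,
    assemble_template_matrix,
    averagine_distribution,
    build_template,
    eval_emg,
    eval_gaussian,
    peptide_monoisotopic_mz,
    template_profile,
)
from isopick.calibration import ShapeParamModel
from isopick._chem import PROTON_MASS, deamidation_mass_shift

from .oracles import averagine_bruteforce, emg_mpmath


class TestGaussian:
    def test_unit_height_and_inflection(self):
        assert eval_gaussian(np.array([10.0]), 10.0, 0.1)[0] == 1.0
        np.testing.assert_allclose(
            eval_gaussian(np.array([10.1, 9.9]), 10.0, 0.1), np.exp(-0.5), rtol=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(d=st.floats(-5, 5), sigma=st.floats(0.01, 2.0))
    def test_symmetry(self, d, sigma):
        left, right = eval_gaussian(np.array([-d, d]), 0.0, sigma)
        assert left == pytest.approx(right, rel=1e-12)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ParameterError):
            eval_gaussian(np.array([1.0]), 1.0, 0.0)


class TestEMG:
    def test_matches_high_precision_oracle(self):
        params = PeakShapeParams(sigma=0.1, alpha=0.05, mu=0.0)
        for d in (0.0, 0.05, -0.1, 0.3):
            ours = eval_emg(np.array([d]), 0.0, params)[0]
            ref = emg_mpmath(d, 0.05, 0.1, 0.0)
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_integrates_to_one(self):
        params = PeakShapeParams(sigma=0.1, alpha=0.07, mu=0.02)
        x = np.linspace(-3, 4, 200001)
        vals = eval_emg(x, 0.0, params)
        assert np.trapezoid(vals, x) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_limit(self):
        # vanishing tailing: max-normalized EMG approaches the unit Gaussian
        sigma = 0.1
        params = PeakShapeParams(sigma=sigma, alpha=1e-4 * sigma, mu=0.0)
        x = np.linspace(-6 * sigma, 6 * sigma, 2001)
        emg = eval_emg(x, 0.0, params)
        emg = emg / emg.max()
        gauss = eval_gaussian(x, 0.0, sigma)
        assert np.max(np.abs(emg - gauss)) < 1e-4

    def test_stable_for_extreme_sigma_alpha_ratio(self):
        params = PeakShapeParams(sigma=1.0, alpha=1e-4, mu=0.0)
        vals = eval_emg(np.linspace(-5, 5, 101), 0.0, params)
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)


class TestAveragine:
    def test_monoisotopic_dominant_below_1800(self):
        assert averagine_distribution(700.0).most_intense_index == 0

    @pytest.mark.parametrize("mass", [500.0, 1000.0, 2000.0, 4000.0])
    def test_matches_bruteforce_convolution(self, mass):
        ours = averagine_distribution(mass, trim_rel=0.0).weights
        ref = averagine_bruteforce(mass)
        n = min(ours.size, ref.size)
        np.testing.assert_allclose(ours[:n], ref[:n], atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(mass=st.floats(300, 5000))
    def test_normalization_contract(self, mass):
        dist = averagine_distribution(mass)
        assert np.all(dist.weights >= 0)
        assert dist.weights.max() == pytest.approx(1.0)
        assert dist.weights[dist.most_intense_index] == dist.weights.max()

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ParameterError):
            averagine_distribution(-5.0)


class TestTemplate:
    def test_center_spacing_charge1(self):
        tpl = build_template(1, 700.4, "gaussian", PeakShapeParams(sigma=0.05), kappa=1.00235)
        np.testing.assert_allclose(np.diff(tpl.peak_centers), 1.00235, atol=1e-9)

    def test_center_spacing_charge2(self):
        tpl = build_template(2, 700.4, "gaussian", PeakShapeParams(sigma=0.05), kappa=1.00235)
        np.testing.assert_allclose(np.diff(tpl.peak_centers), 0.501175, atol=1e-9)

    def test_low_mass_anchor_is_monoisotopic(self):
        # neutral mass ~700 Da: the monoisotopic peak is the most intense,
        # so no centers lie left of the anchor
        tpl = build_template(2, 351.2, "gaussian", PeakShapeParams(sigma=0.05))
        assert tpl.weights.most_intense_index == 0
        assert tpl.peak_centers[0] == pytest.approx(tpl.anchor_mz)

    @pytest.mark.parametrize("kind,params", [
        ("gaussian", PeakShapeParams(sigma=0.05)),
        ("emg", PeakShapeParams(sigma=0.05, alpha=0.03, mu=0.01)),
    ])
    def test_max_normalization(self, kind, params):
        tpl = build_template(2, 900.0, kind, params)
        lo, hi = tpl.support
        grid = np.arange(lo, hi, params.sigma / 50)
        assert np.max(template_profile(tpl, grid)) == pytest.approx(1.0, abs=1e-3)


class TestTemplateMatrix:
    def _spectrum(self):
        x = np.arange(690.0, 715.0, 0.01)
        return Spectrum(x, np.ones_like(x))

    def test_columns_normalized_and_nonnegative(self, gauss_model):
        spec = self._spectrum()
        m = assemble_template_matrix(spec, [(1, 700.0), (2, 705.0)], gauss_model)
        assert m.columns.min() >= 0
        # the grid contains the exact centers, so sampled maxima reach 1
        col_max = m.columns.max(axis=0).toarray().ravel()
        np.testing.assert_allclose(col_max, 1.0, atol=1e-3)

    def test_contiguous_support(self, gauss_model):
        spec = self._spectrum()
        m = assemble_template_matrix(spec, [(2, 700.0)], gauss_model)
        rows = m.columns.indices
        assert np.array_equal(rows, np.arange(rows[0], rows[-1] + 1))

    def test_disjoint_supports_block_diagonal_gram(self, gauss_model):
        spec = self._spectrum()
        m = assemble_template_matrix(spec, [(1, 695.0), (1, 712.0)], gauss_model)
        gram = (m.columns.T @ m.columns).toarray()
        assert gram[0, 1] == 0 and gram[1, 0] == 0

    def test_gram_bandwidth_matches_overlap(self, gauss_model):
        spec = self._spectrum()
        anchors = [(1, a) for a in np.arange(698.0, 706.0, 1.0)]
        m = assemble_template_matrix(spec, anchors, gauss_model)
        gram = (m.columns.T @ m.columns).toarray()
        nz = np.nonzero(gram)
        bandwidth = int(np.max(np.abs(nz[0] - nz[1])))
        # bandwidth equals the number of templates whose supports overlap
        supports = []
        for j in range(m.columns.shape[1]):
            rows = m.columns.indices[m.columns.indptr[j]:m.columns.indptr[j + 1]]
            supports.append((rows[0], rows[-1]))
        expected = max(
            sum(1 for (s2, e2) in supports if s2 <= e1 and e2 >= s1) - 1
            for (s1, e1) in supports
        )
        assert bandwidth <= expected

    def test_permuted_placements_same_matrix(self, gauss_model):
        spec = self._spectrum()
        pl = [(1, 700.0), (2, 703.0), (1, 705.0)]
        m1 = assemble_template_matrix(spec, pl, gauss_model)
        m2 = assemble_template_matrix(spec, pl[::-1], gauss_model)
        assert (m1.columns != m2.columns).nnz == 0
        assert m1.block_index == m2.block_index

    def test_rejects_empty_and_out_of_range(self, gauss_model):
        spec = self._spectrum()
        with pytest.raises(ParameterError):
            assemble_template_matrix(spec, [], gauss_model)
        with pytest.raises(ParameterError, match="9999"):
            assemble_template_matrix(spec, [(1, 9999.0)], gauss_model)


class TestPeptideMass:
    @pytest.mark.parametrize("seq,charge,expected", [
        ("GACLLPK", 2, 351.20437),
        ("CCTKPESER", 3, 351.48816),
        ("VLASSAR", 2, 352.20850),
    ])
    def test_reference_peptides(self, seq, charge, expected):
        assert peptide_monoisotopic_mz(seq, charge) == pytest.approx(expected, abs=1e-5)

    def test_unknown_residue_named(self):
        with pytest.raises(ParameterError, match="'B'"):
            peptide_monoisotopic_mz("GABK", 1)

    def test_carbamidomethyl_flag(self):
        plain = peptide_monoisotopic_mz("GACLLPK", 2)
        mod = peptide_monoisotopic_mz("GACLLPK", 2, carbamidomethyl=True)
        assert mod - plain == pytest.approx(57.021464 / 2, abs=1e-6)


def test_deamidation_shift_value():
    assert round(deamidation_mass_shift(), 2) == 0.98
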