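"""Model algebra: categories, Lambda_k, parameter counts, reduced form,
Willham conversion and derived genetic parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calvingsem.core import (
    DispersionSet, GLCategoryMap, StructuralCoefficients, Thresholds,
    build_lambda, count_free_parameters, genetic_parameters, gl_category,
    overall_effect_sb_from_gl, reduced_form_covariances, variant_masks,
    willham_inverse, willham_transform,
)


@pytest.mark.parametrize("days,expected", [
    (265, 1), (267, 1), (268, 2), (273, 2), (274, 3), (279, 3), (280, 4),
    (291, 4), (240, 1), (310, 4),
])
def test_gl_category_boundaries_belong_to_lower_class(days, expected):
    assert gl_category(days) == expected


def test_category_map_validation():
    with pytest.raises(ValueError):
        GLCategoryMap((273, 267))


def _coeffs(cd_gl=0.0, sb_gl=0.0, sb_cd=0.0, n=4):
    return StructuralCoefficients(np.full(n, cd_gl), np.full(n, sb_gl),
                                  np.full(n, sb_cd))


class TestBuildLambda:
    def test_zero_recursion_is_identity(self):
        assert np.array_equal(build_lambda(_coeffs(), 2), np.eye(3))

    def test_layout_matches_structural_system(self):
        # rates for mid-range gestations: CD<-GL 0.020, SB<-CD 0.331
        c = _coeffs(cd_gl=0.020, sb_gl=-0.02762, sb_cd=0.331)
        lam = build_lambda(c, 2)
        expected = np.array([[1, 0, 0], [-0.020, 1, 0], [0.02762, -0.331, 1]])
        assert np.allclose(lam, expected)

    def test_inverse_accumulates_indirect_effect(self):
        a = -0.02762
        c = _coeffs(cd_gl=0.020, sb_gl=a, sb_cd=0.331)
        inv = np.linalg.inv(build_lambda(c, 2))
        assert np.allclose(np.diag(inv), 1.0)
        assert inv[2, 0] == pytest.approx(a + 0.020 * 0.331)

    @given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_unit_determinant_and_recursion_free_gl_row(self, lams):
        c = _coeffs(*lams)
        lam = build_lambda(c, 1)
        assert np.linalg.det(lam) == pytest.approx(1.0)
        assert np.array_equal(lam[0], [1.0, 0.0, 0.0])

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            build_lambda(_coeffs(), 5)


class TestOverallEffect:
    def test_zero_when_gl_paths_absent(self):
        assert overall_effect_sb_from_gl(_coeffs(sb_cd=0.9), 1) == 0.0

    def test_direct_plus_mediated(self):
        c = _coeffs(cd_gl=0.020, sb_gl=-0.02762, sb_cd=0.331)
        assert overall_effect_sb_from_gl(c, 2) == pytest.approx(-0.021, abs=5e-4)

    @given(st.floats(-0.3, 0.3), st.floats(-1.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_matches_lambda_inverse_entry(self, cd_gl, sb_cd):
        c = _coeffs(cd_gl=cd_gl, sb_gl=0.05, sb_cd=sb_cd)
        inv = np.linalg.inv(build_lambda(c, 3))
        assert overall_effect_sb_from_gl(c, 3) == pytest.approx(inv[2, 0])


@pytest.mark.parametrize("variant,expected", [
    ("RMM1", 41), ("RMM2", 38), ("RMM3", 26), ("SMM", 32),
])
def test_free_parameter_counts(variant, expected):
    assert count_free_parameters(variant) == expected


def test_count_rejects_unknown_variant():
    with pytest.raises(ValueError):
        count_free_parameters("RMM9")


def _rmm3_dispersion():
    g0 = np.zeros((6, 6))
    for t, (s, m, c) in enumerate([(2.0, 1.0, 0.7), (0.02, 0.02, 0.008),
                                   (0.015, 0.02, 0.006)]):
        g0[t, t], g0[t + 3, t + 3] = s, m
        g0[t, t + 3] = g0[t + 3, t] = c
    return DispersionSet(g0, np.diag([2.0, 0.03, 0.03]),
                         np.diag([18.0, 0.8, 1.0]), variant="RMM3")


class TestReducedForm:
    def test_identity_at_zero_recursion(self):
        disp = _rmm3_dispersion()
        g, h, r = reduced_form_covariances(disp, _coeffs(), 2)
        assert np.allclose(g, disp.G0)
        assert np.allclose(h, disp.H0)
        assert np.allclose(r, disp.R0)

    def test_triangular_propagation_of_gl_variance(self):
        # only CD<-GL active: reduced residual (GL, CD) entry = c * r_GL
        c_val = 0.03
        disp = _rmm3_dispersion()
        _, _, r = reduced_form_covariances(disp, _coeffs(cd_gl=c_val), 1)
        assert r[0, 1] == pytest.approx(c_val * disp.R0[0, 0])
        assert r[1, 1] == pytest.approx(disp.R0[1, 1] + c_val ** 2 * disp.R0[0, 0])

    @given(st.floats(-0.3, 0.3), st.floats(-0.3, 0.3), st.floats(-0.8, 0.8))
    @settings(deadline=None, max_examples=40)
    def test_congruence_preserves_positive_definiteness(self, a, b, c):
        disp = _rmm3_dispersion()
        g, h, r = reduced_form_covariances(disp, _coeffs(a, b, c), 4)
        for m in (g, h, r):
            assert np.linalg.eigvalsh(m).min() > 0


class TestWillham:
    def test_per_trait_identities(self):
        s0 = np.diag([1.0, 1.0, 1.0])
        m0 = np.diag([1.0, 1.0, 1.0])
        c = np.diag([0.5, 0.5, 0.5])
        wp = willham_transform(s0, m0, c)
        assert np.allclose(np.diag(wp.direct), 4.0)
        assert np.allclose(np.diag(wp.direct_maternal), 0.0)
        assert np.allclose(np.diag(wp.maternal), 3.0)

    def test_zero_maps_to_zero(self):
        wp = willham_transform(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))
        assert not wp.direct.any() and not wp.maternal.any()
        assert not wp.direct_maternal.any()

    def test_recovers_maternal_variance_from_forward_map(self):
        # build sire/MGS components from known direct/maternal truth
        var_d, var_m = 1.6, 0.9
        s0 = np.diag([var_d / 4, 0.1, 0.1])
        c = np.diag([var_d / 8, 0.02, 0.02])       # sigma_dm = 0
        m0 = np.diag([var_d / 16 + var_m / 4, 0.05, 0.05])
        wp = willham_transform(s0, m0, c)
        assert wp.direct[0, 0] == pytest.approx(var_d)
        assert wp.maternal[0, 0] == pytest.approx(var_m)
        assert wp.direct_maternal[0, 0] == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_round_trip_through_inverse(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 6))
        g = a @ a.T + 0.5 * np.eye(6)
        s0, m0, c = g[:3, :3], g[3:, 3:], g[:3, 3:]
        back = willham_inverse(willham_transform(s0, m0, c))
        for orig, rec in zip((s0, m0, c), back):
            assert np.allclose(orig, rec, atol=1e-10)


class TestGeneticParameters:
    def test_direct_heritability_arithmetic(self):
        g0 = np.zeros((6, 6))
        g0[0, 0], g0[3, 3] = 0.25, 0.0625
        g0[0, 3] = g0[3, 0] = 0.125
        g0[1, 1] = g0[4, 4] = 0.05
        g0[2, 2] = g0[5, 5] = 0.05
        disp = DispersionSet(g0, np.diag([0.1, 0.1, 0.1]),
                             np.diag([1.0, 1.0, 1.0]), variant="RMM3")
        s = genetic_parameters(disp, StructuralCoefficients.zeros(4), 1)
        assert s.phenotypic_var[0] == pytest.approx(1.4375)
        assert s.h2_direct[0] == pytest.approx(4 * 0.25 / 1.4375)

    def test_category_invariance_without_recursion(self):
        disp = _rmm3_dispersion()
        summaries = [genetic_parameters(disp, StructuralCoefficients.zeros(4), k)
                     for k in range(1, 5)]
        for s in summaries[1:]:
            assert np.allclose(s.h2_direct, summaries[0].h2_direct)
            assert np.allclose(s.corr_direct, summaries[0].corr_direct)

    def test_diagonal_g0_gives_zero_genetic_correlations(self):
        disp = _rmm3_dispersion()
        s = genetic_parameters(disp, StructuralCoefficients.zeros(4), 1)
        off = s.corr_direct[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_bounds_on_h2_and_correlations(self, small_dataset):
        disp = _rmm3_dispersion()
        s = genetic_parameters(disp, _coeffs(0.02, -0.03, 0.33), 3)
        assert np.all((s.h2_direct >= 0) & (s.h2_direct <= 1))
        assert np.all(np.abs(s.corr_direct) <= 1)
        assert np.all(np.abs(s.corr_residual) <= 1)


class TestDispersionSet:
    def test_variant_mask_enforced(self):
        g0 = np.eye(6)
        h0 = np.eye(3)
        r0 = np.eye(3)
        r0[0, 1] = r0[1, 0] = 0.3
        with pytest.raises(ValueError, match="constraint mask"):
            DispersionSet(g0, h0, r0, variant="RMM1")

    def test_sb_residual_variance_fixed(self):
        with pytest.raises(ValueError, match="fixed at 1"):
            DispersionSet(np.eye(6), np.eye(3), np.diag([1.0, 1.0, 2.0]),
                          variant="RMM3")

    def test_masks_nested_by_restrictiveness(self):
        m1 = variant_masks("RMM1")
        m3 = variant_masks("RMM3")
        assert (~m1["R0"] | ~m3["R0"]).sum() >= 0
        assert m3["G0"].sum() < m1["G0"].sum()


def test_thresholds_fixing_rules():
    with pytest.raises(ValueError):
        Thresholds(np.array([0.5, 1.0]))
    t = Thresholds.default(5)
    assert t.n_free == 2
    assert t.cd[0] == 0.0 and t.cd[1] == 1.0
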