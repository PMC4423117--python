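"""Reaction network: regulation function, reaction terms, fixed point."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import root

import dvpattern as dv
from tests.conftest import draw_table2_parameters


@pytest.fixture
def p():
    return dv.ModelParameters()


class TestSogExpressionRate:
    @pytest.mark.parametrize("b, d, expected", [
        (0.0, 0.0, 2.8e-4),            # basal rate with no inputs
        (0.2, 0.0, 1.4e-4),            # half-maximal repression at b = b0
        (0.0, 1.0, (2.8e-4 + 2e-3) / 2),  # midpoint activation at d = d0
    ])
    def test_printed_values(self, p, b, d, expected):
        assert dv.sog_expression_rate(b, d, p) == pytest.approx(expected, rel=1e-12)

    def test_full_repression_limit(self, p):
        assert dv.sog_expression_rate(1e12, 5.0, p) < 1e-14

    def test_monotone_in_both_arguments(self, p):
        b = np.linspace(0, 3, 100)[:, None]
        d = np.linspace(0, 3, 100)[None, :]
        rate = dv.sog_expression_rate(np.broadcast_to(b, (100, 100)),
                                      np.broadcast_to(d, (100, 100)), p)
        assert (np.diff(rate, axis=0) < 0).all()   # decreasing in BMP
        assert (np.diff(rate, axis=1) > 0).all()   # increasing in Dorsal
        assert rate.max() < p.eta1
        assert rate.min() > 0

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            dv.sog_expression_rate(-0.1, 0.0, p)
        with pytest.raises(ValueError):
            dv.sog_expression_rate(0.0, -1e-9, p)


class TestReactionTerms:
    def test_zero_state(self, p):
        f_s, f_b, f_c = dv.reaction_terms(0.0, 0.0, 0.0, 0.0, p)
        assert f_s == pytest.approx(p.eta0)
        assert f_b == pytest.approx(p.eta_b)
        assert f_c == 0.0

    def test_hand_evaluation_at_reference_initial_state(self, p):
        # term-by-term arithmetic at the standard starting concentrations
        s, b, c = 0.01, 0.32, 0.14
        bind = 5.0 * s * b
        eta = 2.8e-4 / (1 + b / 0.2)
        exp_fs = eta - bind + 5e-5 * c - 2e-3 * s
        exp_fb = 4e-5 - bind + 5e-5 * c + 2e-3 * c - 5e-5 * b
        exp_fc = bind - 5e-5 * c - 2e-3 * c
        f_s, f_b, f_c = dv.reaction_terms(s, b, c, 0.0, p)
        assert f_s == pytest.approx(exp_fs, rel=1e-12)
        assert f_b == pytest.approx(exp_fb, rel=1e-12)
        assert f_c == pytest.approx(exp_fc, rel=1e-12)

    @pytest.mark.parametrize("d", [0.0, 0.3, 1.0, 7.5])
    def test_vanishes_at_fixed_point(self, p, d):
        sbar, bbar, cbar = dv.homogeneous_fixed_point(d, p)
        rates = dv.reaction_terms(sbar, bbar, cbar, d, p)
        assert max(abs(r) for r in rates) < 1e-12


class TestHomogeneousFixedPoint:
    def test_bmp_level_is_production_over_decay(self, p):
        for d in (0.0, 0.5, 2.0):
            _, bbar, _ = dv.homogeneous_fixed_point(d, p)
            assert bbar == pytest.approx(0.8, rel=1e-14)

    def test_reference_values_at_zero_dorsal(self, p):
        sbar, bbar, cbar = dv.homogeneous_fixed_point(0.0, p)
        assert sbar == pytest.approx(1.43e-5, rel=5e-3)
        assert cbar == pytest.approx(2.80e-2, rel=5e-3)

    def test_no_bmp_production_limit(self, p):
        # with eta_b = 0 the BMP branch empties and Sog balances its decay
        pp = p.with_overrides(eta_b=0.0)
        sbar, bbar, cbar = dv.homogeneous_fixed_point(0.0, pp)
        assert (sbar, bbar, cbar) == pytest.approx((0.14, 0.0, 0.0), rel=1e-12)

    def test_no_bmp_sink_is_an_error(self, p):
        with pytest.raises(ValueError, match="alpha_b"):
            dv.homogeneous_fixed_point(0.0, p.with_overrides(alpha_b=0.0))

    def test_residual_small_over_random_parameter_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pp, d = draw_table2_parameters(rng)
            fp = dv.homogeneous_fixed_point(d, pp)
            rates = dv.reaction_terms(*fp, d, pp)
            assert max(abs(r) for r in rates) < 1e-12

    def test_agrees_with_numeric_root_finder(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pp, d = draw_table2_parameters(rng)
            fp = np.array(dv.homogeneous_fixed_point(d, pp))
            sol = root(lambda u: dv.reaction_terms(*np.abs(u), d, pp),
                       fp * (1 + 1e-3), method="hybr")
            assert np.abs(np.abs(sol.x) - fp).max() <= 1e-8 * np.abs(fp).max()


class TestParameterValidation:
    def test_reference_defaults_match_published_table(self, p):
        assert (p.eta0, p.eta1, p.b0, p.d0) == (2.8e-4, 2e-3, 0.2, 1.0)
        assert (p.eta_b, p.alpha_s, p.alpha_b, p.alpha_c) == (4e-5, 2e-3, 5e-5, 2e-4)
        assert (p.k_plus, p.k_minus) == (5.0, 5e-5)
        assert (p.D_s, p.D_b, p.D_c) == (1.5e-13, 7.8e-13, 2.5e-9)
        assert (p.l_x, p.l_y) == (0.0017, 0.002)

    def test_complex_diffuses_fastest(self, p):
        assert p.D_c > p.D_b > p.D_s

    @pytest.mark.parametrize("bad", [
        {"eta1": 1e-4},          # activation must exceed basal rate
        {"alpha_s": -1e-3},
        {"D_c": float("nan")},
        {"complex_cleavage_rate": "alpha_x"},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            dv.ModelParameters(**bad)

    def test_cleavage_switch(self, p):
        assert p.cleavage == p.alpha_s
        pv = p.with_overrides(complex_cleavage_rate="alpha_c")
        assert pv.cleavage == pv.alpha_c
        # fixed point still exact under the variant
        fp = dv.homogeneous_fixed_point(0.4, pv)
        assert max(abs(r) for r in dv.reaction_terms(*fp, 0.4, pv)) < 1e-12


class TestEtaBar:
    def test_saturates_at_eta1(self, p):
        assert dv.eta_bar(1e9, p) == pytest.approx(p.eta1, rel=1e-8)

    def test_midpoint_at_d0(self, p):
        assert dv.eta_bar(p.d0, p) == pytest.approx((p.eta0 + p.eta1) / 2)

    @given(st.floats(min_value=2.9e-4, max_value=1.9e-3))
    def test_inversion_roundtrip(self, value):
        p = dv.ModelParameters()
        d = dv.dorsal_for_eta_bar(value, p)
        assert dv.eta_bar(d, p) == pytest.approx(value, rel=1e-12)

    def test_inversion_domain(self, p):
        with pytest.raises(ValueError):
            dv.dorsal_for_eta_bar(p.eta1, p)
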