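"""Analytic identities of the subjective-value equations and choice rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordrisk import (
    HyperpriorSettings,
    SubjectParams,
    choice_prob_logistic,
    choice_prob_trembling,
    prior_mean_alpha,
    sv_classic,
    sv_estimated,
    sv_fixed,
)

PRINTED_INCREMENTS = (7.22, 4.13, 6.23, 8.77)


class TestSvClassic:
    @pytest.mark.parametrize(
        "P, A, V, alpha, beta, expected",
        [
            (1.0, 0.0, 5.0, 1.0, 0.65, 5.0),  # certainty, linear utility
            (0.5, 0.0, 25.0, 1.0, 0.0, 12.5),  # plain expected value
            (0.5, 0.74, 8.0, 0.72, 1.0, 0.13 * 8.0**0.72),
            (0.5, 0.5, 12.0, 0.8, -0.4, (0.5 + 0.1) * 12.0**0.8),
        ],
    )
    def test_values(self, P, A, V, alpha, beta, expected):
        assert sv_classic(P, A, V, alpha, beta) == pytest.approx(expected, rel=1e-12)

    @given(
        P=st.sampled_from([0.25, 0.5, 0.75]),
        V=st.floats(5.0, 25.0),
        alpha=st.floats(0.1, 1.6),
    )
    @settings(deadline=None)
    def test_no_ambiguity_reduces_to_expected_utility(self, P, V, alpha):
        assert sv_classic(P, 0.0, V, alpha, 1.3) == pytest.approx(P * V**alpha)

    @given(
        A=st.sampled_from([0.24, 0.5, 0.74]),
        V=st.floats(5.0, 25.0),
        alpha=st.floats(0.1, 1.6),
    )
    @settings(deadline=None)
    def test_beta_zero_ignores_ambiguity(self, A, V, alpha):
        assert sv_classic(0.5, A, V, alpha, 0.0) == pytest.approx(
            sv_classic(0.5, 0.0, V, alpha, 0.0)
        )

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            sv_classic(0.0, 0.0, 5.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            sv_classic(0.5, 1.5, 5.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            sv_classic(0.5, 0.0, -5.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            sv_classic(0.5, 0.0, 5.0, 0.0, 0.0)


class TestSvEstimated:
    def test_certain_option_is_first_increment(self):
        assert sv_estimated(1.0, 0.0, 1, PRINTED_INCREMENTS, 0.9) == pytest.approx(7.22)

    def test_level_three_is_cumulative_sum(self):
        assert sv_estimated(1.0, 0.0, 3, PRINTED_INCREMENTS, 0.0) == pytest.approx(
            7.22 + 4.13 + 6.23
        )

    def test_full_ambiguity_cancels_probability_term(self):
        # P - beta*A/2 = 0.5 - 0.5 = 0 at A=1, beta=1
        assert sv_estimated(0.5, 1.0, 2, PRINTED_INCREMENTS, 1.0) == pytest.approx(0.0)

    @given(
        nu=st.tuples(*[st.floats(0.0, 20.0)] * 4),
        beta=st.floats(-1.5, 1.5),
    )
    @settings(deadline=None)
    def test_nondecreasing_in_level(self, nu, beta):
        vals = [sv_estimated(0.5, 0.0, lvl, nu, beta) for lvl in (1, 2, 3, 4)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_agrees_with_classic_on_matched_values(self):
        # increments chosen so cumulative values equal V^alpha pointwise
        alpha, beta = 0.8, 0.4
        amounts = np.array([5.0, 8.0, 12.0, 25.0])
        cumulative = amounts**alpha
        nu = np.diff(np.concatenate([[0.0], cumulative]))
        for lvl, V in zip((1, 2, 3, 4), amounts):
            for P, A in [(0.25, 0.0), (0.5, 0.5), (0.75, 0.0)]:
                assert sv_estimated(P, A, lvl, nu, beta) == pytest.approx(
                    sv_classic(P, A, V, alpha, beta)
                )

    def test_rejects_bad_level_and_negative_increments(self):
        with pytest.raises(ValueError):
            sv_estimated(0.5, 0.0, 5, PRINTED_INCREMENTS, 0.0)
        with pytest.raises(ValueError):
            sv_estimated(0.5, 0.0, 2, (1.0, -0.1, 1.0, 1.0), 0.0)


class TestSvFixed:
    @pytest.mark.parametrize(
        "P, A, level, expected",
        [(1.0, 0.0, 2, 2.0), (0.75, 0.0, 4, 3.0), (0.5, 0.5, 4, 1.0)],
    )
    def test_values(self, P, A, level, expected):
        assert sv_fixed(P, A, level) == pytest.approx(expected)


class TestChoiceRules:
    def test_indifference_gives_half(self):
        assert choice_prob_logistic(3.3, 3.3, 2.0) == pytest.approx(0.5)
        assert choice_prob_trembling(3.3, 3.3, 0.0) == pytest.approx(0.5)

    def test_logistic_scalar_value(self):
        assert choice_prob_logistic(5.0, 6.0, 1.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0))
        )

    def test_dominance_limits_are_stable(self):
        assert choice_prob_logistic(0.0, 1e6, 1.0) == pytest.approx(1.0)
        assert choice_prob_logistic(1e6, 0.0, 1.0) == pytest.approx(0.0)
        assert np.isfinite(choice_prob_logistic(-1e8, 1e8, 10.0))

    def test_trembling_bounds(self):
        assert choice_prob_trembling(0.0, 1e9, 0.2) == pytest.approx(0.9)
        assert choice_prob_trembling(1e9, 0.0, 0.2) == pytest.approx(0.1)
        assert choice_prob_trembling(0.0, 123.0, 1.0) == pytest.approx(0.5)

    @given(
        d1=st.floats(-5, 5),
        d2=st.floats(-5, 5),
        gamma=st.floats(0.1, 10.0),
        delta=st.floats(0.0, 0.9),
    )
    @settings(deadline=None)
    def test_monotone_in_sv_difference(self, d1, d2, gamma, delta):
        lo, hi = sorted([d1, d2])
        assert choice_prob_logistic(0.0, lo, gamma) <= choice_prob_logistic(
            0.0, hi, gamma
        )
        assert choice_prob_trembling(0.0, lo, delta) <= choice_prob_trembling(
            0.0, hi, delta
        )

    def test_high_inverse_temperature_approaches_step(self):
        assert choice_prob_logistic(5.0, 5.1, 1e4) > 0.999
        assert choice_prob_logistic(5.1, 5.0, 1e4) < 0.001


class TestHyperpriors:
    def test_prior_mean_alpha_default(self):
        # closed form 2*4/(4+7) = 8/11, slight risk aversion
        assert prior_mean_alpha() == pytest.approx(8.0 / 11.0)
        assert abs(prior_mean_alpha() - 0.72) < 0.01

    @pytest.mark.parametrize("loc1, loc2", [(1.0, 1.0), (4.0, 4.0)])
    def test_symmetric_shapes_give_unit_mean(self, loc1, loc2):
        s = HyperpriorSettings(alpha_shape1_loc=loc1, alpha_shape2_loc=loc2)
        assert prior_mean_alpha(s) == pytest.approx(1.0)

    def test_yaml_roundtrip(self, tmp_path):
        s = HyperpriorSettings(beta_group_mean_loc=0.3)
        path = tmp_path / "hp.yaml"
        s.to_yaml(path)
        assert HyperpriorSettings.from_yaml(path) == s

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            HyperpriorSettings(gamma_log_scale=0.0)
        with pytest.raises(ValueError):
            HyperpriorSettings(beta_lower=-1.0, beta_upper=1.5)

    def test_subject_params_validation(self):
        SubjectParams(alpha=0.5, beta=0.2, gamma=1.0)
        with pytest.raises(ValueError):
            SubjectParams(alpha=-1.0)
        with pytest.raises(ValueError):
            SubjectParams(beta=2.0)
        with pytest.raises(ValueError):
            SubjectParams(delta=1.5)
        with pytest.raises(ValueError):
            SubjectParams(nu_increments=(1.0, -1.0, 1.0, 1.0))
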