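"""Unit and property tests for the closed-form MFPT lifetime model."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import quiet_params
from dwellkin.kinetic_model import (
    ComplexConfig,
    ComplexKind,
    InvalidGeometryError,
    LifetimePrediction,
    NonAbsorbingError,
    RateParams,
    bond_rates,
    energy_from_param,
    lifetime_nn,
    lifetime_ns,
    lifetime_ss,
    mfpt_oracle,
    multiplicity,
    param_from_energy,
    predict_lifetime,
    predict_ns_branches,
    predictions_frame,
)

PRINTED = dict(x=1.7, y=5.0, u=4.6)


class TestMultiplicity:
    @pytest.mark.parametrize(
        ("length", "footprint", "expected"),
        [(23, 13, 11), (13, 13, 1), (33, 13, 21), (100, 1, 100)],
    )
    def test_examples(self, length, footprint, expected):
        assert multiplicity(length, footprint) == expected

    def test_too_short_duplex_names_both_values(self):
        with pytest.raises(InvalidGeometryError, match="12.*13|13.*12"):
            multiplicity(12, 13)

    def test_bad_footprint(self):
        with pytest.raises(ValueError):
            multiplicity(23, 0)


class TestRateParams:
    def test_positivity_enforced(self):
        for bad in (dict(x=0), dict(y=-1), dict(u=0)):
            kwargs = {"x": 1.5, "y": 2.0, "u": 1.0, **bad}
            with pytest.raises(ValueError):
                RateParams(**kwargs)

    def test_sub_unity_param_warns_not_raises(self):
        with pytest.warns(UserWarning, match="negative bond energy"):
            p = RateParams(x=0.5, y=2.0, u=1.0)
        assert p.x == 0.5

    def test_energy_properties(self, fitted_params):
        assert fitted_params.es == pytest.approx(2 * math.log(5.0))
        assert fitted_params.en == pytest.approx(2 * math.log(1.7))

    def test_from_energies_round_trip(self, fitted_params):
        back = RateParams.from_energies(fitted_params.en, fitted_params.es, 4.6)
        assert back.x == pytest.approx(1.7)
        assert back.y == pytest.approx(5.0)


class TestBondRates:
    def test_energy_neutral_case(self):
        r = bond_rates(RateParams(1, 1, 1), m=1)
        assert (r.break_ns, r.rebind_ns, r.break_s, r.rebind_s) == (1, 1, 1, 1)

    def test_printed_parameter_values(self, fitted_params):
        r = bond_rates(fitted_params, m=11)
        assert r.break_ns == pytest.approx(4.6 / 1.7)  # 2.70588
        assert r.rebind_ns == pytest.approx(11 * 4.6 * 1.7)  # 86.02
        assert r.break_s == pytest.approx(0.92)
        assert r.rebind_s == pytest.approx(23.0)

    @given(
        x=st.floats(0.5, 10),
        y=st.floats(0.5, 10),
        u=st.floats(0.1, 100),
        m=st.integers(1, 50),
    )
    @settings(max_examples=50)
    def test_detailed_balance_identity(self, x, y, u, m):
        r = bond_rates(quiet_params(x, y, u), m)
        # rebind/(m*break) = x^2 = exp(En)
        assert r.rebind_ns / (m * r.break_ns) == pytest.approx(x**2, rel=1e-12)
        assert r.rebind_ns / (m * r.break_ns) == pytest.approx(
            math.exp(energy_from_param(x)), rel=1e-12
        )

    def test_invalid_multiplicity(self, fitted_params):
        with pytest.raises(ValueError):
            bond_rates(fitted_params, m=0)


class TestClosedFormLifetimes:
    def test_neutral_limits_are_three_steps(self):
        p = RateParams(1, 1, 1)
        assert lifetime_nn(p, 1) == pytest.approx(3.0)
        assert lifetime_ss(p) == pytest.approx(3.0)
        assert lifetime_ns(p, 1) == pytest.approx(3.0)

    def test_printed_parameter_lifetimes(self, fitted_params):
        # (2*1.7 + 11*1.7^3)/4.6 and friends, frozen from direct arithmetic
        assert lifetime_nn(fitted_params, 11) == pytest.approx(12.487609, abs=1e-6)
        assert lifetime_nn(fitted_params, 21) == pytest.approx(23.168043, abs=1e-6)
        assert lifetime_ss(fitted_params) == pytest.approx(29.347826, abs=1e-6)
        assert lifetime_ns(fitted_params, 11) == pytest.approx(36.010870, abs=1e-6)
        assert lifetime_ns(fitted_params, 21) == pytest.approx(67.423913, abs=1e-6)

    def test_headline_ordering_entropic_crossover(self, fitted_params):
        t_nn = lifetime_nn(fitted_params, 11)
        t_ss = lifetime_ss(fitted_params)
        t_ns = lifetime_ns(fitted_params, 11)
        assert t_ns > t_ss > t_nn

    @given(
        x=st.floats(0.5, 10),
        y=st.floats(0.5, 10),
        u=st.floats(0.1, 100),
        m=st.integers(1, 49),
    )
    @settings(max_examples=50)
    def test_monotone_in_multiplicity(self, x, y, u, m):
        p = quiet_params(x, y, u)
        assert lifetime_nn(p, m + 1) > lifetime_nn(p, m)
        assert lifetime_ns(p, m + 1) > lifetime_ns(p, m)
        # ss has no multiplicity dependence at all
        assert lifetime_ss(p) == lifetime_ss(p)


class TestEnergyConversion:
    def test_neutral_bond(self):
        assert energy_from_param(1.0) == 0.0

    def test_printed_specific_energy(self):
        assert energy_from_param(5.0) == pytest.approx(3.2189, abs=1e-4)

    def test_nonspecific_energy_as_written(self):
        # 2*ln(1.7): the formula's value, regardless of what was printed elsewhere
        assert energy_from_param(1.7) == pytest.approx(1.0613, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            energy_from_param(0.0)
        with pytest.raises(ValueError):
            energy_from_param(-2.0)

    @given(p=st.floats(0.1, 100))
    @settings(max_examples=100)
    def test_round_trip(self, p):
        assert param_from_energy(energy_from_param(p)) == pytest.approx(p, rel=1e-12)


class TestMfptOracle:
    def test_all_unit_rates(self):
        assert mfpt_oracle(1, 1, 1) == pytest.approx(3.0, rel=1e-12)

    def test_irreversible_chain_is_sum_of_waits(self):
        assert mfpt_oracle(2.0, 0.0, 5.0) == pytest.approx(0.5 + 0.2, rel=1e-12)

    def test_zero_forward_rate_raises(self):
        with pytest.raises(NonAbsorbingError):
            mfpt_oracle(0.0, 1.0, 1.0)
        with pytest.raises(NonAbsorbingError):
            mfpt_oracle(1.0, 1.0, 0.0)

    def test_matches_ns_closed_form_at_printed_params(self, fitted_params):
        r = bond_rates(fitted_params, 11)
        t = mfpt_oracle(r.break_ns, r.rebind_ns, r.break_s)
        assert t == pytest.approx(lifetime_ns(fitted_params, 11), rel=1e-12)

    def test_oracle_equivalence_1000_random_parameter_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            x, y = np.exp(rng.uniform(np.log(0.5), np.log(10), 2))
            u = np.exp(rng.uniform(np.log(0.1), np.log(100)))
            m = int(rng.integers(1, 51))
            p = quiet_params(x, y, u)
            r = bond_rates(p, m)
            assert mfpt_oracle(r.break_ns, r.rebind_ns, r.break_ns) == pytest.approx(
                lifetime_nn(p, m), rel=1e-10
            )
            assert mfpt_oracle(r.break_s, r.rebind_s, r.break_s) == pytest.approx(
                lifetime_ss(p), rel=1e-10
            )
            assert mfpt_oracle(r.break_ns, r.rebind_ns, r.break_s) == pytest.approx(
                lifetime_ns(p, m), rel=1e-10
            )


class TestComplexConfig:
    def test_length_shorter_than_footprint_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ComplexConfig("nn", 12, 23)

    def test_designation_only_for_ns(self):
        with pytest.raises(ValueError):
            ComplexConfig("nn", 23, 23, nonspecific="a")

    def test_multiplicity_properties(self):
        c = ComplexConfig("ns", 23, 33, nonspecific="b")
        assert c.m_a == 11
        assert c.m_b == 21
        assert c.nonspecific_multiplicity() == 21


class TestPredictLifetime:
    def test_ss_is_length_independent(self, fitted_params):
        t23 = predict_lifetime(fitted_params, ComplexConfig("ss", 23, 23))
        t33 = predict_lifetime(fitted_params, ComplexConfig("ss", 33, 33))
        assert t23.lifetime == t33.lifetime == pytest.approx(29.347826, abs=1e-6)

    def test_ns_23bp_printed_value(self, fitted_params, ns_config):
        pred = predict_lifetime(fitted_params, ns_config)
        assert pred.lifetime == pytest.approx(36.0, rel=0.005)
        assert pred.components["m"] == 11

    def test_nn_mixed_lengths_is_arithmetic_mean(self):
        p = RateParams(1, 1, 1)
        pred = predict_lifetime(p, ComplexConfig("nn", 23, 33))
        # m=11 gives (2+11)=13, m=21 gives 23; rule forces their mean
        assert pred.lifetime == pytest.approx(18.0)
        assert pred.components["branch_a"] == pytest.approx(13.0)
        assert pred.components["branch_b"] == pytest.approx(23.0)

    def test_ambiguous_ns_raises_and_branches_report_both(self, fitted_params):
        ambiguous = ComplexConfig("ns", 23, 33)
        with pytest.raises(ValueError, match="designation"):
            predict_lifetime(fitted_params, ambiguous)
        branches = predict_ns_branches(fitted_params, ambiguous)
        assert branches["a"].lifetime == pytest.approx(
            lifetime_ns(fitted_params, 11)
        )
        assert branches["b"].lifetime == pytest.approx(
            lifetime_ns(fitted_params, 21)
        )

    def test_prediction_reproducible_bit_exact(self, fitted_params, ns_config):
        a = predict_lifetime(fitted_params, ns_config)
        b = predict_lifetime(fitted_params, ns_config)
        assert a.lifetime == b.lifetime

    def test_invalid_lifetime_rejected(self, ns_config):
        with pytest.raises(ValueError):
            LifetimePrediction(ns_config, lifetime=0.0)


def test_predictions_frame_expands_ambiguous_ns(fitted_params):
    df = predictions_frame(
        fitted_params,
        [ComplexConfig("ss", 23, 23), ComplexConfig("ns", 23, 33)],
    )
    assert set(df["kind"]) == {"ss", "ns[a]", "ns[b]"}
    assert list(df.columns) == ["kind", "length_a", "length_b", "m", "lifetime_s"]
    assert (df["lifetime_s"] > 0).all()
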