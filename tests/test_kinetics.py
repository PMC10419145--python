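"""Closed-form release curves against the independent ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdemask import (
    KineticsError,
    RateSet,
    bond_hydrolysis_fraction,
    build_network,
    integrate,
    one_stage_concentrations,
    two_stage_coefficients,
    two_stage_concentrations,
)

TIMES = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])

# rates away from the degenerate bands, for closed-form paths
rate_values = st.floats(min_value=0.01, max_value=20.0)


def _assume_nondegenerate(ki, kj, kd=None):
    from pepdemask.kinetics import is_degenerate

    return not is_degenerate(RateSet(kdf=0.46, ki=ki, kj=kj, kd=kd))


def _oracle(rates: RateSet, times):
    network = build_network(rates.mechanism, rates)
    return integrate(network, times)


class TestOneStage:
    def test_initial_condition(self):
        curves = one_stage_concentrations(RateSet(0.46, 0.53, 1.41), [0.0])
        assert curves["masked"].values[0] == pytest.approx(1.0)
        for name in ("ABC", "AB", "BC", "A", "B", "C"):
            assert curves[name].values[0] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustion_limit(self):
        curves = one_stage_concentrations(RateSet(0.46, 0.53, 1.41), [1e6])
        for name in ("A", "B", "C"):
            assert curves[name].values[0] == pytest.approx(1.0, abs=1e-9)
        for name in ("masked", "ABC", "AB", "BC"):
            assert curves[name].values[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_ode_oracle_at_study_rates(self):
        rates = RateSet(0.46, 0.53, 1.41)
        curves = one_stage_concentrations(rates, TIMES)
        oracle = _oracle(rates, TIMES)
        for name, curve in curves.items():
            np.testing.assert_allclose(
                curve.values, oracle[name].values, atol=1e-6, err_msg=name
            )

    def test_zero_hydrolysis_rate_directs_to_exclusion(self):
        with pytest.raises(KineticsError, match="excluded"):
            one_stage_concentrations(RateSet(0.46, 0.0, 1.0), TIMES)

    def test_negative_time_rejected(self):
        with pytest.raises(KineticsError, match=">= 0"):
            one_stage_concentrations(RateSet(0.46, 0.5, 1.0), [-1.0])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(ki=rate_values, kj=rate_values)
    def test_mass_conservation(self, ki, kj):
        curves = one_stage_concentrations(RateSet(0.46, ki, kj), TIMES)
        masked = curves["masked"].values
        for block, members in (
            ("A", ("A", "AB", "ABC")),
            ("B", ("B", "AB", "BC", "ABC")),
            ("C", ("C", "BC", "ABC")),
        ):
            total = masked + sum(curves[m].values for m in members)
            np.testing.assert_allclose(total, 1.0, atol=1e-9, err_msg=block)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(ki=rate_values, kj=rate_values)
    def test_mirror_symmetry(self, ki, kj):
        direct = one_stage_concentrations(RateSet(0.46, ki, kj), TIMES)
        swapped = one_stage_concentrations(RateSet(0.46, kj, ki), TIMES)
        for left, right in (("A", "C"), ("AB", "BC"), ("B", "B"), ("ABC", "ABC")):
            np.testing.assert_allclose(
                direct[left].values, swapped[right].values, atol=1e-12
            )

    def test_A_independent_of_kj(self):
        base = one_stage_concentrations(RateSet(0.46, 0.53, 1.41), TIMES)
        perturbed = one_stage_concentrations(RateSet(0.46, 0.53, 7.7), TIMES)
        np.testing.assert_allclose(base["A"].values, perturbed["A"].values)
        np.testing.assert_allclose(base["C"].values,
                                   one_stage_concentrations(
                                       RateSet(0.46, 9.9, 1.41), TIMES
                                   )["C"].values)

    def test_shape_properties(self):
        t = np.linspace(0.0, 40.0, 400)
        curves = one_stage_concentrations(RateSet(0.46, 0.53, 1.41), t)
        assert np.all(np.diff(curves["masked"].values) < 0)
        for name in ("A", "B", "C"):
            assert np.all(np.diff(curves[name].values) >= -1e-12)
        abc = curves["ABC"].values
        peak = abc.argmax()
        assert 0 < peak < abc.size - 1
        assert np.all(np.diff(abc[: peak + 1]) > -1e-12)
        assert np.all(np.diff(abc[peak:]) < 1e-12)


class TestTwoStage:
    def test_initial_condition(self):
        curves = two_stage_concentrations(RateSet(0.46, 1.0, 1.0, kd=0.15), [0.0])
        assert curves["masked"].values[0] == pytest.approx(1.0)
        for name in ("core", "ABC", "AB", "BC", "A", "B", "C"):
            assert curves[name].values[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("ki, kj", [(1.0, 1.0), (2.0, 0.2), (0.3, 5.0)])
    def test_matches_ode_oracle(self, ki, kj):
        rates = RateSet(0.46, ki, kj, kd=0.15)
        curves = two_stage_concentrations(rates, TIMES)
        oracle = _oracle(rates, TIMES)
        for name, curve in curves.items():
            np.testing.assert_allclose(
                curve.values, oracle[name].values, atol=1e-6, err_msg=name
            )

    def test_instant_second_stage_reduces_to_one_stage(self):
        fast = two_stage_concentrations(RateSet(0.46, 1.0, 1.0, kd=1e6),
                                        [1.0, 5.0])
        single = one_stage_concentrations(RateSet(0.46, 1.0, 1.0), [1.0, 5.0])
        for name in ("masked", "ABC", "AB", "BC", "A", "B", "C"):
            np.testing.assert_allclose(
                fast[name].values, single[name].values, atol=1e-4, err_msg=name
            )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(ki=rate_values, kj=rate_values, kd=st.floats(0.05, 5.0))
    def test_mass_conservation(self, ki, kj, kd):
        curves = two_stage_concentrations(RateSet(0.46, ki, kj, kd=kd), TIMES)
        background = curves["masked"].values + curves["core"].values
        for block, members in (
            ("A", ("A", "AB", "ABC")),
            ("B", ("B", "AB", "BC", "ABC")),
            ("C", ("C", "BC", "ABC")),
        ):
            total = background + sum(curves[m].values for m in members)
            np.testing.assert_allclose(total, 1.0, atol=1e-9, err_msg=block)


class TestTwoStageCoefficients:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(ki=rate_values, kj=rate_values, kd=st.floats(0.05, 5.0))
    def test_coefficients_sum_to_zero(self, ki, kj, kd):
        rates = RateSet(0.46, ki, kj, kd=kd)
        if not _assume_nondegenerate(ki, kj, kd):
            return
        for name, coeff in two_stage_coefficients(rates).items():
            assert math.fsum(coeff.coeffs) == pytest.approx(0.0, abs=1e-9), name

    def test_reconstruction_matches_oracle(self):
        rates = RateSet(0.46, 1.0, 1.0, kd=0.15)
        t = np.array([0.5, 2.0, 8.0])
        oracle = _oracle(rates, t)
        for name, coeff in two_stage_coefficients(rates).items():
            np.testing.assert_allclose(
                coeff.evaluate(t), oracle[name].values, atol=1e-6, err_msg=name
            )

    def test_sparsity_structure(self):
        coeffs = two_stage_coefficients(RateSet(0.46, 0.8, 2.5, kd=0.15))
        # exp(-ki t) plays no role for C/BC, exp(-kj t) none for A/AB,
        # and the trimer decays only through kdf, kd and ki+kj
        assert coeffs["A"].coeffs[5] == 0.0 and coeffs["AB"].coeffs[5] == 0.0
        assert coeffs["C"].coeffs[4] == 0.0 and coeffs["BC"].coeffs[4] == 0.0
        assert coeffs["ABC"].coeffs[4] == 0.0 and coeffs["ABC"].coeffs[5] == 0.0
        assert coeffs["A"].coeffs[2] == 0.0 and coeffs["C"].coeffs[2] == 0.0

    def test_A_row_ignores_kj_and_C_row_ignores_ki(self):
        base = two_stage_coefficients(RateSet(0.46, 0.8, 2.5, kd=0.15))
        perturbed = two_stage_coefficients(RateSet(0.46, 0.8, 3.3, kd=0.15))
        assert base["A"].coeffs == perturbed["A"].coeffs
        perturbed = two_stage_coefficients(RateSet(0.46, 1.7, 2.5, kd=0.15))
        assert base["C"].coeffs == perturbed["C"].coeffs

    def test_degenerate_rates_refused_with_pointer_to_limit_path(self):
        with pytest.raises(KineticsError, match="limit path"):
            two_stage_coefficients(RateSet(0.46, 1.0, 1.0, kd=0.46))


class TestDegenerateRates:
    """Rate coincidences go through the division-free limit path."""

    @pytest.mark.parametrize(
        "rates",
        [
            RateSet(0.46, 0.46, 1.41),          # ki = kdf
            RateSet(0.46, 0.23, 0.23),          # ki + kj = kdf
            RateSet(0.46, 0.46, 0.46, kd=0.15),  # ki = kj = kdf
            RateSet(0.46, 0.15, 2.0, kd=0.15),   # ki = kd
        ],
    )
    def test_limit_path_matches_oracle(self, rates):
        evaluate = (
            one_stage_concentrations if rates.kd is None
            else two_stage_concentrations
        )
        curves = evaluate(rates, TIMES)
        oracle = _oracle(rates, TIMES)
        for name, curve in curves.items():
            np.testing.assert_allclose(
                curve.values, oracle[name].values, atol=1e-5, err_msg=name
            )


class TestBondHydrolysisFraction:
    def test_boundary_values(self):
        assert bond_hydrolysis_fraction("one_stage", 0.46, 1.0, 0.0) == (
            pytest.approx(0.0)
        )
        assert bond_hydrolysis_fraction("one_stage", 0.46, 1.0, 1e6) == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert bond_hydrolysis_fraction(
            "two_stage", 0.46, 1.0, 1e6, kd=0.15
        ) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_equal_rates_limit_value(self):
        # at kj = kdf = k the fraction is 1 - e^(-kt)(1 + kt);
        # at t = 1/k that is 1 - 2/e
        value = bond_hydrolysis_fraction("one_stage", 0.46, 0.46, 1 / 0.46)
        assert value == pytest.approx(1 - 2 * math.exp(-1), abs=1e-12)

    def test_two_stage_chain_matches_oracle(self):
        rates = RateSet(0.46, 1e9, 1.0, kd=0.15)
        # with ki effectively instantaneous, the C species of the network
        # tracks exactly the three-step chain kdf -> kd -> kj
        oracle = _oracle(rates, np.array([5.0]))["C"].values[0]
        value = bond_hydrolysis_fraction("two_stage", 0.46, 1.0, 5.0, kd=0.15)
        assert value == pytest.approx(oracle, abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(kj=rate_values, mechanism=st.sampled_from(["one_stage", "two_stage"]))
    def test_monotone_from_zero_to_one(self, kj, mechanism):
        t = np.linspace(0.0, 200.0, 300)
        frac = bond_hydrolysis_fraction(
            mechanism, 0.46, kj, t, kd=0.15 if mechanism == "two_stage" else None
        )
        assert frac[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(frac) >= -1e-12)
        assert np.all((frac >= -1e-12) & (frac <= 1 + 1e-9))

    def test_negative_time_rejected(self):
        with pytest.raises(KineticsError):
            bond_hydrolysis_fraction("one_stage", 0.46, 1.0, -0.1)
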