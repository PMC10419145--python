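"""Release descriptors: d_r, the power exponent n, comparison metrics."""

import numpy as np
import pytest

from pepdemask import (
    DEGREE_GRID,
    mean_abs_difference,
    power_exponent,
    power_exponent_loglinear,
    proportionality,
    release_degree,
)
from pepdemask.descriptors import DescriptorError

GRID = np.asarray(DEGREE_GRID)

# descriptor columns of the packaged study tables (calculated, experimental)
DR_PAIRS = [
    (2.6, 1.5), (3.5, 3.6), (3.9, 3.4), (4.3, 4.4),
    (4.3, 4.7), (3.8, 3.4), (4.7, 6.1),
]
N_PAIRS = [
    (0.85, 0.68), (0.92, 0.86), (0.44, 0.59), (2.41, 1.46), (2.86, 2.37),
    (2.41, 1.40), (2.21, 1.13), (4.84, 5.76), (4.77, 5.10),
]


class TestReleaseDegree:
    def test_uniform_weights_give_grid_mean(self):
        result = release_degree(np.ones(6))
        assert result.d_r == pytest.approx(22.9 / 6)

    def test_point_mass(self):
        c = np.zeros(6)
        c[1] = 0.37
        assert release_degree(c).d_r == pytest.approx(1.5)

    def test_invariant_to_rescaling(self):
        c = np.array([0.0, 0.1, 0.3, 0.25, 0.12, 0.05])
        assert release_degree(c).d_r == pytest.approx(release_degree(50 * c).d_r)

    def test_all_zero_rejected(self):
        with pytest.raises(DescriptorError, match="undefined"):
            release_degree(np.zeros(6))


class TestPowerExponent:
    @pytest.mark.parametrize("n_true", [0.5, 1.0, 2.0, 5.0])
    def test_exact_recovery_on_power_law(self, n_true):
        c = 0.7 * (GRID / 7.9) ** n_true
        fit = power_exponent(c)
        assert fit.n == pytest.approx(n_true, abs=1e-6)
        assert fit.a == pytest.approx(0.7, abs=1e-6)
        assert fit.residual_norm < 1e-7

    def test_exponent_classifies_curvature(self):
        # n > 1 iff the fitted curve is concave-up on the grid
        concave = power_exponent(0.4 * (GRID / 7.9) ** 2.3)
        convex = power_exponent(0.4 * (GRID / 7.9) ** 0.6)
        assert concave.n > 1 > convex.n
        mid = 0.4 * (3.95 / 7.9) ** concave.n
        assert mid < 0.4 / 2  # below the chord through (0, 0) and (7.9, a)

    def test_non_monotone_input_flagged_not_rejected(self):
        c = np.array([0.0, 0.2, 0.15, 0.3, 0.5, 0.7])
        assert power_exponent(c).warning is not None

    def test_too_few_positive_points_rejected(self):
        with pytest.raises(DescriptorError, match="three positive"):
            power_exponent(np.array([0.0, 0.0, 0.0, 0.0, 0.1, 0.2]))

    def test_loglinear_alternative_agrees_on_exact_power_law(self):
        c = 0.55 * (GRID / 7.9) ** 1.8
        alt = power_exponent_loglinear(c)
        assert alt.n == pytest.approx(1.8, abs=1e-9)
        assert alt.a == pytest.approx(c[-1])

    def test_sensitivity_of_n_to_fit_convention_is_moderate(self):
        # on a model-like curve (not an exact power law) the two fitting
        # conventions must agree on the curvature class and roughly on n
        from pepdemask import RateSet, two_stage_concentrations

        t = np.array([0.0, 1.8, 3.2, 5.0, 8.1, 24.8])
        c = two_stage_concentrations(RateSet(0.46, 1.0, 1.0, kd=0.15), t)
        values = c["B"].values
        free = power_exponent(values)
        pinned = power_exponent_loglinear(values)
        assert (free.n > 1) == (pinned.n > 1)
        assert abs(free.n - pinned.n) / free.n < 0.35


class TestComparisonMetrics:
    def test_identical_vectors_give_zero(self):
        stats = mean_abs_difference({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert stats.mean_abs_diff == 0.0

    def test_constant_offset(self):
        stats = mean_abs_difference({"a": 2.0, "b": 3.0}, {"a": 1.0, "b": 2.0})
        assert stats.mean_abs_diff == pytest.approx(1.0)

    def test_missing_experimental_values_dropped(self):
        stats = mean_abs_difference(
            {"a": 1.0, "b": 2.0, "c": 9.0}, {"a": 1.5, "b": 2.5, "c": np.nan}
        )
        assert stats.n_pairs == 2
        assert stats.mean_abs_diff == pytest.approx(0.5)

    def test_no_overlap_rejected(self):
        with pytest.raises(DescriptorError, match="overlap"):
            mean_abs_difference({"a": 1.0}, {"b": 1.0})

    def test_study_table_pairs_reproduce_printed_mean(self):
        calc = {str(k): v[0] for k, v in enumerate(DR_PAIRS)}
        exp = {str(k): v[1] for k, v in enumerate(DR_PAIRS)}
        stats = mean_abs_difference(calc, exp)
        assert stats.mean_abs_diff == pytest.approx(4.0 / 7, abs=1e-12)
        assert round(stats.mean_abs_diff, 1) == 0.6
        assert stats.pooled_min == pytest.approx(1.5)
        assert stats.pooled_max == pytest.approx(6.1)

    def test_proportionality_identity_and_scaling(self):
        same = proportionality({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert (same.mean_ratio, same.sd_ratio) == (1.0, 0.0)
        doubled = proportionality({"a": 2.0, "b": 4.0}, {"a": 1.0, "b": 2.0})
        assert (doubled.mean_ratio, doubled.sd_ratio) == (2.0, 0.0)

    def test_zero_experimental_value_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            stats = proportionality({"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 1.0})
        assert stats.ratios == (2.0,)
        assert stats.dropped == ("a",)

    def test_study_table_ratio_mean(self):
        calc = {str(k): v[0] for k, v in enumerate(N_PAIRS)}
        exp = {str(k): v[1] for k, v in enumerate(N_PAIRS)}
        stats = proportionality(calc, exp)
        # mean of per-peptide ratios of the printed descriptor columns
        brute = np.mean([a / b for a, b in N_PAIRS])
        assert stats.mean_ratio == pytest.approx(brute, abs=1e-12)
        assert stats.mean_ratio == pytest.approx(1.264, abs=0.001)
        assert stats.sd_ratio == pytest.approx(
            np.std([a / b for a, b in N_PAIRS], ddof=1), abs=1e-12
        )
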