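"""Tracking metrics, factorial main effects, rm-ANOVA, paired tests, learning filter."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from cuefidelity import (
    DegenerateFitError,
    DomainError,
    IncompleteDesignError,
    LearningFilterConfig,
    SeriesAlignmentError,
    learning_filter,
    main_effects,
    median_abs_error,
    paired_compare,
    rm_anova,
)
from cuefidelity.tracking import holm_correct

FACTORS = ("e", "t", "m", "d")


def factorial_table(n_subjects, cell_fn, factors=FACTORS):
    """Complete 2^k design; cell_fn(subject_index, cell_dict) -> error value."""
    rows = []
    for s in range(n_subjects):
        for cell in product((0, 1), repeat=len(factors)):
            d = dict(zip(factors, cell))
            rows.append({"subject_id": f"S{s}", **d,
                         "median_abs_error": cell_fn(s, d)})
    return pd.DataFrame(rows)


class TestMedianAbsError:
    def test_identical_series(self):
        t = np.linspace(0, 1, 50)
        assert median_abs_error(t, t) == 0.0

    def test_constant_offset(self):
        t = np.sin(np.linspace(0, 10, 200))
        assert median_abs_error(t, t + 0.39) == pytest.approx(0.39)

    def test_robust_to_outliers(self):
        assert median_abs_error([0, 0, 0], [0, 1, 100]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(SeriesAlignmentError):
            median_abs_error([1, 2], [1, 2, 3])


class TestMainEffects:
    def test_constant_table_has_zero_effects(self):
        table = factorial_table(4, lambda s, c: 0.7)
        eff = main_effects(table)
        assert np.allclose(eff["difference"], 0.0)

    def test_constructed_additive_motion_effect(self):
        table = factorial_table(5, lambda s, c: 0.8 - 0.1 * c["m"])
        eff = main_effects(table)
        assert eff.loc["m", "difference"] == pytest.approx(0.1)
        for f in ("e", "t", "d"):
            assert eff.loc[f, "difference"] == pytest.approx(0.0, abs=1e-12)

    def test_additive_design_recovers_generating_coefficients(self, rng):
        coef = {"e": 0.02, "t": -0.05, "m": 0.12, "d": -0.3}
        base = rng.uniform(0.5, 1.0, 6)  # per-subject offsets
        table = factorial_table(
            6, lambda s, c: base[s] - sum(coef[f] * c[f] for f in FACTORS)
        )
        eff = main_effects(table)
        for f in FACTORS:
            assert eff.loc[f, "difference"] == pytest.approx(coef[f], abs=1e-12)

    def test_missing_cells_rejected(self):
        table = factorial_table(3, lambda s, c: 0.5).iloc[:-1]
        with pytest.raises(IncompleteDesignError) as exc:
            main_effects(table)
        assert exc.value.missing


class TestRmAnova:
    def test_two_subject_hand_computed_oracle(self):
        # subject-by-level means: S0 (1, 3); S1 (2, 8)
        # SS_factor = 2*((1.5-3.5)^2 + (5.5-3.5)^2) = 16, SS_inter = 4 -> F = 4
        table = pd.DataFrame({
            "subject_id": ["S0", "S0", "S1", "S1"],
            "m": [0, 1, 0, 1],
            "median_abs_error": [1.0, 3.0, 2.0, 8.0],
        })
        res = rm_anova(table, factors=("m",))
        assert res.loc["m", "F"] == pytest.approx(4.0)
        assert (res.loc["m", "df1"], res.loc["m", "df2"]) == (1, 1)

    def test_equivalence_with_paired_t(self, rng):
        scores0 = rng.uniform(0.3, 1.0, 8)
        scores1 = scores0 + rng.normal(0.1, 0.2, 8)
        table = pd.DataFrame({
            "subject_id": np.repeat([f"S{i}" for i in range(8)], 2),
            "m": np.tile([0, 1], 8),
            "median_abs_error": np.column_stack([scores0, scores1]).ravel(),
        })
        res = rm_anova(table, factors=("m",))
        t, df, p = paired_compare(scores0, scores1)
        assert res.loc["m", "F"] == pytest.approx(t ** 2, abs=1e-9)
        assert res.loc["m", "p"] == pytest.approx(p, abs=1e-12)

    def test_large_effect_tiny_noise_separates(self, rng):
        table = factorial_table(
            8, lambda s, c: 1.0 - 0.5 * c["m"] + rng.normal(0, 1e-4)
        )
        res = rm_anova(table)
        assert res.loc["m", "p"] < 1e-6
        assert res.loc["e", "p"] > 0.01

    def test_unbalanced_rejected(self):
        table = factorial_table(3, lambda s, c: 0.5)
        extra = table.iloc[[0]]
        with pytest.raises(IncompleteDesignError):
            rm_anova(pd.concat([table, extra], ignore_index=True))


class TestPairedCompare:
    def test_textbook_pairs(self):
        # pairs (10,12), (9,11), (11,12): d = (-2,-2,-1), mean -5/3,
        # sd = 1/sqrt(3), so t = (-5/3) / (1/sqrt(3)/sqrt(3)) = -5
        t, df, p = paired_compare([10, 9, 11], [12, 11, 12])
        assert t == pytest.approx(-5.0, rel=1e-12)
        assert df == 2

    def test_identical_inputs_convention(self):
        t, df, p = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateFitError):
            paired_compare([1, 2, 3, 4], [2, 3, 4, 5])

    def test_one_sided_direction(self, rng):
        a = rng.normal(1.0, 0.05, 10)
        b = a - rng.uniform(0.4, 0.6, 10)  # b clearly smaller
        t, df, p_greater = paired_compare(a, b, alternative="greater")
        assert p_greater < 1e-6
        _, _, p_less = paired_compare(a, b, alternative="less")
        assert p_less > 0.999

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            paired_compare([1.0], [2.0])


class TestLearningFilter:
    def test_linear_learner_included(self):
        res = learning_filter([0.9, 0.8, 0.7, 0.6])
        assert res.improvement == pytest.approx(0.3)
        assert res.slope == pytest.approx(-0.1)
        assert res.included

    def test_flat_learner_excluded(self):
        res = learning_filter([0.5, 0.5, 0.5, 0.5])
        assert res.improvement == pytest.approx(0.0)
        assert not res.included

    def test_noisy_learner_against_normal_equations(self):
        y = np.array([0.6, 0.5, 0.55, 0.46])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope = (np.sum(x * y) - 4 * x.mean() * y.mean()) / (
            np.sum(x ** 2) - 4 * x.mean() ** 2
        )
        res = learning_filter(y)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.improvement == pytest.approx(-3 * slope, rel=1e-12)
        assert res.included == (-3 * slope >= 0.15)

    def test_threshold_boundary(self):
        # improvement exactly 0.15 is included; just under is not
        assert learning_filter([0.65, 0.6, 0.55, 0.5]).included
        assert not learning_filter([0.649, 0.6, 0.551, 0.502]).included

    def test_steepening_cannot_exclude(self, rng):
        base = rng.uniform(0.4, 0.9, 4)
        res_base = learning_filter(base)
        for extra in (0.05, 0.1, 0.3):
            steeper = base - extra * np.arange(4)
            res = learning_filter(steeper)
            assert res.improvement >= res_base.improvement
            if res_base.included:
                assert res.included

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            learning_filter([0.5, 0.4, np.nan, 0.3])
        with pytest.raises(DomainError):
            learning_filter([0.5, 0.4, 0.3])


def test_holm_correction_monotone():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_correct(p)
    assert np.all(adj >= p)
    assert adj[3] == 0.5
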