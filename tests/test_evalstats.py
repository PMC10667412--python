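"""Statistics: Dice, Wilcoxon, Mann-Whitney, Yates chi-square, kappa,
score summaries — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from focusedview.core import ValidationError, one_hot
from focusedview.evalstats import (
    Contingency2x2,
    chi_square_yates,
    compare_conditions,
    dice_coefficient,
    mann_whitney,
    summarize_scores,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from focusedview.train import dice_loss


class TestDice:
    def test_identical_maps(self):
        y = np.random.default_rng(0).integers(0, 3, (6, 6, 6))
        assert dice_coefficient(y, y, 1) == 1.0

    def test_disjoint_equal_regions(self):
        a = np.zeros((10, 1, 1), dtype=int)
        b = np.zeros((10, 1, 1), dtype=int)
        a[:5] = 1
        b[5:] = 1
        assert dice_coefficient(a, b, 1) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((200, 1, 1), dtype=int)
        b = np.zeros((200, 1, 1), dtype=int)
        a[:100] = 2
        b[:50] = 2
        assert dice_coefficient(a, b, 2) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4, 4), dtype=int)
        assert dice_coefficient(z, z, 2) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, (8, 8, 8))
        b = rng.integers(0, 3, (8, 8, 8))
        assert dice_coefficient(a, b, 1) == dice_coefficient(b, a, 1)

    def test_complements_dice_loss_for_one_hot(self):
        """For one-hot inputs, 1 - dice_loss equals the mean per-class
        dice coefficient (eps -> 0)."""
        rng = np.random.default_rng(2)
        t = rng.integers(0, 3, (6, 6, 6))
        p = rng.integers(0, 3, (6, 6, 6))
        loss = dice_loss(one_hot(p).astype(np.float64), t, eps=1e-12)
        mean_dice = np.mean(
            [dice_coefficient(p, t, c) for c in (1, 2)]
        )
        assert abs((1 - loss) - mean_dice) < 1e-9


class TestWilcoxon:
    def test_identical_lists(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([3, 3, 4], [3, 3, 4])
        assert p == 1.0

    def test_six_one_sided_exact(self):
        """All differences of one sign, n = 6: p = 2/2^6."""
        _, p = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
        assert p == pytest.approx(2 / 64)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 1, 12)
            _, p = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_approx_matches_scipy_tie_corrected(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 6, 40).astype(float)
        b = rng.integers(1, 6, 40).astype(float)
        _, p = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(
            a, b, zero_method="wilcox", method="approx", correction=False
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_pratt_variant_runs(self):
        a = [1, 2, 3, 4, 5, 5]
        b = [1, 1, 1, 1, 1, 5]
        _, p_drop = wilcoxon_signed_rank(a, b, zero_method="drop")
        _, p_pratt = wilcoxon_signed_rank(a, b, zero_method="pratt")
        assert 0 < p_drop <= 1 and 0 < p_pratt <= 1

    def test_type_one_error_calibrated(self):
        """2000-rep null simulation: rejection rate at alpha = 0.05 within
        [0.035, 0.065]."""
        rng = np.random.default_rng(7)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            if wilcoxon_signed_rank(x, y)[1] < 0.05:
                rej += 1
        assert 0.035 <= rej / reps <= 0.065


class TestMannWhitney:
    def test_identical_singletons(self):
        _, p = mann_whitney([3], [3])
        assert p == 1.0

    def test_small_exact_enumeration(self):
        """a=[1,2] vs b=[3,4]: the most extreme of C(4,2)=6 orderings in
        either direction, p = 2/6."""
        _, p = mann_whitney([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            if mann_whitney(x, y)[1] < 0.05:
                rej += 1
        assert 0.035 <= rej / reps <= 0.065


class TestChiSquareYates:
    @pytest.mark.parametrize(
        "cells,expected_p",
        [
            ((61, 39, 29, 12), 0.369),  # training vs test gender split
            ((24, 76, 6, 35), 0.314),  # large-vessel-occlusion prevalence
            ((10, 89, 3, 38), 0.844),  # right-ICA plaque prevalence
            ((3, 97, 3, 37), 0.468),  # left-vertebral plaque prevalence
            ((6, 86, 3, 38), 1.000),  # left-ICA plaque prevalence
        ],
    )
    def test_cohort_tables_to_three_decimals(self, cells, expected_p):
        _, p = chi_square_yates(Contingency2x2(*cells))
        assert round(p, 3) == expected_p

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, 4))
            chi2, p = chi_square_yates([[a, b], [c, d]])
            n = a + b + c + d
            oracle = n * max(abs(a * d - b * c) - n / 2, 0) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert abs(chi2 - oracle) < 1e-12
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equal_proportions_give_p_one(self):
        chi2, p = chi_square_yates([[10, 30], [20, 60]])
        assert chi2 == 0.0 and p == 1.0

    def test_group_relabel_invariance(self):
        _, p1 = chi_square_yates([[61, 39], [29, 12]])
        _, p2 = chi_square_yates([[29, 12], [61, 39]])
        assert p1 == pytest.approx(p2, abs=1e-14)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_yates([[0, 0], [5, 5]])


class TestWeightedKappa:
    def test_perfect_agreement(self):
        a = [1, 2, 3, 4, 5, 2, 3]
        assert weighted_kappa(a, a) == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 6, 300)
        b = np.clip(a + rng.integers(-1, 2, 300), 1, 5)
        for w in ("linear", "quadratic"):
            ours = weighted_kappa(a, b, weighting=w)
            ref = cohen_kappa_score(a, b, weights=w)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 6, 5000)
        b = rng.permutation(a)
        assert abs(weighted_kappa(a, b)) < 0.05

    def test_two_category_weights_coincide_with_unweighted(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 3, 200)
        b = rng.integers(1, 3, 200)
        lin = weighted_kappa(a, b, categories=(1, 2), weighting="linear")
        quad = weighted_kappa(a, b, categories=(1, 2), weighting="quadratic")
        unw = cohen_kappa_score(a, b)
        assert lin == pytest.approx(quad, abs=1e-12)
        assert lin == pytest.approx(unw, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(ValidationError, match="undefined"):
            weighted_kappa([3, 3, 3], [3, 3, 3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.lists(st.integers(1, 5), min_size=3, max_size=30),
    b=st.lists(st.integers(1, 5), min_size=3, max_size=30),
)
def test_pvalues_in_unit_interval(a, b):
    import warnings

    _, p = mann_whitney(a, b)
    assert 0 < p <= 1
    n = min(len(a), len(b))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, pw = wilcoxon_signed_rank(a[:n], b[:n])
    assert 0 < pw <= 1


class TestScoreSummaries:
    def _table(self, scores, structure="C5", condition="focused"):
        return pd.DataFrame(
            {
                "case": range(len(scores)),
                "structure": structure,
                "condition": condition,
                "reader": 1,
                "score": scores,
            }
        )

    def test_constant_scores(self):
        out = summarize_scores(self._table([4, 4, 4, 4]))
        row = out.iloc[0]
        assert row["formatted"] == "4 (IQR: 4–4, range: 4–4)"

    def test_full_spread(self):
        row = summarize_scores(self._table([1, 2, 3, 4, 5])).iloc[0]
        assert row["median"] == 3 and row["min"] == 1 and row["max"] == 5

    def test_even_sample_half_integer_median(self):
        row = summarize_scores(self._table([2, 2, 3, 3])).iloc[0]
        assert row["median"] == 2.5

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValidationError):
            summarize_scores(self._table([0, 3, 4, 5]))

    def test_paired_condition_comparison(self):
        rng = np.random.default_rng(0)
        n = 30
        focused = rng.integers(2, 5, n)
        rows = []
        for i in range(n):
            rows.append(("c%d" % i, "C5", "focused", 1, int(focused[i])))
            rows.append(("c%d" % i, "C5", "unmodified", 1, 5))
        table = pd.DataFrame(
            rows, columns=["case", "structure", "condition", "reader", "score"]
        )
        out = compare_conditions(table)
        assert out.iloc[0]["p_value"] < 0.001  # uniformly lower scores
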