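import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncdys.differential_expression import (
    DiffThresholds,
    benjamini_hochberg,
    call_differential,
    choose_test,
    fisher_detection_test,
    fold_change,
    two_group_t_test,
    zero_fraction,
)
from lncdys.expression_data import ExpressionMatrix
from lncdys.synthetic_cohort import CohortSpec, generate_cohort


def fisher_enumeration_oracle(a: int, n1: int, b: int, n2: int) -> Fraction:
    """Exact two-sided Fisher p by enumerating the hypergeometric tables.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's, using integer
    arithmetic throughout.
    """
    d = a + b
    obs_w = math.comb(n1, a) * math.comb(n2, b)
    total = math.comb(n1 + n2, d)
    acc = 0
    for k in range(max(0, d - n2), min(n1, d) + 1):
        w = math.comb(n1, k) * math.comb(n2, d - k)
        if w <= obs_w:
            acc += w
    return Fraction(acc, total)


class TestZeroFraction:
    @pytest.mark.parametrize(
        "vec,expected",
        [([0, 0, 1, 3], 0.5), ([1, 2, 3], 0.0), ([0, 0, 0], 1.0)],
    )
    def test_examples(self, vec, expected):
        assert zero_fraction(vec) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            zero_fraction([])


class TestChooseTest:
    @pytest.mark.parametrize(
        "zc,zn,expected",
        [
            (0.4, 0.1, "fisher"),
            (0.30, 0.30, "ttest"),  # "more than 30%" is strict
            (0.0, 0.95, "fisher"),
            (0.0, 0.0, "ttest"),
        ],
    )
    def test_rule(self, zc, zn, expected):
        assert choose_test(zc, zn) == expected

    @given(
        st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 1), st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_zero_fractions(self, zc, zn, dc, dn):
        """Raising either zero fraction never flips fisher -> ttest."""
        before = choose_test(zc, zn)
        after = choose_test(min(zc + dc, 1.0), min(zn + dn, 1.0))
        assert not (before == "fisher" and after == "ttest")


class TestFisherDetection:
    def test_fully_separated_small_table(self):
        # all 5 detected vs none of 5: only the two extreme tables are as
        # improbable as observed -> p = 2/252
        p = fisher_detection_test(5, 5, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_identical_proportions_give_p_one(self):
        assert fisher_detection_test(3, 6, 3, 6) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_spot(self):
        p = fisher_detection_test(8, 10, 2, 10)
        oracle = fisher_enumeration_oracle(8, 10, 2, 10)
        assert p == pytest.approx(float(oracle), rel=1e-10)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            fisher_detection_test(0, 0, 1, 5)


class TestTTest:
    def test_identical_vectors_give_p_one(self):
        assert two_group_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        p = two_group_t_test([1, 2, 3], [101, 102, 103])
        assert p < 1e-4
        # closed-form check: t = -100 / (1 * sqrt(2/3)), df = 4
        from scipy import stats

        t = -100 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-9)

    def test_zero_variance_conventions(self):
        assert two_group_t_test([5, 5], [5, 5]) == 1.0
        assert two_group_t_test([5, 5], [7, 7]) == 0.0

    def test_agrees_with_exact_permutation_oracle(self, rng):
        """Analytic p tracks the exact label-permutation p at n = 6 + 6."""
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(0.8, 1.0, 6)
        p_analytic = two_group_t_test(x, y)
        pooled = np.r_[x, y]
        obs = abs(x.mean() - y.mean())
        count = 0
        combos = list(itertools.combinations(range(12), 6))
        for idx in combos:
            mask = np.zeros(12, dtype=bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            if diff >= obs - 1e-12:
                count += 1
        p_perm = count / len(combos)
        assert p_analytic == pytest.approx(p_perm, abs=0.05)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        # m = 4; adjusted_i = min_{rank j >= i} m p_j / j = 0.04 for all
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_invariant_to_input_order(self, pvals):
        p = np.asarray(pvals)
        perm = np.random.default_rng(0).permutation(len(p))
        direct = benjamini_hochberg(p)
        via_perm = np.empty_like(direct)
        via_perm[perm] = benjamini_hochberg(p[perm])
        assert np.allclose(direct, via_perm)


class TestFoldChange:
    def test_examples(self):
        fc, d = fold_change(10, 5)
        assert d == "up_in_cancer" and fc == pytest.approx(2.0, rel=1e-2)
        fc2, d2 = fold_change(5, 10)
        assert d2 == "down_in_cancer" and fc2 == pytest.approx(fc)
        fc3, d3 = fold_change(0, 0)
        assert (fc3, d3) == (1.0, "none")

    def test_fc_never_below_one(self, rng):
        for a, b in rng.uniform(0, 100, (50, 2)):
            fc, _ = fold_change(a, b)
            assert fc >= 1.0


class TestCallDifferential:
    def _matrix(self, cancer, normal):
        values = pd.DataFrame(
            np.c_[cancer, normal],
            index=[f"g{i}" for i in range(cancer.shape[0])],
            columns=[f"c{i}" for i in range(cancer.shape[1])]
            + [f"n{i}" for i in range(normal.shape[1])],
        )
        group = pd.Series(
            ["cancer"] * cancer.shape[1] + ["normal"] * normal.shape[1],
            index=values.columns,
        )
        return ExpressionMatrix(values=values, group=group)

    def test_planted_fourfold_gene_called_up(self, rng):
        cancer = rng.lognormal(np.log(40), 0.3, (1, 50))
        normal = rng.lognormal(np.log(10), 0.3, (1, 50))
        mat = self._matrix(cancer, normal)
        rec = call_differential(mat)
        assert bool(rec["significant"].iloc[0])
        assert rec["direction"].iloc[0] == "up_in_cancer"

    def test_fc_filter_blocks_small_effects(self, rng):
        # 1.5-fold shift with tiny noise: p is minute but fc <= 2
        cancer = np.full((1, 100), 15.0) + rng.normal(0, 0.01, (1, 100))
        normal = np.full((1, 100), 10.0) + rng.normal(0, 0.01, (1, 100))
        rec = call_differential(self._matrix(cancer, normal))
        assert rec["p"].iloc[0] < 1e-10
        assert not bool(rec["significant"].iloc[0])

    def test_one_test_per_gene_and_family_fdr(self, default_cohort):
        matrix, ann, _, _ = default_cohort
        rec = call_differential(matrix)
        assert set(rec["test_used"].unique()) <= {"fisher", "ttest"}
        # BH within family: every family's fdr is a valid BH output
        for fam in ("fisher", "ttest"):
            sub = rec[rec["test_used"] == fam]
            assert np.allclose(
                sub["fdr"], benjamini_hochberg(sub["p"].to_numpy())
            )

    def test_too_few_samples_errors(self, rng):
        mat = self._matrix(rng.uniform(1, 2, (2, 1)), rng.uniform(1, 2, (2, 3)))
        with pytest.raises(ValueError):
            call_differential(mat)
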