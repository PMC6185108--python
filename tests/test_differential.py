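import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from glycoshift import (
    DECREASED,
    EXCLUSIVE_CONTROL,
    EXCLUSIVE_MUTANT,
    UNCHANGED,
    bh_qvalues,
    filter_complete_cases,
    filter_glyco_sites,
    paired_protein_test,
    partition_and_test,
)


def brute_force_bh(p):
    """Step-up oracle: q_(i) = min_{j >= i} m * p_(j) / j, mapped back."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        best = min(best, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(best, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBH:
    def test_hand_computed_example(self):
        # four equally spaced p-values: every q collapses to the largest p
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04] * 4)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(bh_qvalues(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert (bh_qvalues(p) >= p - 1e-12).all()


class TestCompleteCases:
    def test_rows_with_any_missing_filtered(self, make_matrix):
        m = make_matrix(
            {"full": [1] * 8, "hole": [1, None, 1, 1, 1, 1, 1, 1]}, kind="protein"
        )
        kept, dropped = filter_complete_cases(m)
        assert kept.feature_ids == ["full"] and dropped == ["hole"]

    def test_empty_matrix(self, make_matrix):
        kept, dropped = filter_complete_cases(make_matrix({}, kind="protein"))
        assert len(kept) == 0 and dropped == []


class TestPairedTest:
    def test_identical_pairs_give_p_one_unchanged(self, make_matrix):
        m = make_matrix({"f": [4, 5, 6, 7, 4, 5, 6, 7]}, kind="protein")
        res = paired_protein_test(m)
        row = res.iloc[0]
        assert row.p_value == 1.0 and row.status == UNCHANGED
        assert row.flag == "degenerate_zero_variance"

    def test_constant_halving_is_decreased(self, make_matrix):
        rng = np.random.default_rng(1)
        rows = {}
        base = rng.uniform(1e6, 2e6, size=4)
        for i in range(5):
            noise = rng.normal(1, 0.01, size=4)
            rows[f"f{i}"] = list(base * noise) + list(base * noise * 0.5 * rng.normal(1, 0.01, 4))
        res = paired_protein_test(make_matrix(rows, kind="protein"))
        assert (res.status == DECREASED).all()
        assert (res.log2_fold_change < 0).all()

    def test_constant_nonzero_shift_flagged_tiny_p(self, make_matrix):
        # exact doubling in every pair: zero variance of differences, shift != 0
        m = make_matrix({"f": [10, 20, 40, 80, 20, 40, 80, 160]}, kind="protein")
        res = paired_protein_test(m)
        row = res.iloc[0]
        assert row.flag == "degenerate_zero_variance"
        assert 0 < row.p_value <= np.finfo(float).tiny
        assert row.log2_fold_change == pytest.approx(1.0)

    def test_matches_scipy_on_random_data(self, make_matrix):
        rng = np.random.default_rng(2)
        rows = {f"f{i}": list(rng.lognormal(14, 1, 8)) for i in range(20)}
        m = make_matrix(rows, kind="protein")
        res = paired_protein_test(m).set_index("feature_id")
        log2 = np.log2(pd.DataFrame(rows).T)
        t, p = stats.ttest_rel(log2.iloc[:, 4:], log2.iloc[:, :4], axis=1)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p, rtol=1e-10)

    def test_incomplete_matrix_rejected(self, make_matrix):
        m = make_matrix({"f": [1, None, 1, 1, 1, 1, 1, 1]}, kind="protein")
        with pytest.raises(ValueError, match="complete-case"):
            paired_protein_test(m)


DETECTED = 1500.0


def pattern_matrix(make_matrix, patterns):
    rows = {
        fid: [DETECTED * (i + 1) if flag else None for i, flag in enumerate(flags)]
        for fid, flags in patterns.items()
    }
    return make_matrix(rows)


class TestGlycoFilter:
    def test_spec_examples(self, make_matrix):
        m = pattern_matrix(
            make_matrix,
            {
                "three_ctrl": [1, 1, 1, 0, 1, 1, 1, 1],
                "excl_mut": [0, 0, 0, 0, 1, 1, 1, 0],
                "two_ctrl_four_mut": [1, 1, 0, 0, 1, 1, 1, 1],
            },
        )
        part = filter_glyco_sites(m)
        assert part.testable.feature_ids == ["three_ctrl"]
        assert part.exclusive_mutant == ["excl_mut"]
        assert part.filtered_out == ["two_ctrl_four_mut"]

    @given(st.lists(st.tuples(*[st.booleans()] * 8), min_size=1, max_size=40))
    def test_partition_is_exhaustive_and_disjoint(self, flags):
        from glycoshift import CONTROL, MUTANT, QuantMatrix, SampleDesign

        design = [
            *(SampleDesign(f"C{i}", CONTROL, i) for i in range(1, 5)),
            *(SampleDesign(f"M{i}", MUTANT, i) for i in range(1, 5)),
        ]
        patterns = {f"f{i}": list(map(int, row)) for i, row in enumerate(flags)}
        df = pd.DataFrame.from_dict(
            {
                fid: [DETECTED if flag else np.nan for flag in row]
                for fid, row in patterns.items()
            },
            orient="index",
            columns=[s.sample_id for s in design],
        )
        m = QuantMatrix(df, design, "glycosite")
        part = filter_glyco_sites(m)
        buckets = (
            part.testable.feature_ids
            + part.exclusive_control
            + part.exclusive_mutant
            + part.filtered_out
        )
        assert sorted(buckets) == sorted(patterns)


class TestGlycoTest:
    def test_flat_rows_unchanged_p_one(self, make_matrix):
        m = make_matrix({"f": [2**16] * 8})
        _, res = partition_and_test(m)
        row = res.iloc[0]
        assert row.p_value == 1.0 and row.status == UNCHANGED

    def test_complete_separation_is_decreased(self, make_matrix):
        # equal variances, controls strictly above mutants
        ctrl = [2**16.2, 2**16.1, 2**15.9, 2**15.8]
        mut = [2**14.2, 2**14.1, 2**13.9, 2**13.8]
        m = make_matrix({"f": ctrl + mut})
        _, res = partition_and_test(m)
        row = res.iloc[0]
        # oracle: Welch on the log2 values via the t distribution
        ref = stats.ttest_ind(np.log2(mut), np.log2(ctrl), equal_var=False)
        assert row.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        assert row.p_value < 0.05 and row.status == DECREASED

    def test_low_mutant_coverage_flagged_unchanged(self, make_matrix):
        m = make_matrix({"f": [1000, 1100, 900, None, 500, None, None, None]})
        _, res = partition_and_test(m)
        row = res.iloc[0]
        assert row.status == UNCHANGED and row.flag == "low_coverage"
        assert np.isnan(row.p_value)

    def test_exclusives_reported_with_counts(self, make_matrix):
        m = make_matrix(
            {
                "ec": [1000, 1100, 900, 1050, None, None, None, None],
                "em": [None, None, None, None, 1000, 1100, 900, None],
            }
        )
        _, res = partition_and_test(m)
        res = res.set_index("feature_id")
        assert res.loc["ec", "status"] == EXCLUSIVE_CONTROL
        assert res.loc["ec", "n_detected_control"] == 4
        assert res.loc["em", "status"] == EXCLUSIVE_MUTANT
        assert res.loc["em", "n_detected_mutant"] == 3
        assert res["q_value"].isna().all()

    def test_every_feature_appears_once_in_results(self, make_matrix):
        rng = np.random.default_rng(3)
        rows = {}
        for i in range(60):
            vals = rng.lognormal(12, 1, 8)
            mask = rng.random(8) < 0.35
            rows[f"f{i}"] = [None if m else v for v, m in zip(vals, mask)]
        m = make_matrix(rows)
        part, res = partition_and_test(m)
        assert sorted(res.feature_id) == sorted(
            part.testable.feature_ids + part.exclusive_control + part.exclusive_mutant
        )
        assert len(res) + len(part.filtered_out) == 60
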