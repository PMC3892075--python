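"""Cohort statistics: 2x2 diagnostics, exact rank tests, group summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mibgtools import (
    PatientRecord,
    TwoByTwo,
    crosstab,
    diagnostic_metrics,
    group_summary,
    paired_rank_test,
    unpaired_rank_test,
)


def records(pairs):
    return [
        PatientRecord(id=i + 1, defect_post=d, relapse=r)
        for i, (d, r) in enumerate(pairs)
    ]


class TestCrosstab:
    def test_published_counts(self):
        cohort = records([(True, True)] * 4 + [(True, False)] * 6
                         + [(False, True)] * 1 + [(False, False)] * 5)
        t = crosstab(cohort)
        assert (t.tp, t.fp, t.fn, t.tn) == (4, 6, 1, 5)

    def test_all_positive(self):
        t = crosstab(records([(True, True)] * 7))
        assert (t.tp, t.fp, t.fn, t.tn) == (7, 0, 0, 0)

    def test_matches_counting_loop_and_counts_exclusions(self, rng):
        pairs = [(bool(d), bool(r)) for d, r in rng.integers(0, 2, size=(50, 2))]
        cohort = records(pairs)
        cohort.append(PatientRecord(id=99, defect_post=None, relapse=True))
        t = crosstab(cohort)
        tp = sum(1 for d, r in pairs if d and r)
        fp = sum(1 for d, r in pairs if d and not r)
        fn = sum(1 for d, r in pairs if not d and r)
        tn = sum(1 for d, r in pairs if not d and not r)
        assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)
        assert t.n_excluded == 1

    def test_empty_after_exclusion_is_an_error(self):
        with pytest.raises(ValueError):
            crosstab([PatientRecord(id=1, defect_post=None, relapse=True)])

    def test_order_invariance(self, rng):
        pairs = [(bool(d), bool(r)) for d, r in rng.integers(0, 2, size=(30, 2))]
        a = crosstab(records(pairs))
        shuffled = records(pairs)
        rng.shuffle(shuffled)
        b = crosstab(shuffled)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


class TestDiagnosticMetrics:
    def test_published_table(self):
        m = diagnostic_metrics(TwoByTwo(tp=4, fp=6, fn=1, tn=5))
        assert m.as_printed() == {
            "sensitivity": 80, "specificity": 45, "ppv": 40, "npv": 83
        }

    def test_degenerate_table_marks_undefined_fields(self):
        m = diagnostic_metrics(TwoByTwo(tp=9, fp=0, fn=0, tn=0))
        assert m.sensitivity == 100.0 and m.ppv == 100.0
        assert m.specificity is None and m.npv is None

    def test_matches_closed_forms(self, rng):
        tp, fp, fn, tn = rng.integers(1, 30, 4)
        m = diagnostic_metrics(TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn))
        assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        assert m.specificity == pytest.approx(100 * tn / (tn + fp))
        assert m.ppv == pytest.approx(100 * tp / (tp + fp))
        assert m.npv == pytest.approx(100 * tn / (tn + fn))


def brute_wilcoxon_p(diffs):
    """Enumeration oracle: two-sided p of the signed-rank test by listing
    every sign vector explicitly."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([1, -1], repeat=len(ranks))
    ]
    n = len(ws)
    le = sum(w <= w_obs + 1e-9 for w in ws) / n
    ge = sum(w >= w_obs - 1e-9 for w in ws) / n
    return min(1.0, 2.0 * min(le, ge))


def brute_mannwhitney_p(a, b):
    """Enumeration oracle over all group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na = len(a)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = [
        sum(ranks[list(idx)]) - na * (na + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), na)
    ]
    n = len(us)
    le = sum(u <= u_obs + 1e-9 for u in us) / n
    ge = sum(u >= u_obs - 1e-9 for u in us) / n
    return min(1.0, 2.0 * min(le, ge))


class TestPairedRankTest:
    def test_five_positive_differences_give_exact_p(self):
        res = paired_rank_test([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            pre = rng.integers(0, 5, n).astype(float)
            post = pre + rng.integers(-3, 4, n)
            if np.all(post == pre):
                post[0] += 1
            res = paired_rank_test(pre, post)
            assert res.p_value == pytest.approx(brute_wilcoxon_p(post - pre))

    def test_matches_scipy_on_tie_free_data(self, rng):
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.5, 1.0, size=12)
        res = paired_rank_test(pre, post)
        ref = sps.wilcoxon(post, pre, mode="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_statistic_symmetric_under_sign_flip(self, rng):
        pre = np.zeros(10)
        post = rng.normal(size=10)
        fwd = paired_rank_test(pre, post)
        rev = paired_rank_test(post, pre)
        n = fwd.n_used
        assert fwd.statistic + rev.statistic == pytest.approx(n * (n + 1) / 2)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_zero_differences_dropped_and_counted(self):
        res = paired_rank_test([1, 2, 3, 4], [1, 2, 5, 6])
        assert res.n_zero_dropped == 2
        assert res.n_used == 2

    def test_all_zero_differences_is_an_error(self):
        with pytest.raises(ValueError):
            paired_rank_test([1, 2, 3], [1, 2, 3])

    def test_approximation_branch_close_to_exact(self, rng):
        pre = rng.normal(size=25)
        post = pre + rng.normal(0.3, 1.0, size=25)
        exact = paired_rank_test(pre, post, exact_max_n=30)
        approx = paired_rank_test(pre, post, exact_max_n=10)
        assert approx.method == "normal_approx"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


class TestUnpairedRankTest:
    def test_complete_separation_small_groups(self):
        res = unpaired_rank_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_multisets_give_p_one(self):
        res = unpaired_rank_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_single_swap_from_extreme_ordering_increases_p(self):
        extreme = unpaired_rank_test([1, 2, 3], [4, 5, 6]).p_value
        swapped = unpaired_rank_test([1, 2, 4], [3, 5, 6]).p_value
        assert swapped > extreme

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(15):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.integers(0, 4, na).astype(float)
            b = rng.integers(0, 4, nb).astype(float)
            res = unpaired_rank_test(a, b)
            assert res.p_value == pytest.approx(brute_mannwhitney_p(a, b))

    def test_matches_scipy_on_tie_free_data(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(0.8, 1.0, size=7)
        res = unpaired_rank_test(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_rank_test([], [1, 2])


class TestGroupSummary:
    def _cohort(self):
        vols = {True: [99, 122, 123, 183, None], False: [72, 118, 76, 82, 125]}
        cohort = []
        i = 0
        for rel, vs in vols.items():
            for v in vs:
                i += 1
                cohort.append(PatientRecord(id=i, relapse=rel, la_volume_ml=v))
        return cohort

    def test_sample_sd_and_missing_exclusion(self):
        out = group_summary(self._cohort(), "la_volume_ml", "relapse")
        rel = out[True]
        assert rel.n == 4 and rel.n_missing == 1
        vals = np.array([99, 122, 123, 183], float)
        assert rel.mean == pytest.approx(vals.mean())
        assert rel.sd == pytest.approx(vals.std(ddof=1))

    def test_constant_field_has_zero_sd(self):
        cohort = [PatientRecord(id=i, relapse=False, la_volume_ml=70.0) for i in range(1, 5)]
        out = group_summary(cohort, "la_volume_ml", "relapse")
        assert out[False].sd == 0.0

    def test_two_point_group_closed_form(self):
        a, b = 60.0, 100.0
        cohort = [PatientRecord(id=1, relapse=True, la_volume_ml=a),
                  PatientRecord(id=2, relapse=True, la_volume_ml=b)]
        out = group_summary(cohort, "la_volume_ml", "relapse")
        assert out[True].sd == pytest.approx(abs(a - b) / math.sqrt(2))

    def test_single_observation_group_has_undefined_sd(self):
        cohort = [PatientRecord(id=1, relapse=True, la_volume_ml=80.0)]
        out = group_summary(cohort, "la_volume_ml", "relapse")
        assert out[True].sd is None

    def test_empty_group_is_an_error(self):
        cohort = [PatientRecord(id=1, relapse=True, la_volume_ml=None)]
        with pytest.raises(ValueError):
            group_summary(cohort, "la_volume_ml", "relapse")
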