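"""Cohort-level statistics in the style of small nuclear-cardiology series.

Covers the 2x2 diagnostic performance of post-ablation innervation deficits
for AF relapse (sensitivity, specificity, PPV, NPV, reported to the nearest
integer percent), nonparametric paired (Wilcoxon signed-rank) and unpaired
(Mann-Whitney U) comparisons with exact small-sample null distributions, and
mean +/- SD group summaries with explicit missing-data exclusion.

Exact p-values use the doubled smaller one-sided tail, capped at 1 — the
common convention for discrete tests.  Zero differences in the signed-rank
test are dropped (and counted); ties receive midranks in both tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "TwoByTwo",
    "DiagnosticMetrics",
    "RankTestResult",
    "GroupSummary",
    "crosstab",
    "diagnostic_metrics",
    "paired_rank_test",
    "unpaired_rank_test",
    "group_summary",
    "cohort_to_frame",
]


@dataclass
class PatientRecord:
    """One patient's clinical fields plus computed imaging metrics.

    Missing values are ``None``.  ``relapse`` is AF recurrence within the
    follow-up window; ``defect_pre``/``defect_post`` are the innervation
    deficit verdicts before/after pulmonary vein isolation.
    """

    id: int
    sex: str | None = None
    age: float | None = None
    af_duration: float | None = None
    chd: str | None = None
    la_volume_ml: float | None = None
    relapse: bool | None = None
    defect_pre: bool | None = None
    defect_post: bool | None = None
    sds_pre: int | None = None
    sds_post: int | None = None
    hm_late_pre: float | None = None
    hm_late_post: float | None = None
    wr_pre: float | None = None
    wr_post: float | None = None

    def __post_init__(self) -> None:
        if self.la_volume_ml is not None and self.la_volume_ml <= 0:
            raise ValueError("left atrial volume must be positive when present")
        for name in ("sds_pre", "sds_post"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 68):
                raise ValueError(f"{name} outside the valid SDS range 0..68")


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{f.name: getattr(p, f.name) for f in fields(PatientRecord)} for p in cohort]
    )


@dataclass
class TwoByTwo:
    """Counts with test = post-PVI deficit and condition = AF relapse."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticMetrics:
    """Diagnostic performance in percent; ``None`` marks an undefined field
    (zero denominator).  ``rounding`` records the printing convention."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    rounding: str = "nearest_integer"

    def as_printed(self) -> dict[str, int | None]:
        return {
            k: (None if v is None else round(v))
            for k, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def crosstab(cohort: list[PatientRecord]) -> TwoByTwo:
    """2x2 table of post-PVI deficit against relapse.

    Patients missing either field are excluded with a logged count; an
    empty table after exclusions is an error.
    """
    kept = [p for p in cohort if p.defect_post is not None and p.relapse is not None]
    n_excluded = len(cohort) - len(kept)
    if n_excluded:
        log.info("crosstab: excluded %d patients with missing fields", n_excluded)
    if not kept:
        raise ValueError("no patient has both defect_post and relapse recorded")
    tp = sum(p.defect_post and p.relapse for p in kept)
    fp = sum(p.defect_post and not p.relapse for p in kept)
    fn = sum((not p.defect_post) and p.relapse for p in kept)
    tn = sum((not p.defect_post) and not p.relapse for p in kept)
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded=n_excluded)


def diagnostic_metrics(t: TwoByTwo) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV in percent.

    Never divides by zero: a field whose denominator is empty is ``None``.
    """

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=pct(t.tp, t.tp + t.fn),
        specificity=pct(t.tn, t.tn + t.fp),
        ppv=pct(t.tp, t.tp + t.fp),
        npv=pct(t.tn, t.tn + t.fn),
    )


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    method: str
    n_used: int
    n_zero_dropped: int = 0


def _doubled_tail(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def paired_rank_test(
    pre, post, exact_max_n: int = 20
) -> RankTestResult:
    """Wilcoxon signed-rank test on paired samples (two-sided).

    Zero differences are dropped with a logged count; absolute differences
    receive midranks.  With at most ``exact_max_n`` nonzero differences the
    null distribution of W+ is enumerated exactly over all sign assignments
    (tie-aware); beyond that a normal approximation with tie correction is
    used.  The two-sided p doubles the smaller one-sided tail, capped at 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    d = post - pre
    n_zero = int(np.sum(d == 0))
    if n_zero:
        log.info("paired_rank_test: dropped %d zero differences", n_zero)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # Tie-aware exact null: DP convolution over doubled midranks
        # (doubling makes .5 midranks integral).
        scaled = np.rint(2 * ranks).astype(np.int64)
        total = int(scaled.sum())
        dist = np.zeros(total + 1, dtype=float)
        dist[0] = 1.0
        for r in scaled:
            dist[r:] += dist[: total + 1 - r]
        dist /= dist.sum()
        w2 = int(np.rint(2 * w_plus))
        p = _doubled_tail(dist[: w2 + 1].sum(), dist[w2:].sum())
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RankTestResult(
        statistic=w_plus, p_value=float(p), method=method,
        n_used=n, n_zero_dropped=n_zero,
    )


def unpaired_rank_test(
    a, b, exact_max_combinations: int = 200_000
) -> RankTestResult:
    """Mann-Whitney U test on two independent samples (two-sided).

    The null distribution of U is enumerated exactly over all group
    assignments whenever C(n_a + n_b, n_a) <= ``exact_max_combinations``
    (tie-aware via midranks); otherwise a normal approximation with tie
    correction is used.  Two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    n = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:na].sum()) - na * (na + 1) / 2.0
    n_comb = math.comb(n, na)
    if n_comb <= exact_max_combinations:
        base = na * (na + 1) / 2.0
        us = np.fromiter(
            (sum(ranks[list(idx)]) - base for idx in itertools.combinations(range(n), na)),
            dtype=float,
            count=n_comb,
        )
        cdf_le = float(np.mean(us <= u_a + 1e-9))
        cdf_ge = float(np.mean(us >= u_a - 1e-9))
        p = _doubled_tail(cdf_le, cdf_ge)
        method = "exact"
    else:
        mean = na * nb / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        z = (u_a - mean) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RankTestResult(statistic=u_a, p_value=float(p), method=method, n_used=n)


@dataclass
class GroupSummary:
    group: object
    mean: float
    sd: float | None
    n: int
    n_missing: int


def group_summary(
    cohort: list[PatientRecord] | pd.DataFrame,
    value_field: str,
    group_field: str,
) -> dict[object, GroupSummary]:
    """Mean +/- sample SD (n-1 denominator) of ``value_field`` per level of
    ``group_field``.  Missing values are excluded and counted; a group left
    empty is an error; a single-observation group has ``sd=None``.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    out: dict[object, GroupSummary] = {}
    for g, sub in df.groupby(group_field, dropna=False):
        vals = pd.to_numeric(sub[value_field], errors="coerce").dropna()
        n_missing = len(sub) - len(vals)
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has no observed {value_field}")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
        out[g] = GroupSummary(
            group=g, mean=float(vals.mean()), sd=sd, n=len(vals), n_missing=n_missing
        )
    return out
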