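"""Subtype-annotation and subtype-survival statistics.

Overlap between two label sets is scored per label pair by the one-sided
(enrichment) Fisher exact test — the upper hypergeometric tail including the
observed overlap count.  Survival differences between groups use the
Kaplan-Meier product-limit estimator and the multi-group log-rank test;
continuous score differences use the Mann-Whitney U test with midrank ties.
No multiple-testing correction is applied by default; a Benjamini-Hochberg
helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .dataio import ValidationError


@dataclass
class SurvivalData:
    """Per-sample survival time (days), event flag, and group label."""

    time: pd.Series
    event: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        for s in ("time", "event", "group"):
            val = getattr(self, s)
            if not isinstance(val, pd.Series):
                setattr(self, s, pd.Series(val))
        if not (self.time.index.equals(self.event.index) and self.time.index.equals(self.group.index)):
            raise ValidationError("time/event/group must share the same samples")
        if (self.time < 0).any():
            raise ValidationError("negative survival time")

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame, group_col: str) -> "SurvivalData":
        keep = annotation["surv_time"].notna() & annotation[group_col].notna()
        sub = annotation.loc[keep]
        return cls(
            time=sub["surv_time"],
            event=sub["surv_event"].astype(int),
            group=sub[group_col].astype(str),
        )


def fisher_enrichment_p(k: int, n_a: int, n_b: int, n_total: int) -> float:
    """One-sided Fisher (enrichment) p for an overlap of ``k`` samples.

    ``n_a`` samples carry label A, ``n_b`` carry label B, out of ``n_total``;
    the p-value is the upper hypergeometric tail P(X >= k) including the
    observed count.
    """
    if not (0 <= k <= min(n_a, n_b) and n_a <= n_total and n_b <= n_total):
        raise ValidationError("inconsistent 2x2 margins")
    return float(stats.hypergeom.sf(k - 1, n_total, n_a, n_b))


def overlap_enrichment(
    labels_a: dict[str, str] | pd.Series,
    labels_b: dict[str, str] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided Fisher enrichment p-values for every (label_a, label_b) pair.

    Only samples present in both label sets enter the 2x2 tables.  Returns
    (p_values, overlap_counts), each label_a x label_b.
    """
    a = pd.Series(dict(labels_a)) if not isinstance(labels_a, pd.Series) else labels_a
    b = pd.Series(dict(labels_b)) if not isinstance(labels_b, pd.Series) else labels_b
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between the two label sets")
    a, b = a.loc[shared], b.loc[shared]
    n_total = len(shared)
    la = sorted(a.unique())
    lb = sorted(b.unique())
    pvals = pd.DataFrame(index=la, columns=lb, dtype=float)
    counts = pd.DataFrame(index=la, columns=lb, dtype=int)
    for x in la:
        in_a = a == x
        for y in lb:
            in_b = b == y
            k = int((in_a & in_b).sum())
            pvals.loc[x, y] = fisher_enrichment_p(k, int(in_a.sum()), int(in_b.sum()), n_total)
            counts.loc[x, y] = k
    return pvals, counts


def benjamini_hochberg(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def km_estimate(surv: SurvivalData) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curve per group.

    Censored times reduce the risk set without producing a step; at tied
    times, events are processed before censorings (the standard convention).
    Returns per group a (time, survival) step-function table starting at
    S(0) = 1.
    """
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(surv.group.unique()):
        mask = surv.group == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(surv: SurvivalData) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi-square, df, p)."""
    groups = surv.group.unique()
    if len(groups) < 2:
        raise ValidationError("log-rank test needs >=2 groups")
    if int(surv.event.sum()) < 1:
        raise ValidationError("log-rank test needs >=1 event")
    res = multivariate_logrank_test(surv.time, surv.group, surv.event)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when the combined sample is small (n <= 12) with no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction.  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank-sum test requires nonempty samples")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
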