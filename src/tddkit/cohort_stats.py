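"""Group-level statistics: exact 2x2 association, paired time-point
comparison, and Holm-Bonferroni step-down correction.

The central group analysis is a one-sided Fisher exact test of whether
patients with lesions in somatosensory "target" areas have a higher
incidence of TDD impairment than patients lesioned elsewhere, together with
the matching one-sided conditional exact confidence bound on the odds ratio
(noncentral hypergeometric inversion; the upper end is infinite whenever the
observed count sits at its conditional maximum, as it does when every
target-lesion patient is impaired).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_one_sided",
    "fisher_or_ci",
    "fisher_or_ci_lower",
    "paired_t",
    "holm_bonferroni",
]


class ContingencyTable2x2(NamedTuple):
    """Counts with rows = lesion group (target, other) and columns =
    (impaired, not impaired)."""

    a: int  # target lesion, impaired
    b: int  # target lesion, not impaired
    c: int  # other lesion, impaired
    d: int  # other lesion, not impaired

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("table is empty")
        return cls(*(int(x) for x in arr.ravel()))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_one_sided(table) -> float:
    """One-sided Fisher exact p: hypergeometric upper-tail P(X >= a)
    conditional on the margins, for the alternative that the first row
    (target-lesion group) has the higher impairment odds.  Degenerate
    margins give p = 1 by convention."""
    t = ContingencyTable2x2.from_array(table)
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="greater")[1])


class OddsRatioCI(NamedTuple):
    lower: float
    upper: float
    confidence: float


def _cond_upper_tail(t: ContingencyTable2x2, odds: float) -> float:
    """P(X >= a) under Fisher's noncentral hypergeometric with the observed
    margins: M patients total, row-1 size a+b, column-1 size a+c."""
    M = t.a + t.b + t.c + t.d
    return float(stats.nchypergeom_fisher.sf(t.a - 1, M, t.a + t.b, t.a + t.c, odds))


def fisher_or_ci(table, confidence: float = 0.95) -> OddsRatioCI:
    """One-sided conditional exact CI for the odds ratio.

    The lower bound is the odds parameter at which the conditional upper
    tail P(X >= a) equals 1 - confidence, found by monotone root solving on
    the log-odds scale.  When the observed count is at its conditional
    maximum the upper bound is infinite; when at its minimum the lower bound
    is 0.
    """
    t = ContingencyTable2x2.from_array(table)
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    lo_support = max(0, (t.a + t.b) - (t.b + t.d))
    hi_support = min(t.a + t.b, t.a + t.c)
    upper = np.inf if t.a == hi_support else _invert(t, alpha, side="upper")
    if t.a == lo_support:
        return OddsRatioCI(0.0, upper, confidence)

    def f(log_odds: float) -> float:
        return _cond_upper_tail(t, float(np.exp(log_odds))) - alpha

    # bracket the root: the tail is increasing in the odds parameter
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) < 0:
            break
        lo -= 2.0
    else:
        raise RuntimeError(f"CI lower bound: no bracket below exp({lo})")
    for _ in range(200):
        if f(hi) > 0:
            break
        hi += 2.0
    else:
        raise RuntimeError(f"CI lower bound: no bracket above exp({hi})")
    root = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return OddsRatioCI(float(np.exp(root)), upper, confidence)


def _invert(t: ContingencyTable2x2, alpha: float, side: str) -> float:
    """Upper confidence bound: odds at which P(X <= a) = alpha."""
    M = t.a + t.b + t.c + t.d

    def f(log_odds: float) -> float:
        return float(stats.nchypergeom_fisher.cdf(
            t.a, M, t.a + t.b, t.a + t.c, np.exp(log_odds))) - alpha

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if f(lo) > 0:
            break
        lo -= 2.0
    for _ in range(200):
        if f(hi) < 0:
            break
        hi += 2.0
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)))


def fisher_or_ci_lower(table, confidence: float = 0.95) -> float:
    """Lower bound of the one-sided conditional exact odds-ratio CI."""
    return fisher_or_ci(table, confidence).lower


class PairedTResult(NamedTuple):
    mean_diff: float
    t: float
    df: int
    p: float


def paired_t(pre: Sequence[float], post: Sequence[float]) -> PairedTResult:
    """Classical paired t-test on (pre - post), pairing by position.

    Differences are earlier-minus-later, so a positive mean difference on
    relative TDD scores means improvement over time.  Zero variance of the
    differences leaves t and p undefined (NaN).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and the same length")
    if len(pre) < 2:
        raise ValueError("need >=2 pairs")
    d = pre - post
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical series: no change anywhere
            return PairedTResult(0.0, 0.0, len(d) - 1, 1.0)
        return PairedTResult(float(d.mean()), np.nan, len(d) - 1, np.nan)
    res = stats.ttest_rel(pre, post)
    return PairedTResult(mean_diff=float(d.mean()), t=float(res.statistic),
                         df=len(d) - 1, p=float(res.pvalue))


class HolmResult(NamedTuple):
    reject: np.ndarray          # aligned with the input p-values
    critical_alphas: np.ndarray  # ascending-p order: alpha/(m-k+1), k=1..m
    adjusted_p: np.ndarray       # aligned step-down adjusted p-values


def holm_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm step-down multiple-comparison procedure.

    The k-th smallest p-value is compared with alpha/(m-k+1); testing stops
    at the first failure.  With two tests the critical alphas are 0.025 and
    0.05.  Rejections are a superset of Bonferroni's and a subset of the
    unadjusted alpha rule.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    crit = alpha / (m - np.arange(m))
    reject_sorted = np.zeros(m, bool)
    for k in range(m):
        if p[order[k]] <= crit[k]:
            reject_sorted[k] = True
        else:
            break
    reject = np.zeros(m, bool)
    reject[order] = reject_sorted
    adj_sorted = np.maximum.accumulate(np.minimum(p[order] * (m - np.arange(m)), 1.0))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return HolmResult(reject=reject, critical_alphas=crit, adjusted_p=adj)
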