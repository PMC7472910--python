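"""Single-case deficit tests against a small normative sample.

These are the classic small-sample t procedures for asking whether one
patient's score is abnormally extreme relative to a modest control group:
the case-versus-sample test (a modified t treating the case as a new draw
from the control population) and the case-versus-regression test (the same
idea applied to the residual from an age-predicted value).  Both yield an
estimated percentile of the case in the control population; here higher TDD
scores mean poorer discrimination, so "worse than 90% of controls" means an
estimated percentile above 90 with the one-tailed alternative toward high
scores.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normative import NormativeSample, ThresholdModel

__all__ = [
    "CrawfordResult",
    "crawford_howell_test",
    "crawford_regression_test",
    "compare_classification_strategies",
]

_TAILS = ("greater", "less", "two-sided")


class CrawfordResult(NamedTuple):
    t: float
    df: int
    p: float
    percentile: float  # estimated % of controls scoring below the case


def _tail_p(t: float, df: int, tail: str) -> float:
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    return float(2 * stats.t.sf(abs(t), df))


def crawford_howell_test(
    case_score: float,
    sample_mean: float,
    sample_sd: float,
    n: int,
    tail: str = "greater",
) -> CrawfordResult:
    """Case versus normative sample.

    t = (case - mean) / (sd * sqrt((n+1)/n)), df = n-1.  The estimated
    percentile is the one-tailed probability that a control scores below the
    case, times 100.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    if n < 2:
        raise ValueError("normative sample must have n >= 2")
    if sample_sd <= 0:
        raise ValueError("sample_sd must be positive")
    t = (float(case_score) - float(sample_mean)) / (sample_sd * np.sqrt((n + 1) / n))
    df = n - 1
    return CrawfordResult(t=float(t), df=df, p=_tail_p(t, df, tail),
                          percentile=float(stats.t.cdf(t, df) * 100))


def crawford_regression_test(
    case_age: float,
    case_score: float,
    ages: Sequence[float],
    scores: Sequence[float],
    tail: str = "greater",
) -> CrawfordResult:
    """Case versus the age-regression line of the normative sample.

    Fits score ~ age by OLS on the controls and tests the case's residual
    against the prediction-interval standard error

        s_resid * sqrt(1 + 1/n + (age - mean_age)^2 / SS_age),  df = n-2.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    ages = np.asarray(ages, float)
    scores = np.asarray(scores, float)
    n = len(ages)
    if n < 3 or len(scores) != n:
        raise ValueError("need >=3 (age, score) control records")
    if np.ptp(ages) == 0:
        raise ValueError("constant age: regression not identifiable")
    slope, intercept = np.polyfit(ages, scores, 1)
    resid = scores - (slope * ages + intercept)
    df = n - 2
    s_resid = float(np.sqrt(np.sum(resid ** 2) / df))
    ss_age = float(np.sum((ages - ages.mean()) ** 2))
    se = s_resid * np.sqrt(1 + 1 / n + (float(case_age) - ages.mean()) ** 2 / ss_age)
    if se == 0:
        raise ValueError("zero residual variance: test degenerate")
    t = (float(case_score) - (slope * float(case_age) + intercept)) / se
    return CrawfordResult(t=float(t), df=df, p=_tail_p(t, df, tail),
                          percentile=float(stats.t.cdf(t, df) * 100))


def compare_classification_strategies(
    cohort: pd.DataFrame,
    hand_sample: NormativeSample,
    foot_sample: NormativeSample,
    hand_model: ThresholdModel,
    foot_model: ThresholdModel,
    percentile_cut: float = 90.0,
) -> pd.DataFrame:
    """Concordance between the two impairment-classification strategies.

    Strategy A: raw score above the normative-percentile threshold model
    (flat for the hand, age-linear for the foot).  Strategy B: Crawford
    estimated percentile > ``percentile_cut`` (case-vs-sample for the hand,
    case-vs-regression for the foot, one-tailed toward worse scores).

    ``cohort`` needs columns: patient, age, and raw scores ``raw_{site}``
    for sites r_hand, l_hand, r_foot, l_foot.  Returns a per-patient frame
    with both overall flags and a ``concordant`` column; discordant patients
    are those where the two strategies disagree.
    """
    h_mean = float(hand_sample.scores.mean())
    h_sd = float(hand_sample.scores.std(ddof=1))
    h_n = len(hand_sample.scores)
    rows = []
    for _, rec in cohort.iterrows():
        abn_thr = abn_cw = False
        for site in ("r_hand", "l_hand", "r_foot", "l_foot"):
            raw = float(rec[f"raw_{site}"])
            age = float(rec["age"])
            if site.endswith("hand"):
                thr = hand_model(age)
                cw = crawford_howell_test(raw, h_mean, h_sd, h_n, tail="greater")
            else:
                thr = foot_model(age)
                cw = crawford_regression_test(
                    age, raw, foot_sample.ages, foot_sample.scores, tail="greater")
            abn_thr |= raw > thr
            abn_cw |= cw.percentile > percentile_cut
        rows.append({"abnormal_threshold": abn_thr,
                     "abnormal_crawford": abn_cw,
                     "concordant": abn_thr == abn_cw})
    out = pd.DataFrame(rows)
    out.insert(0, "patient", cohort["patient"].to_numpy())
    return out
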