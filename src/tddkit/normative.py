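"""Normative thresholds and abnormality classification for TDD scores.

A raw TDD score (18-186, higher = worse) is judged against a cutoff derived
from a healthy normative sample: the 90th percentile of normative scores,
either per decade age band (flat model, used for the hand, where scores show
a floor effect and no age trend) or as a linear function of age (used for
the foot, where discrimination declines roughly linearly with age).  Patient
performance is expressed as a relative score

    relative = (raw - threshold) / threshold

so that positive values mean worse than the normative cutoff.  A test site
is abnormal when its relative score exceeds zero or when an examiner-supplied
side-difference flag marks an abnormal left/right asymmetry; a patient is
abnormal when any tested site is.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_AGE_BANDS",
    "NormativeSample",
    "ThresholdModel",
    "SiteResult",
    "fit_flat_threshold",
    "fit_linear_threshold",
    "age_effect_test",
    "sex_effect_test",
    "relative_score",
    "classify_sites",
    "classify_patient",
    "classify_cohort",
    "interexaminer_agreement",
]

SCORE_MIN, SCORE_MAX = 18, 186

#: Decade bands used for the flat (hand) threshold: 20-29 ... 60-69.
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (20, 29), (30, 39), (40, 49), (50, 59), (60, 69),
)


@dataclass
class NormativeSample:
    """Healthy-control scores for one test site (hand or foot)."""

    site: str  # "hand" | "foot"
    records: pd.DataFrame  # columns: age, sex, raw_score

    def __post_init__(self) -> None:
        if self.site not in ("hand", "foot"):
            raise ValueError("site must be 'hand' or 'foot'")
        df = pd.DataFrame(self.records)
        missing = {"age", "sex", "raw_score"} - set(df.columns)
        if missing:
            raise ValueError(f"normative table missing columns {sorted(missing)}")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad = ~df["raw_score"].between(SCORE_MIN, SCORE_MAX)
        if bad.any():
            raise ValueError(
                f"raw scores outside [{SCORE_MIN}, {SCORE_MAX}] at rows "
                f"{df.index[bad].tolist()}")
        self.records = df

    @property
    def ages(self) -> np.ndarray:
        return self.records["age"].to_numpy(float)

    @property
    def scores(self) -> np.ndarray:
        return self.records["raw_score"].to_numpy(float)


def _validate_bands(bands: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    bands = [tuple(b) for b in bands]
    for lo, hi in bands:
        if hi < lo:
            raise ValueError(f"band {lo}-{hi} reversed")
    for (a_lo, a_hi), (b_lo, b_hi) in zip(bands, bands[1:]):
        if b_lo <= a_hi:
            raise ValueError("age bands must be ordered and non-overlapping")
    return bands


@dataclass
class ThresholdModel:
    """Impairment cutoff: flat per age band, or linear in age.

    Linear form: threshold(age) = slope * age + intercept, extrapolated
    linearly outside the normative age range (stroke patients can be older
    than the oldest control).
    """

    kind: str  # "flat" | "linear"
    threshold: float | None = None            # pooled flat value
    band_thresholds: dict | None = None       # {(lo, hi): value}
    slope: float | None = None
    intercept: float | None = None
    quantile: float = 0.90
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "linear"):
            raise ValueError("kind must be 'flat' or 'linear'")
        if self.kind == "flat":
            vals = ([self.threshold] if self.threshold is not None else []) + \
                list((self.band_thresholds or {}).values())
            if not vals:
                raise ValueError("flat model needs a threshold")
            for v in vals:
                if not SCORE_MIN < v < SCORE_MAX:
                    raise ValueError(f"flat threshold {v} outside ({SCORE_MIN}, {SCORE_MAX})")
        else:
            if self.slope is None or self.intercept is None:
                raise ValueError("linear model needs slope and intercept")

    def __call__(self, age: float) -> float:
        if self.kind == "linear":
            return self.slope * float(age) + self.intercept
        if self.band_thresholds:
            for (lo, hi), v in self.band_thresholds.items():
                if lo <= age <= hi:
                    return v
            if self.threshold is not None:  # outside all bands: pooled fallback
                return self.threshold
            # nearest band when no pooled value available
            key = min(self.band_thresholds,
                      key=lambda b: min(abs(age - b[0]), abs(age - b[1])))
            return self.band_thresholds[key]
        return self.threshold

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        obj = {"kind": self.kind, "quantile": self.quantile}
        if self.kind == "flat":
            obj["threshold"] = self.threshold
            if self.band_thresholds:
                obj["band_thresholds"] = [
                    {"lo": lo, "hi": hi, "threshold": v}
                    for (lo, hi), v in self.band_thresholds.items()]
        else:
            obj["slope"], obj["intercept"] = self.slope, self.intercept
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdModel":
        obj = json.loads(text)
        bands = None
        if obj.get("band_thresholds"):
            bands = {(b["lo"], b["hi"]): b["threshold"] for b in obj["band_thresholds"]}
        return cls(kind=obj["kind"], threshold=obj.get("threshold"),
                   band_thresholds=bands, slope=obj.get("slope"),
                   intercept=obj.get("intercept"), quantile=obj.get("quantile", 0.90))


class SiteResult(NamedTuple):
    raw_score: float
    threshold: float
    relative_score: float
    abnormal: bool
    side_diff_flag: bool


def fit_flat_threshold(
    sample: NormativeSample,
    bands: Sequence[tuple[int, int]] | None = DEFAULT_AGE_BANDS,
    quantile: float = 0.90,
) -> ThresholdModel:
    """Per-age-band 90th-percentile cutoff (linear-interpolation quantile).

    With ``bands=None`` a single pooled percentile is returned.  A band with
    fewer than two usable records inherits the pooled threshold (warning).
    """
    pooled = float(np.quantile(sample.scores, quantile, method="linear"))
    if bands is None:
        return ThresholdModel(kind="flat", threshold=pooled, quantile=quantile,
                              meta={"site": sample.site, "n": len(sample.scores)})
    band_thr: dict[tuple[int, int], float] = {}
    for lo, hi in _validate_bands(bands):
        in_band = sample.scores[(sample.ages >= lo) & (sample.ages <= hi)]
        if len(in_band) < 2:
            warnings.warn(
                f"age band {lo}-{hi} has {len(in_band)} record(s); "
                f"using pooled threshold {pooled:.1f}", stacklevel=2)
            band_thr[(lo, hi)] = pooled
        else:
            band_thr[(lo, hi)] = float(np.quantile(in_band, quantile, method="linear"))
    return ThresholdModel(kind="flat", threshold=pooled, band_thresholds=band_thr,
                          quantile=quantile,
                          meta={"site": sample.site, "n": len(sample.scores)})


def fit_linear_threshold(sample: NormativeSample, quantile: float = 0.90) -> ThresholdModel:
    """Age-linear cutoff: OLS of score on age, intercept shifted up by the
    90th percentile of the residuals, so ~90% of normative points fall below
    the line while it keeps the fitted age slope."""
    ages, scores = sample.ages, sample.scores
    if len(np.unique(ages)) < 3:
        raise ValueError("need >=3 distinct ages to fit an age-linear threshold")
    slope, intercept = np.polyfit(ages, scores, 1)
    resid = scores - (slope * ages + intercept)
    shift = float(np.quantile(resid, quantile, method="linear"))
    return ThresholdModel(kind="linear", slope=float(slope),
                          intercept=float(intercept + shift), quantile=quantile,
                          meta={"site": sample.site, "n": len(scores),
                                "ols_intercept": float(intercept)})


class RegressionFTest(NamedTuple):
    F: float
    df: tuple[int, int]
    p: float
    slope: float


def age_effect_test(sample: NormativeSample) -> RegressionFTest:
    """F test of zero age slope in the simple linear regression of raw score
    on age; df = (1, n-2)."""
    ages, scores = sample.ages, sample.scores
    n = len(ages)
    if n < 4:
        raise ValueError("need >=4 records")
    if np.ptp(ages) == 0:
        raise ValueError("age is constant; slope not identifiable")
    if np.ptp(scores) == 0:  # flat response: no effect by construction
        return RegressionFTest(F=0.0, df=(1, n - 2), p=1.0, slope=0.0)
    slope, intercept = np.polyfit(ages, scores, 1)
    fitted = slope * ages + intercept
    ss_res = float(np.sum((scores - fitted) ** 2))
    ss_reg = float(np.sum((fitted - scores.mean()) ** 2))
    df = (1, n - 2)
    if ss_res == 0.0:
        F = np.inf if ss_reg > 0 else 0.0
    else:
        F = (ss_reg / df[0]) / (ss_res / df[1])
    p = float(stats.f.sf(F, *df)) if np.isfinite(F) else 0.0
    return RegressionFTest(F=float(F), df=df, p=p, slope=float(slope))


class RankSumTest(NamedTuple):
    U: float
    p: float


def sex_effect_test(sample: NormativeSample) -> RankSumTest:
    """Two-sided Mann-Whitney U test of a sex difference in raw scores,
    with tie correction."""
    groups = [g["raw_score"].to_numpy(float)
              for _, g in sample.records.groupby("sex")]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("both sexes must be present")
    if len(groups) > 2:
        raise ValueError("more than two sex categories")
    res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                             method="auto")
    return RankSumTest(U=float(res.statistic), p=float(res.pvalue))


def relative_score(raw: float, threshold: float) -> float:
    """(raw - threshold) / threshold; positive = worse than the cutoff."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (float(raw) - float(threshold)) / float(threshold)


def classify_sites(
    relative_scores: dict[str, float],
    side_diff_flags: dict[str, bool] | None = None,
) -> dict[str, bool]:
    """Site-level abnormality: relative score strictly greater than 0, or a
    side-difference flag.  A score exactly at the threshold is normal."""
    flags = side_diff_flags or {}
    return {site: (rel > 0) or bool(flags.get(site, False))
            for site, rel in relative_scores.items()}


class PatientClassification(NamedTuple):
    sites: dict  # site -> SiteResult
    abnormal: bool
    complete: bool


def classify_patient(
    raw_scores: dict[str, float],
    age: float,
    models: dict[str, ThresholdModel],
    side_diff_flags: dict[str, bool] | None = None,
    expected_sites: Sequence[str] = ("r_hand", "l_hand", "r_foot", "l_foot"),
) -> PatientClassification:
    """Classify one patient from raw scores and threshold models.

    ``models`` maps each site (or the generic 'hand'/'foot') to its
    ThresholdModel.  Missing sites are skipped and the record flagged
    incomplete.
    """
    flags = side_diff_flags or {}
    site_results: dict[str, SiteResult] = {}
    complete = True
    for site in expected_sites:
        if site not in raw_scores or raw_scores[site] is None or (
                isinstance(raw_scores[site], float) and np.isnan(raw_scores[site])):
            complete = False
            continue
        model = models.get(site) or models.get(site.split("_")[-1])
        if model is None:
            raise KeyError(f"no threshold model for site {site!r}")
        thr = model(age)
        rel = relative_score(raw_scores[site], thr)
        flag = bool(flags.get(site, False))
        site_results[site] = SiteResult(
            raw_score=float(raw_scores[site]), threshold=float(thr),
            relative_score=rel, abnormal=(rel > 0) or flag, side_diff_flag=flag)
    if not site_results:
        warnings.warn("no sites available; patient unclassifiable", stacklevel=2)
    return PatientClassification(
        sites=site_results,
        abnormal=any(r.abnormal for r in site_results.values()),
        complete=complete)


SITES = ("r_hand", "l_hand", "r_foot", "l_foot")


def classify_cohort(cohort: pd.DataFrame, timepoint: str = "m3") -> pd.DataFrame:
    """Classify a cohort table of *relative* scores (Table-2 dialect).

    ``cohort`` must carry columns ``{timepoint}_{site}`` for the four sites
    and boolean flag columns ``sd_{timepoint}_{site}`` (as produced by
    :func:`tddkit.io.read_cohort`).  Returns one row per patient with
    per-site abnormality and the overall flag.
    """
    out = {"patient": cohort["patient"].to_numpy()}
    any_abn = np.zeros(len(cohort), dtype=bool)
    for site in SITES:
        rel = cohort[f"{timepoint}_{site}"].to_numpy(float)
        flag_col = f"sd_{timepoint}_{site}"
        flags = cohort[flag_col].to_numpy(bool) if flag_col in cohort else np.zeros(len(cohort), bool)
        abn = (rel > 0) | flags
        out[f"{site}_abnormal"] = abn
        any_abn |= abn
    out["abnormal"] = any_abn
    return pd.DataFrame(out)


class AgreementResult(NamedTuple):
    r_squared: float
    mean_diff: float
    t: float
    p: float


def interexaminer_agreement(pairs: Sequence[tuple[float, float]]) -> AgreementResult:
    """Agreement between two examiners scoring the same participants:
    squared Pearson correlation plus a two-sided paired t-test on the
    score differences."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >=3 (score_A, score_B) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r2 = np.nan
    else:
        r2 = float(stats.pearsonr(a, b).statistic ** 2)
    d = a - b
    if np.ptp(d) == 0:
        t, p = (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
    else:
        res = stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return AgreementResult(r_squared=r2, mean_diff=float(d.mean()), t=t, p=p)
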