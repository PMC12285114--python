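"""Lifestyle classification and genetic-risk categorisation.

Six lifestyle factors (smoking, diet, physical activity, sleep duration,
BMI, waist circumference) are each flagged favourable/unfavourable; the
count of unfavourable factors maps to three lifestyle categories
(favourable 0-1, intermediate 2-4, unfavourable 5-6).  A continuous
polygenic score is stratified into low / intermediate / high risk by
quintiles (bottom / 2nd-4th / top) or, for sensitivity analyses, tertiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from typing import Literal

import numpy as np

__all__ = [
    "SmokingStatus",
    "RedMeatFreq",
    "Sex",
    "LifestyleProfile",
    "LifestyleClassification",
    "classify_lifestyle",
    "lifestyle_category_from_count",
    "categorize_prs",
    "GENETIC_RISK_LABELS",
    "LIFESTYLE_LABELS",
]

GENETIC_RISK_LABELS = ("low", "intermediate", "high")
LIFESTYLE_LABELS = ("favorable", "intermediate", "unfavorable")


class SmokingStatus(str, Enum):
    NEVER = "never"
    FORMER_BY_CHOICE = "former_by_choice"
    FORMER_BY_ILLNESS = "former_by_illness"
    CURRENT = "current"


class RedMeatFreq(str, Enum):
    DAILY = "daily"
    WEEKLY = "weekly"
    LESS_THAN_WEEKLY = "less_than_weekly"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class LifestyleProfile:
    """One participant's lifestyle measurements.

    ``total_physical_activity`` is in MET-hours/day, ``sleep_hours`` in
    hours/day, ``bmi`` in kg/m^2 and ``waist_circumference`` in cm.
    """

    smoking_status: SmokingStatus
    eats_fruit_daily: bool
    eats_veg_daily: bool
    red_meat_freq: RedMeatFreq
    total_physical_activity: float
    sleep_hours: float
    bmi: float
    waist_circumference: float
    sex: Sex
    age: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"missing lifestyle field: {f.name}")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.waist_circumference <= 0:
            raise ValueError("waist_circumference must be positive")
        if not 0 <= self.sleep_hours <= 24:
            raise ValueError("sleep_hours must be within [0, 24]")


@dataclass(frozen=True)
class LifestyleClassification:
    smoking: bool
    diet: bool
    physical_activity: bool
    sleep: bool
    bmi: bool
    waist: bool
    n_unfavorable: int
    category: Literal["favorable", "intermediate", "unfavorable"]


def lifestyle_category_from_count(n_unfavorable: int) -> str:
    """Map a count of unfavourable factors to the three-level category."""
    if not 0 <= n_unfavorable <= 6:
        raise ValueError("n_unfavorable must be in 0..6")
    if n_unfavorable <= 1:
        return "favorable"
    if n_unfavorable <= 4:
        return "intermediate"
    return "unfavorable"


def classify_lifestyle(
    profile: LifestyleProfile,
    pa_median: float,
    *,
    pa_median_unfavorable_at_equality: bool = False,
) -> LifestyleClassification:
    """Flag each lifestyle factor and categorise the participant.

    Parameters
    ----------
    profile
        Complete lifestyle measurements; missing fields are rejected at
        construction, never imputed.
    pa_median
        Median total physical activity (MET-hours/day) of the matching
        sex- and age-specific stratum.
    pa_median_unfavorable_at_equality
        The unfavourable physical-activity group is the *lower half* of
        the stratum; by default activity exactly equal to the median is
        favourable (strict ``<``).  Set True to flag equality as
        unfavourable instead.

    Unfavourable definitions: current smoking or having quit because of
    illness; any of (no daily fruit, no daily vegetables, red meat daily
    or less than weekly); physical activity below the stratum median;
    sleeping < 7 or > 9 h/day; BMI < 18.5 or >= 24.0 kg/m^2; waist
    circumference >= 90 cm (men) / >= 85 cm (women).
    """
    if pa_median <= 0 or math.isnan(pa_median):
        raise ValueError("pa_median must be positive")

    smoking = profile.smoking_status in (
        SmokingStatus.CURRENT,
        SmokingStatus.FORMER_BY_ILLNESS,
    )
    diet = (
        not profile.eats_fruit_daily
        or not profile.eats_veg_daily
        or profile.red_meat_freq in (RedMeatFreq.DAILY, RedMeatFreq.LESS_THAN_WEEKLY)
    )
    if pa_median_unfavorable_at_equality:
        physical_activity = profile.total_physical_activity <= pa_median
    else:
        physical_activity = profile.total_physical_activity < pa_median
    sleep = profile.sleep_hours < 7 or profile.sleep_hours > 9
    bmi = profile.bmi < 18.5 or profile.bmi >= 24.0
    waist_cut = 90.0 if profile.sex is Sex.MALE else 85.0
    waist = profile.waist_circumference >= waist_cut

    flags = (smoking, diet, physical_activity, sleep, bmi, waist)
    n = int(sum(flags))
    return LifestyleClassification(
        smoking=smoking,
        diet=diet,
        physical_activity=physical_activity,
        sleep=sleep,
        bmi=bmi,
        waist=waist,
        n_unfavorable=n,
        category=lifestyle_category_from_count(n),
    )


def categorize_prs(
    scores, scheme: Literal["quintile", "tertile"] = "quintile"
) -> np.ndarray:
    """Stratify scores into genetic-risk categories by rank.

    Quintile scheme: bottom fifth is ``low``, top fifth ``high``, the
    middle three fifths ``intermediate``; tertile scheme splits in
    thirds with the same labels.  Ranks come from a stable sort, so ties
    are broken by input order and the group sizes are exact up to the
    ceiling rounding of the cut ranks (``ceil(k*n/5)``).  Because only
    ranks are used, any strictly monotone transform of the scores leaves
    the assignment unchanged.

    Returns an object array of labels aligned with the input.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D array")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    n = scores.size
    if np.unique(scores).size < 5:
        raise ValueError("need at least 5 distinct score values")

    order = np.argsort(scores, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)  # 1-based rank, ties by input order

    if scheme == "quintile":
        lo_cut = math.ceil(n / 5)
        hi_cut = math.ceil(4 * n / 5)
    elif scheme == "tertile":
        lo_cut = math.ceil(n / 3)
        hi_cut = math.ceil(2 * n / 3)
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")

    out = np.where(
        rank <= lo_cut, "low", np.where(rank <= hi_cut, "intermediate", "high")
    )
    return out.astype(object)
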