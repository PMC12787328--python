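"""Fried frailty phenotype criterion scoring.

Each of the five criteria is a binary flag (1 = criterion met) derived
from either standard clinical instruments or their sensor counterparts:

* weight loss — self-reported unintentional loss (> 4.5 kg or > 5% of
  body weight over the past year), asked directly or via smart speaker;
* exhaustion — CES-D items 7/8 frequency codes (standard) or a
  days-per-week category from a spoken dialogue (sensor);
* low activity — weekly kcal below sex cutoffs (standard, see
  :mod:`frailsense.champs`) or total timed-task duration above the
  cohort's 80th percentile (sensor);
* weakness — maximum grip force at or below a sex- and BMI-band cutoff;
* slowness — 15-ft walk time at or above a sex- and height-stratified
  threshold.

The total score 0-5 maps to robust (0), pre-frail (1-2), frail (3-4)
and very frail (5); the dichotomy groups 0-2 as not frail, 3-5 as frail.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidConfigError
from .models import CriterionFlags, FrailtyResult

# Sex- and BMI-band grip-strength cutoffs (kg): grip at or below the
# cutoff meets the weakness criterion. Bands are half-open so every BMI
# maps to exactly one cutoff: <=24, (24,26], (26,28], >28.
GRIP_CUTOFF_KG = {
    "male": ((24.0, 29.0), (26.0, 30.0), (28.0, 31.0), (math.inf, 32.0)),
    "female": ((24.0, 17.0), (26.0, 17.3), (28.0, 18.0), (math.inf, 21.0)),
}

# Height (cm) above which the faster 6 s slowness threshold applies;
# at or below it, 7 s.
SLOWNESS_HEIGHT_CM = {"male": 173.0, "female": 159.0}
SLOWNESS_THRESHOLD_S = {"tall": 6.0, "short": 7.0}


def weight_loss_flag(
    answer: Optional[str] = None,
    lost_kg: Optional[float] = None,
    pct_lost: Optional[float] = None,
) -> int:
    """1 iff unintentional weight loss is reported or measured.

    Any one of: an affirmative answer, a loss strictly greater than
    4.5 kg, or strictly greater than 5% of body weight.
    """
    if answer is not None and answer not in ("yes", "no"):
        raise InvalidConfigError(f"answer must be 'yes'/'no', got {answer!r}")
    if answer == "yes":
        return 1
    if lost_kg is not None and lost_kg > 4.5:
        return 1
    if pct_lost is not None and pct_lost > 5.0:
        return 1
    return 0


def exhaustion_flag_standard(item7: int, item8: int) -> int:
    """1 iff either CES-D item 7 or 8 is answered 2 (a moderate amount
    of the time) or 3 (most of the time)."""
    for v in (item7, item8):
        if v not in (0, 1, 2, 3):
            raise InvalidConfigError(f"CES-D item code {v!r} not in 0..3")
    return int(max(item7, item8) >= 2)


def exhaustion_flag_sensor(days_category: str) -> int:
    """Spoken-dialogue route: '3-7' days of exhaustion per week -> 1,
    '0-2' -> 0."""
    if days_category == "3-7":
        return 1
    if days_category == "0-2":
        return 0
    raise InvalidConfigError(f"unknown days category {days_category!r}")


def grip_cutoff(sex: str, bmi: float) -> float:
    """Weakness cutoff (kg) for a sex and BMI."""
    try:
        bands = GRIP_CUTOFF_KG[sex]
    except KeyError:
        raise InvalidConfigError(f"unknown sex {sex!r}") from None
    if bmi <= 0:
        raise InvalidConfigError("BMI must be positive")
    for upper, cutoff in bands:
        if bmi <= upper:
            return cutoff
    raise AssertionError("unreachable: last band is unbounded")


def weakness_flag(grip_max_kg: Optional[float], sex: str, bmi: float) -> Optional[int]:
    """1 iff maximum grip force is at or below the sex/BMI cutoff;
    None when the grip measurement is missing."""
    if grip_max_kg is None:
        return None
    if grip_max_kg <= 0:
        raise InvalidConfigError("grip force must be positive")
    return int(grip_max_kg <= grip_cutoff(sex, bmi))


def slowness_threshold(sex: str, height_cm: float) -> float:
    """15-ft walk-time threshold (s) for a sex/height stratum."""
    try:
        h = SLOWNESS_HEIGHT_CM[sex]
    except KeyError:
        raise InvalidConfigError(f"unknown sex {sex!r}") from None
    return SLOWNESS_THRESHOLD_S["tall" if height_cm > h else "short"]


def slowness_flag(walk_time_s: float, sex: str, height_cm: float) -> int:
    """1 iff the 15-ft walk time meets or exceeds the stratum threshold."""
    if walk_time_s <= 0:
        raise InvalidConfigError("walk time must be positive")
    return int(walk_time_s >= slowness_threshold(sex, height_cm))


def percentile_threshold(values: Sequence[float], q: float = 0.80) -> float:
    """Linear-interpolation percentile of the values (default 80th),
    used as the cohort-relative task-duration threshold."""
    if len(values) < 5:
        raise InsufficientDataError("need >= 5 values for a percentile threshold")
    if not 0 <= q <= 1:
        raise InvalidConfigError("q must lie in [0, 1]")
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


def low_activity_flag_sensor(duration_total_s: float, threshold_s: float) -> int:
    """1 iff the total timed-task duration strictly exceeds the cohort
    threshold (ties are not frail)."""
    return int(duration_total_s > threshold_s)


def total_and_categorize(flags: CriterionFlags) -> FrailtyResult:
    """Compose total score, three-level category and dichotomous class.

    With any missing criterion the result is marked incomplete: the
    total is the partial sum of observed flags and the category and
    dichotomy are None.
    """
    if not flags.complete:
        return FrailtyResult(total=flags.partial_total, category=None,
                             dichotomous=None, complete=False)
    total = flags.partial_total
    if total == 0:
        category = "robust"
    elif total <= 2:
        category = "pre_frail"
    elif total <= 4:
        category = "frail"
    else:
        category = "very_frail"
    dichotomous = "not_frail" if total <= 2 else "frail"
    return FrailtyResult(total=total, category=category,
                         dichotomous=dichotomous, complete=True)
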