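"""Physical competence domain: shuttle run, plank and agility-course scoring.

The domain score (0-30) sums three 10-point protocol scores; if exactly one
protocol is missing the remaining two are rescaled from /20 to /30.
"""

from __future__ import annotations

import math
from typing import Any

from ._missing import coerce_int, coerce_number, is_missing
from .config import ScoringConfig
from .weighting import reweighted_sum

__all__ = [
    "convert_pacer_laps",
    "score_pacer",
    "score_plank",
    "score_camsa_time",
    "score_camsa_trial",
    "score_camsa",
    "score_pc",
]


def convert_pacer_laps(lap_distance: Any, laps_run: Any, config: ScoringConfig) -> int | None:
    """Convert shuttle-run laps to their 20-metre equivalent.

    20-metre laps are returned unchanged when inside the valid range;
    15-metre laps go through the configured conversion table first.  Any
    other distance, a fractional lap count, or an out-of-range result is
    missing.
    """
    distance = coerce_number(lap_distance)
    laps = coerce_int(laps_run)
    if distance is None or laps is None:
        return None
    low, high = config.pacer_valid_range
    if distance == 20:
        return laps if low <= laps <= high else None
    if distance == 15:
        converted = config.pacer_conversion.get(laps)
        if converted is None:
            return None
        return converted if low <= converted <= high else None
    return None


def score_pacer(laps_20m: Any, config: ScoringConfig) -> int | None:
    """Score 20-metre laps on 0-10: one point per 5 laps, capped at 10."""
    laps = coerce_int(laps_20m)
    if laps is None or laps < 0:
        return None
    return min(laps // config.pacer_laps_per_point, config.pacer_max_score)


def score_plank(plank_time: Any, config: ScoringConfig) -> int | None:
    """Score a plank hold (seconds) on 0-10 via the configured rule."""
    seconds = coerce_number(plank_time)
    if seconds is None or seconds < 0:
        return None
    return min(int(seconds // config.plank_seconds_per_point), config.plank_max_score)


def score_camsa_time(trial_time: Any, config: ScoringConfig) -> int | None:
    """Score an agility-course trial time (seconds) on 1-14.

    Faster times earn more points via right-closed bins; times slower than
    the last bin edge earn the floor score.  Non-positive or non-numeric
    times are missing.
    """
    seconds = coerce_number(trial_time)
    if seconds is None or seconds <= 0:
        return None
    for upper, score in config.camsa_time_bins:
        if seconds <= upper:
            return score
    return config.camsa_slowest_score


def score_camsa_trial(skill: Any, trial_time: Any, config: ScoringConfig) -> int | None:
    """Combine a trial's skill checklist (0-14) and time score into 1-28."""
    skill_value = coerce_int(skill)
    low, high = config.camsa_skill_range
    if skill_value is None or not (low <= skill_value <= high):
        return None
    time_score = score_camsa_time(trial_time, config)
    if time_score is None:
        return None
    return skill_value + time_score


def score_camsa(skill_time1: Any, skill_time2: Any, config: ScoringConfig) -> float | None:
    """Score the better of two trials out of 10 (max skill+time / 2.8).

    Both trials must be valid; a single missing trial makes the result
    missing rather than silently scoring one attempt.
    """
    first = coerce_number(skill_time1)
    second = coerce_number(skill_time2)
    if first is None or second is None:
        return None
    if not (1 <= first <= 28 and 1 <= second <= 28):
        return None
    return max(first, second) / config.camsa_divisor


def score_pc(pacer_score: Any, plank_score: Any, camsa_score: Any) -> float | None:
    """Aggregate the three protocol scores into the 0-30 domain score."""
    values = [_clip_component(v) for v in (pacer_score, plank_score, camsa_score)]
    return reweighted_sum(values, maxima=(10, 10, 10), total=30)


def _clip_component(value: Any) -> float | None:
    number = coerce_number(value)
    if number is None or math.isnan(number) or not (0 <= number <= 10):
        return None
    return number
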