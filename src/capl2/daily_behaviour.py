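"""Daily behaviour domain: pedometer wear time, step averaging and scoring.

The domain score (0-30) is the step score (/25) plus the self-reported
activity score (/5).  Unlike the other domains there is no reweighting: if
either part is missing the domain score is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._missing import coerce_int, coerce_number, is_missing
from .config import ScoringConfig
from .validators import to_24_hour, validate_scale

__all__ = [
    "StepWeek",
    "wear_time",
    "validate_steps",
    "step_average",
    "score_steps",
    "score_self_report",
    "score_db",
]


@dataclass
class StepWeek:
    """One child's validated pedometer week."""

    steps_valid: list[int | None] = field(default_factory=lambda: [None] * 7)
    wear_hours: list[float | None] = field(default_factory=lambda: [None] * 7)
    valid_days: int = 0
    step_average: float | None = None
    imputed_day_source: int | None = None  # 0-based index into valid days


def wear_time(time_on: Any, time_off: Any, non_wear: Any) -> float | None:
    """Pedometer wear time in decimal hours for one day.

    ``(off - on) - non_wear/60``; a missing non-wear entry counts as zero
    minutes.  Missing clock times, off at/before on, or a negative result
    are all missing.
    """
    on_hours = to_24_hour(time_on)
    off_hours = to_24_hour(time_off)
    if on_hours is None or off_hours is None or off_hours <= on_hours:
        return None
    non_wear_minutes = coerce_number(non_wear)
    if non_wear_minutes is None:
        non_wear_minutes = 0.0
    hours = (off_hours - on_hours) - non_wear_minutes / 60
    return hours if hours >= 0 else None


def validate_steps(steps: Any, wear_hours: Any, config: ScoringConfig) -> int | None:
    """Accept a daily step count only if plausible and worn long enough."""
    count = coerce_int(steps)
    hours = coerce_number(wear_hours)
    if count is None or hours is None:
        return None
    low, high = config.step_bounds
    if not (low <= count <= high) or hours < config.min_wear_hours:
        return None
    return count


def step_average(
    week: dict[str, Any],
    config: ScoringConfig,
    rng: np.random.Generator,
) -> StepWeek:
    """Validate a pedometer week and compute the daily step average.

    ``week`` maps the raw column names (``steps1``.. ``non_wear_time7``) to
    values.  At least four valid days are required for a mean; with exactly
    three, one valid-day value is sampled (seeded, via ``rng``) as a stand-in
    fourth day.  Two or fewer valid days leave the average missing.
    """
    result = StepWeek()
    for day in range(1, 8):
        hours = wear_time(
            week.get(f"time_on{day}"),
            week.get(f"time_off{day}"),
            week.get(f"non_wear_time{day}"),
        )
        result.wear_hours[day - 1] = hours
        result.steps_valid[day - 1] = validate_steps(week.get(f"steps{day}"), hours, config)

    valid_values = [v for v in result.steps_valid if v is not None]
    result.valid_days = len(valid_values)
    if result.valid_days >= 4:
        result.step_average = float(np.mean(valid_values))
    elif result.valid_days == 3:
        pick = int(rng.integers(0, 3))
        result.imputed_day_source = pick
        result.step_average = float(np.mean(valid_values + [valid_values[pick]]))
    return result


def score_steps(average: Any, config: ScoringConfig) -> int | None:
    """Score a step average on 0-25 via the configured bin table."""
    value = coerce_number(average)
    if value is None or value < 0:
        return None
    score = 0
    for edge in config.step_score_lower_edges:
        if value >= edge:
            score += 1
        else:
            break
    return score


def score_self_report(days: Any, config: ScoringConfig) -> int | None:
    """Score self-reported active days (0-7) on 0-5."""
    response = validate_scale(days, 0, 7)
    if response is None:
        return None
    return config.self_report_map[response]


def score_db(step_score: Any, self_report_score: Any) -> int | None:
    """Daily behaviour domain score: step + self-report, no reweighting."""
    if is_missing(step_score) or is_missing(self_report_score):
        return None
    step = coerce_number(step_score)
    self_report = coerce_number(self_report_score)
    if step is None or self_report is None:
        return None
    if not (0 <= step <= 25 and 0 <= self_report <= 5):
        return None
    total = step + self_report
    return int(total) if total.is_integer() else total
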