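"""Questionnaire domains: motivation & confidence, knowledge & understanding.

Motivation & confidence (0-30) sums four 7.5-point subscales — two from the
self-perception questionnaire (predilection, adequacy) and two from the
exercise-regulation questionnaire (intrinsic motivation, activity
competence) — rescaling when exactly one subscale is missing.

Knowledge & understanding (0-10) sums four 1-point multiple-choice items and
a 6-point fill-in-the-blanks story, likewise reweighted for one missing
component.
"""

from __future__ import annotations

from typing import Any

from ._missing import coerce_int, coerce_number, is_missing
from .config import ScoringConfig
from .validators import validate_scale
from .weighting import reweighted_sum

__all__ = [
    "score_csappa_subscale",
    "score_breq_subscale",
    "score_mc",
    "score_binary_item",
    "score_fill_blanks",
    "score_ku",
]

#: Item triples backing the two self-perception subscales.
CSAPPA_SUBSCALES: dict[str, tuple[str, str, str]] = {
    "predilection": ("csappa1", "csappa3", "csappa5"),
    "adequacy": ("csappa2", "csappa4", "csappa6"),
}


def _csappa_item_points(item: str, response: Any, config: ScoringConfig) -> float | None:
    value = validate_scale(response, 1, 4)
    if value is None:
        return None
    if config.csappa_orientation.get(item, "normal") == "reversed":
        value = 5 - value
    return config.csappa_points[value]


def score_csappa_subscale(
    item_a: Any,
    item_b: Any,
    item_c: Any,
    which: str,
    config: ScoringConfig,
) -> float | None:
    """Score a three-item self-perception subscale (1.8-7.5).

    ``which`` selects the item maps ("predilection" uses items 1/3/5,
    "adequacy" items 2/4/6) and their per-item orientations.  Any invalid or
    missing response makes the subscale missing.
    """
    try:
        items = CSAPPA_SUBSCALES[which]
    except KeyError:
        raise ValueError(f"unknown subscale {which!r}; expected one of {sorted(CSAPPA_SUBSCALES)}")
    total = 0.0
    for item, response in zip(items, (item_a, item_b, item_c)):
        points = _csappa_item_points(item, response, config)
        if points is None:
            return None
        total += points
    return total


def score_breq_subscale(item1: Any, item2: Any, item3: Any, config: ScoringConfig) -> float | None:
    """Score a three-item exercise-regulation subscale (1.5-7.5)."""
    total = 0.0
    for response in (item1, item2, item3):
        value = validate_scale(response, 1, 5)
        if value is None:
            return None
        total += config.breq_points[value]
    return total


def score_mc(
    predilection: Any,
    adequacy: Any,
    intrinsic: Any,
    pa_competence: Any,
) -> float | None:
    """Motivation & confidence domain score (0-30) with reweighting."""
    values = [_subscale_value(v) for v in (predilection, adequacy, intrinsic, pa_competence)]
    return reweighted_sum(values, maxima=(7.5, 7.5, 7.5, 7.5), total=30)


def _subscale_value(value: Any) -> float | None:
    number = coerce_number(value)
    if number is None or not (0 <= number <= 7.5):
        return None
    return number


def _matches(response: Any, code: int, strings: list[str], case_sensitive: bool) -> bool:
    as_int = coerce_int(response)
    if as_int is not None:
        return as_int == code
    text = str(response).strip()
    if case_sensitive:
        return any(text == accepted for accepted in strings)
    return any(text.lower() == accepted.lower() for accepted in strings)


def score_binary_item(response: Any, item: str, config: ScoringConfig) -> int | None:
    """Score a multiple-choice knowledge item: 1 correct, 0 incorrect.

    The answer key accepts either the item's integer response code or the
    verbatim answer text.  Empty or absent responses are missing; any other
    non-matching response scores 0.
    """
    key = config.answer_keys[item]
    if is_missing(response) or (isinstance(response, str) and not response.strip()):
        return None
    matched = _matches(response, key["code"], key["strings"], config.case_sensitive_answers)
    return 1 if matched else 0


def score_fill_blanks(
    pa_is: Any,
    pa_is_also: Any,
    improve: Any,
    increase: Any,
    when_cooling_down: Any,
    heart_rate: Any,
    config: ScoringConfig,
) -> int:
    """Count correct story blanks (0-6); blank answers simply score 0."""
    responses = {
        "pa_is": pa_is,
        "pa_is_also": pa_is_also,
        "improve": improve,
        "increase": increase,
        "when_cooling_down": when_cooling_down,
        "heart_rate": heart_rate,
    }
    case_sensitive = config.case_sensitive_answers
    score = 0
    for blank, response in responses.items():
        if is_missing(response):
            continue
        accepted = config.fill_blank_keys[blank]
        text = str(response).strip()
        if case_sensitive:
            correct = text in accepted
        else:
            correct = text.lower() in (a.lower() for a in accepted)
        if correct:
            score += 1
    return score


def score_ku(q1: Any, q2: Any, q3: Any, q4: Any, fill: Any) -> float | None:
    """Knowledge & understanding domain score (0-10) with reweighting."""
    binaries = []
    for value in (q1, q2, q3, q4):
        number = coerce_number(value)
        binaries.append(number if number in (0.0, 1.0) else None)
    fill_value = coerce_number(fill)
    if fill_value is not None and not (0 <= fill_value <= 6):
        fill_value = None
    return reweighted_sum([*binaries, fill_value], maxima=(1, 1, 1, 1, 6), total=10)
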