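"""Quiet validators.

Every function here is total: any scalar input yields either a clean value or
``None`` (the missing marker), never an exception.  This keeps batch scoring
running in the presence of messy spreadsheet data; invalid cells simply
propagate as missing through downstream scores.
"""

from __future__ import annotations

import datetime
import math
import re
from typing import Any

from ._missing import coerce_int, coerce_number, is_missing

__all__ = ["validate_age", "validate_gender", "validate_scale", "to_24_hour"]

_GIRL_TOKENS = frozenset({"girl", "g", "female", "f", "1"})
_BOY_TOKENS = frozenset({"boy", "b", "male", "m", "0"})

_CLOCK_12H = re.compile(r"^(\d{1,2}):(\d{2})\s*([ap])\.?m\.?$", re.IGNORECASE)
_CLOCK_24H = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")


def validate_age(value: Any) -> int | None:
    """Validate an age in years; valid ages are 8-12 inclusive.

    Numeric strings are coerced first; fractional ages inside the valid range
    are floored (age-specific lookups run on integer years).  Everything else
    is missing.
    """
    number = coerce_number(value)
    if number is None or not (8 <= number <= 12):
        return None
    return int(math.floor(number))


def validate_gender(value: Any) -> str | None:
    """Normalise a free-text or coded gender to "girl"/"boy", else missing.

    Accepts case-insensitive synonyms ("Girl", "G", "female", "F", 1 and
    "boy", "B", "male", "M", 0), in string or numeric form.
    """
    if is_missing(value) or isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        if float(value).is_integer():
            token = str(int(value))
        else:
            return None
    else:
        token = str(value).strip().lower()
    if token in _GIRL_TOKENS:
        return "girl"
    if token in _BOY_TOKENS:
        return "boy"
    return None


def validate_scale(value: Any, lowest: int, highest: int) -> int | None:
    """Return an integer response within [lowest, highest], else missing."""
    if lowest > highest:
        raise ValueError(f"lowest ({lowest}) must not exceed highest ({highest})")
    response = coerce_int(value)
    if response is None or not (lowest <= response <= highest):
        return None
    return response


def to_24_hour(value: Any) -> float | None:
    """Parse a clock value to decimal hours since midnight in [0, 24).

    Two string dialects are accepted: 12-hour "H:MM am/pm" (case-insensitive,
    optional space before the meridiem) and 24-hour "HH:MM[:SS]".  ``datetime``
    time objects (as produced by spreadsheet imports) are converted directly.
    Anything else is missing.
    """
    if is_missing(value):
        return None
    if isinstance(value, datetime.datetime):
        value = value.time()
    if isinstance(value, datetime.time):
        return value.hour + value.minute / 60 + value.second / 3600
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        # already decimal hours (idempotence for re-validated columns)
        return float(value) if 0 <= float(value) < 24 else None
    if not isinstance(value, str):
        return None
    text = value.strip()

    match = _CLOCK_12H.match(text)
    if match:
        hour, minute = int(match.group(1)), int(match.group(2))
        meridiem = match.group(3).lower()
        if not (1 <= hour <= 12 and 0 <= minute <= 59):
            return None
        hour = hour % 12
        if meridiem == "p":
            hour += 12
        return hour + minute / 60

    match = _CLOCK_24H.match(text)
    if match:
        hour, minute = int(match.group(1)), int(match.group(2))
        second = int(match.group(3) or 0)
        if not (0 <= hour <= 23 and 0 <= minute <= 59 and 0 <= second <= 59):
            return None
        return hour + minute / 60 + second / 3600

    return None
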