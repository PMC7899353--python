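"""Missing-value conventions shared across the package.

Scalar scoring functions signal "missing or invalid" by returning ``None``.
Inside :mod:`pandas` tables the same states appear as ``None``/``NaN``/``NA``;
``is_missing`` recognises all of them.
"""

from __future__ import annotations

import math
from typing import Any

__all__ = ["is_missing", "coerce_number", "coerce_int"]


def is_missing(value: Any) -> bool:
    """Return True for None, NaN and pandas-style NA markers."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    # pandas.NA / numpy scalar NaN without importing pandas here
    try:
        if value != value:  # noqa: PLR0124 - NaN self-inequality
            return True
    except Exception:
        pass
    return False


def coerce_number(value: Any) -> float | None:
    """Coerce a scalar (including numeric strings) to float, else None.

    Booleans are rejected: True/False are never valid measurements.
    """
    if is_missing(value) or isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        text = value.strip()
        if not text:
            return None
        try:
            return float(text)
        except ValueError:
            return None
    # numpy scalars and similar
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def coerce_int(value: Any) -> int | None:
    """Coerce to int when the value is integral (3, 3.0, "3"), else None."""
    number = coerce_number(value)
    if number is None or not number.is_integer():
        return None
    return int(number)
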