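"""Missing-component reweighting shared by the domain and overall scores."""

from __future__ import annotations

from typing import Sequence

from ._missing import is_missing

__all__ = ["reweighted_sum"]


def reweighted_sum(
    values: Sequence[float | None],
    maxima: Sequence[float],
    total: float,
) -> float | None:
    """Sum components, rescaling when exactly one is missing.

    With all components present the plain sum is returned.  With exactly one
    missing, the available sum is rescaled by ``total / (total - missing
    component's maximum)`` so the result stays on the 0..total scale.  Two or
    more missing components make the result missing.
    """
    if len(values) != len(maxima):
        raise ValueError("values and maxima must have equal length")
    available = 0.0
    missing_max = 0.0
    n_missing = 0
    for value, maximum in zip(values, maxima):
        if is_missing(value):
            n_missing += 1
            missing_max = maximum
        else:
            available += float(value)
    if n_missing == 0:
        return available
    if n_missing == 1:
        return available * total / (total - missing_max)
    return None
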