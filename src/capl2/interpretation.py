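"""Overall score, normative interpretation and domain completeness status."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from ._missing import coerce_number, is_missing
from .model import CATEGORIES, DOMAIN_COMPONENTS
from .validators import validate_age, validate_gender
from .weighting import reweighted_sum

__all__ = ["NormTable", "load_norms", "score_capl", "interpret", "domain_status"]

_PACKAGED_NORMS = "norms.csv"
_NORM_COLUMNS = ["protocol", "gender", "age", "category", "lower", "upper"]


class NormTable:
    """Age- and gender-specific category thresholds per protocol.

    Rows carry ``(protocol, gender, age, category, lower, upper)`` with
    half-open ``[lower, upper)`` intervals; the top category is closed at the
    protocol maximum.  For each (protocol, gender, age) the four category
    intervals must partition the score range without gaps or overlaps.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(_NORM_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"norms table is missing columns: {sorted(missing)}")
        self._table = table.loc[:, _NORM_COLUMNS].copy()
        self._index: dict[tuple[str, str, int], list[tuple[float, float, str]]] = {}
        self._validate_and_index()
        self._protocols = frozenset(self._table["protocol"].unique())

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "NormTable":
        source = resources.files("capl2").joinpath("data", _PACKAGED_NORMS)
        with source.open("r", encoding="utf-8") as handle:
            return cls(pd.read_csv(handle))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index=False)

    @property
    def protocols(self) -> frozenset[str]:
        return self._protocols

    def as_frame(self) -> pd.DataFrame:
        return self._table.copy()

    # -- internals ---------------------------------------------------------

    def _validate_and_index(self) -> None:
        for (protocol, gender, age), group in self._table.groupby(
            ["protocol", "gender", "age"], sort=False
        ):
            rows = sorted(
                zip(group["lower"], group["upper"], group["category"]),
                key=lambda row: row[0],
            )
            categories = [row[2] for row in rows]
            if categories != list(CATEGORIES):
                raise ValueError(
                    f"norms for {protocol}/{gender}/{age}: categories {categories} "
                    f"must be exactly {list(CATEGORIES)} ordered by interval"
                )
            for (_, upper_a, cat_a), (lower_b, _, cat_b) in zip(rows, rows[1:]):
                if lower_b != upper_a:
                    kind = "overlap" if lower_b < upper_a else "gap"
                    raise ValueError(
                        f"norms for {protocol}/{gender}/{age}: {kind} between "
                        f"{cat_a!r} and {cat_b!r}"
                    )
            self._index[(str(protocol), str(gender), int(age))] = rows

    def lookup(self, protocol: str, gender: str, age: int, score: float) -> str | None:
        """Category containing ``score``; None when outside the table range."""
        rows = self._index.get((protocol, gender, age))
        if rows is None:
            return None
        top_upper = rows[-1][1]
        for lower, upper, category in rows:
            if lower <= score < upper:
                return category
            if upper == top_upper and score == upper:
                return category  # protocol maximum is inclusive
        return None


def load_norms(path: str | Path | None = None) -> NormTable:
    """Load a norms CSV, or the packaged provisional defaults when None."""
    if path is None:
        return NormTable.default()
    return NormTable.from_csv(path)


def score_capl(pc: Any, db: Any, mc: Any, ku: Any) -> float | None:
    """Overall physical-literacy score (0-100) with one-missing reweighting."""
    maxima = (30.0, 30.0, 30.0, 10.0)
    values = []
    for value, maximum in zip((pc, db, mc, ku), maxima):
        number = coerce_number(value)
        if number is not None and not (0 <= number <= maximum):
            number = None
        values.append(number)
    return reweighted_sum(values, maxima=maxima, total=100)


def interpret(
    age: Any,
    gender: Any,
    score: Any,
    protocol: str,
    norms: NormTable,
) -> str | None:
    """Age/gender-specific interpretive category for a protocol score.

    Age and gender go through the quiet validators first; a missing or
    invalid age, gender or score yields missing.  An unknown protocol name is
    a programming error and raises.
    """
    if protocol not in norms.protocols:
        raise KeyError(f"unknown protocol {protocol!r}; norms define {sorted(norms.protocols)}")
    valid_age = validate_age(age)
    valid_gender = validate_gender(gender)
    value = coerce_number(score)
    if valid_age is None or valid_gender is None or value is None:
        return None
    return norms.lookup(protocol, valid_gender, valid_age, value)


def domain_status(record: Mapping[str, Any], domain: str) -> str:
    """Completeness status of a scored domain.

    Precedence: a missing domain score is "incomplete"; otherwise a missing
    interpretation is "missing interpretation"; otherwise any missing
    component is "missing protocol"; otherwise "complete".
    """
    try:
        wiring = DOMAIN_COMPONENTS[domain]
    except KeyError:
        raise KeyError(f"unknown domain {domain!r}; expected one of {sorted(DOMAIN_COMPONENTS)}")
    if is_missing(record.get(wiring["score"])):
        return "incomplete"
    if is_missing(record.get(wiring["interpretation"])):
        return "missing interpretation"
    if any(is_missing(record.get(component)) for component in wiring["components"]):
        return "missing protocol"
    return "complete"
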