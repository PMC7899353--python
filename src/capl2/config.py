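"""Externalized scoring tables.

Every cut-point, bin table, answer key and validity bound that the assessment
manual defines — rather than the scoring formulas themselves — lives in a
human-readable YAML file so that users holding the manual can correct the
packaged defaults without touching code.  Several defaults are provisional
reconstructions and are marked as such in the packaged file.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ScoringConfig", "load_config"]

_PACKAGED_CONFIG = "default_config.yaml"


class ConfigError(ValueError):
    """Raised when a scoring configuration file is structurally invalid."""


class ScoringConfig:
    """Validated, read-only view over the scoring-table configuration.

    Parameters
    ----------
    data:
        Parsed configuration mapping (see the packaged
        ``capl2/data/default_config.yaml`` for the documented schema).
    """

    def __init__(self, data: dict[str, Any]):
        self._data = copy.deepcopy(data)
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "ScoringConfig":
        """Load the packaged default configuration."""
        source = resources.files("capl2").joinpath("data", _PACKAGED_CONFIG)
        return cls(yaml.safe_load(source.read_text(encoding="utf-8")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls(yaml.safe_load(handle))

    def to_yaml(self, path: str | Path) -> None:
        """Write the configuration back out; round-trips losslessly."""
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self._data, handle, sort_keys=False)

    def as_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._data)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        required = {"pacer", "plank", "camsa", "steps", "self_report", "csappa", "breq", "knowledge"}
        missing = required - set(self._data)
        if missing:
            raise ConfigError(f"config is missing sections: {sorted(missing)}")

        conversion = self.pacer_conversion
        laps = sorted(conversion)
        if laps != list(range(laps[0], laps[-1] + 1)):
            raise ConfigError("pacer 15m->20m conversion table has gaps")
        values = [conversion[lap] for lap in laps]
        if any(b < a for a, b in zip(values, values[1:])):
            raise ConfigError("pacer 15m->20m conversion table is not monotone")

        bins = self.camsa_time_bins
        uppers = [edge for edge, _ in bins]
        scores = [score for _, score in bins]
        if uppers != sorted(uppers) or scores != sorted(scores, reverse=True):
            raise ConfigError("camsa time bins must be increasing in time, decreasing in score")

        edges = self.step_score_lower_edges
        if list(edges) != sorted(edges):
            raise ConfigError("step score lower edges must be non-decreasing")

        mapping = self.self_report_map
        if sorted(mapping) != list(range(0, 8)):
            raise ConfigError("self-report map must cover responses 0-7")
        ordered = [mapping[k] for k in sorted(mapping)]
        if ordered != sorted(ordered):
            raise ConfigError("self-report map must be monotone")

        if sorted(self.csappa_points) != [1, 2, 3, 4]:
            raise ConfigError("csappa point map must cover responses 1-4")
        if sorted(self.breq_points) != [1, 2, 3, 4, 5]:
            raise ConfigError("breq point map must cover responses 1-5")
        for item, orientation in self.csappa_orientation.items():
            if orientation not in ("normal", "reversed"):
                raise ConfigError(f"unknown orientation {orientation!r} for {item}")

    # -- PACER -------------------------------------------------------------

    @property
    def pacer_conversion(self) -> dict[int, int]:
        return self._data["pacer"]["conversion_15m_to_20m"]

    @property
    def pacer_laps_per_point(self) -> int:
        return self._data["pacer"]["laps_per_point"]

    @property
    def pacer_max_score(self) -> int:
        return self._data["pacer"]["max_score"]

    @property
    def pacer_valid_range(self) -> tuple[int, int]:
        low, high = self._data["pacer"]["valid_lap_range"]
        return int(low), int(high)

    # -- plank -------------------------------------------------------------

    @property
    def plank_seconds_per_point(self) -> float:
        return self._data["plank"]["seconds_per_point"]

    @property
    def plank_max_score(self) -> int:
        return self._data["plank"]["max_score"]

    # -- CAMSA -------------------------------------------------------------

    @property
    def camsa_time_bins(self) -> list[tuple[float, int]]:
        """(upper edge in seconds, score) pairs; right-closed intervals."""
        return [(entry["max_seconds"], entry["score"]) for entry in self._data["camsa"]["time_bins"]]

    @property
    def camsa_skill_range(self) -> tuple[int, int]:
        low, high = self._data["camsa"]["skill_range"]
        return int(low), int(high)

    @property
    def camsa_slowest_score(self) -> int:
        return self._data["camsa"]["slowest_score"]

    @property
    def camsa_divisor(self) -> float:
        return self._data["camsa"]["divisor"]

    # -- pedometry ---------------------------------------------------------

    @property
    def step_bounds(self) -> tuple[int, int]:
        section = self._data["steps"]
        return int(section["min_daily"]), int(section["max_daily"])

    @property
    def min_wear_hours(self) -> float:
        return float(self._data["steps"]["min_wear_hours"])

    @property
    def step_score_lower_edges(self) -> list[float]:
        """Lower edge of the step average earning score i+1 (index i)."""
        return list(self._data["steps"]["score_lower_edges"])

    @property
    def self_report_map(self) -> dict[int, int]:
        return self._data["self_report"]["map"]

    # -- questionnaires ----------------------------------------------------

    @property
    def csappa_points(self) -> dict[int, float]:
        return self._data["csappa"]["points"]

    @property
    def csappa_orientation(self) -> dict[str, str]:
        return self._data["csappa"]["orientation"]

    @property
    def breq_points(self) -> dict[int, float]:
        return self._data["breq"]["points"]

    @property
    def answer_keys(self) -> dict[str, dict[str, Any]]:
        return self._data["knowledge"]["answer_keys"]

    @property
    def fill_blank_keys(self) -> dict[str, list[str]]:
        return self._data["knowledge"]["fill_blank_keys"]

    @property
    def case_sensitive_answers(self) -> bool:
        return bool(self._data["knowledge"].get("case_sensitive", True))

    # -- interpretation ----------------------------------------------------

    @property
    def interpretation_inputs(self) -> dict[str, str]:
        """Column fed to the normative lookup for each protocol."""
        defaults = {
            "pacer": "pacer_score",
            "steps": "step_average",
            "plank": "plank_time",
            "camsa": "camsa_score",
            "pc": "pc_score",
            "db": "db_score",
            "mc": "mc_score",
            "ku": "ku_score",
            "capl": "capl_score",
        }
        section = self._data.get("interpretation", {}).get("inputs", {})
        return {**defaults, **section}


def load_config(path: str | Path | None = None) -> ScoringConfig:
    """Load a user configuration, or the packaged default when path is None."""
    if path is None:
        return ScoringConfig.default()
    return ScoringConfig.from_yaml(path)
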