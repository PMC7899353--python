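"""Full-table scoring pipeline, column scaffolding and demo-data generation."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._missing import is_missing
from .config import ScoringConfig, load_config
from .daily_behaviour import (
    score_db,
    score_self_report,
    score_steps,
    step_average,
)
from .interpretation import NormTable, domain_status, interpret, load_norms, score_capl
from .model import DERIVED_VARIABLES, DOMAIN_COMPONENTS, RAW_VARIABLES
from .physical_competence import (
    convert_pacer_laps,
    score_camsa,
    score_camsa_time,
    score_camsa_trial,
    score_pacer,
    score_pc,
    score_plank,
)
from .questionnaires import (
    score_binary_item,
    score_breq_subscale,
    score_csappa_subscale,
    score_fill_blanks,
    score_ku,
    score_mc,
)

__all__ = ["scaffold_missing", "rename_variables", "run_all", "generate_demo"]

logger = logging.getLogger(__name__)

SORT_MODES = ("asis", "abc", "zyx")


def scaffold_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Ensure all 60 required raw columns exist, adding missing ones as NA.

    Existing columns are never touched; idempotent on complete tables.
    """
    result = table.copy()
    for name in RAW_VARIABLES:
        if name not in result.columns:
            result[name] = pd.Series([None] * len(result), dtype=object)
    return result


def rename_variables(
    table: pd.DataFrame,
    search: Sequence[str],
    replace: Sequence[str],
) -> pd.DataFrame:
    """Rename columns positionally: search[i] becomes replace[i]."""
    if len(search) != len(replace):
        raise ValueError(
            f"search ({len(search)} names) and replace ({len(replace)} names) "
            "must have equal length"
        )
    unknown = [name for name in search if name not in table.columns]
    if unknown:
        raise KeyError(f"columns not present in table: {unknown}")
    return table.rename(columns=dict(zip(search, replace)))


def run_all(
    table: pd.DataFrame,
    sort: str = "asis",
    seed: int = 1,
    config: ScoringConfig | None = None,
    norms: NormTable | None = None,
) -> pd.DataFrame:
    """Score a raw table: adds the 40 derived columns.

    Raw columns are scaffolded first, so partial tables run with missing
    outputs rather than failing.  ``seed`` drives the step-imputation RNG
    (one generator per run, rows drawn in order).  ``sort`` controls output
    column order: "asis" appends derived columns in computation order,
    "abc"/"zyx" sort all columns (reverse-)alphabetically.
    """
    if sort not in SORT_MODES:
        raise ValueError(f"sort must be one of {SORT_MODES}, got {sort!r}")
    cfg = config if config is not None else load_config()
    norm_table = norms if norms is not None else load_norms()
    rng = np.random.default_rng(seed)

    data = scaffold_missing(table)
    n = len(data)
    raw = {name: list(data[name]) for name in RAW_VARIABLES}
    out: dict[str, list] = {}

    def interp_column(protocol: str) -> list:
        source = cfg.interpretation_inputs[protocol]
        values = out[source] if source in out else raw[source]
        return [
            interpret(raw["age"][i], raw["gender"][i], values[i], protocol, norm_table)
            for i in range(n)
        ]

    def status_column(domain: str) -> list[str]:
        wiring = DOMAIN_COMPONENTS[domain]
        names = [wiring["score"], wiring["interpretation"], *wiring["components"]]
        return [
            domain_status({name: out[name][i] for name in names}, domain)
            for i in range(n)
        ]

    # physical competence
    out["pacer_laps_20m"] = [
        convert_pacer_laps(raw["pacer_lap_distance"][i], raw["pacer_laps"][i], cfg)
        for i in range(n)
    ]
    out["pacer_score"] = [score_pacer(v, cfg) for v in out["pacer_laps_20m"]]
    out["pacer_interpretation"] = interp_column("pacer")
    out["plank_score"] = [score_plank(v, cfg) for v in raw["plank_time"]]
    out["plank_interpretation"] = interp_column("plank")
    for trial in (1, 2):
        out[f"camsa_time_score{trial}"] = [
            score_camsa_time(v, cfg) for v in raw[f"camsa_time{trial}"]
        ]
        out[f"camsa_skill_time_score{trial}"] = [
            score_camsa_trial(raw[f"camsa_skill_score{trial}"][i], raw[f"camsa_time{trial}"][i], cfg)
            for i in range(n)
        ]
    out["camsa_score"] = [
        score_camsa(out["camsa_skill_time_score1"][i], out["camsa_skill_time_score2"][i], cfg)
        for i in range(n)
    ]
    out["camsa_interpretation"] = interp_column("camsa")
    out["pc_score"] = [
        score_pc(out["pacer_score"][i], out["plank_score"][i], out["camsa_score"][i])
        for i in range(n)
    ]
    out["pc_interpretation"] = interp_column("pc")
    out["pc_status"] = status_column("pc")

    # daily behaviour
    pedometer_names = [
        f"{prefix}{day}"
        for day in range(1, 8)
        for prefix in ("steps", "time_on", "time_off", "non_wear_time")
    ]
    weeks = [
        step_average({name: raw[name][i] for name in pedometer_names}, cfg, rng)
        for i in range(n)
    ]
    out["step_average"] = [week.step_average for week in weeks]
    out["valid_days"] = [week.valid_days for week in weeks]
    out["step_score"] = [score_steps(v, cfg) for v in out["step_average"]]
    out["step_interpretation"] = interp_column("steps")
    out["self_report_pa_score"] = [score_self_report(v, cfg) for v in raw["self_report_pa"]]
    out["db_score"] = [
        score_db(out["step_score"][i], out["self_report_pa_score"][i]) for i in range(n)
    ]
    out["db_interpretation"] = interp_column("db")
    out["db_status"] = status_column("db")

    # motivation & confidence
    out["predilection_score"] = [
        score_csappa_subscale(
            raw["csappa1"][i], raw["csappa3"][i], raw["csappa5"][i], "predilection", cfg
        )
        for i in range(n)
    ]
    out["adequacy_score"] = [
        score_csappa_subscale(
            raw["csappa2"][i], raw["csappa4"][i], raw["csappa6"][i], "adequacy", cfg
        )
        for i in range(n)
    ]
    out["intrinsic_motivation_score"] = [
        score_breq_subscale(
            raw["why_active1"][i], raw["why_active2"][i], raw["why_active3"][i], cfg
        )
        for i in range(n)
    ]
    out["pa_competence_score"] = [
        score_breq_subscale(
            raw["feelings_about_pa1"][i],
            raw["feelings_about_pa2"][i],
            raw["feelings_about_pa3"][i],
            cfg,
        )
        for i in range(n)
    ]
    out["mc_score"] = [
        score_mc(
            out["predilection_score"][i],
            out["adequacy_score"][i],
            out["intrinsic_motivation_score"][i],
            out["pa_competence_score"][i],
        )
        for i in range(n)
    ]
    out["mc_interpretation"] = interp_column("mc")
    out["mc_status"] = status_column("mc")

    # knowledge & understanding
    for item in ("pa_guideline", "crf_means", "ms_means", "sports_skill"):
        out[f"{item}_score"] = [score_binary_item(v, item, cfg) for v in raw[item]]
    out["fill_in_the_blanks_score"] = [
        score_fill_blanks(
            raw["pa_is"][i],
            raw["pa_is_also"][i],
            raw["improve"][i],
            raw["increase"][i],
            raw["when_cooling_down"][i],
            raw["heart_rate"][i],
            cfg,
        )
        for i in range(n)
    ]
    out["ku_score"] = [
        score_ku(
            out["pa_guideline_score"][i],
            out["crf_means_score"][i],
            out["ms_means_score"][i],
            out["sports_skill_score"][i],
            out["fill_in_the_blanks_score"][i],
        )
        for i in range(n)
    ]
    out["ku_interpretation"] = interp_column("ku")
    out["ku_status"] = status_column("ku")

    # overall
    out["capl_score"] = [
        score_capl(out["pc_score"][i], out["db_score"][i], out["mc_score"][i], out["ku_score"][i])
        for i in range(n)
    ]
    out["capl_interpretation"] = interp_column("capl")
    out["capl_status"] = status_column("capl")

    result = data.copy()
    for name in DERIVED_VARIABLES:
        result[name] = pd.Series(out[name], index=result.index, dtype=object)
        result[name] = result[name].infer_objects()

    for domain in DOMAIN_COMPONENTS:
        n_missing = sum(is_missing(v) for v in out[f"{domain}_score"])
        logger.info("domain %s: %d of %d rows missing a score", domain, n_missing, n)

    if sort == "abc":
        result = result[sorted(result.columns)]
    elif sort == "zyx":
        result = result[sorted(result.columns, reverse=True)]
    return result


# -- demo data ---------------------------------------------------------------

_GENDER_ENCODINGS = ("girl", "Girl", "g", "f", "Female", "boy", "Boy", "b", "m", "Male", 0, 1)
_WRONG_WORDS = ("exercise", "sleep", "slowly", "speed", "water", "energy")


def generate_demo(n: int = 500, seed: int = 1, missing_prob: float = 0.05) -> pd.DataFrame:
    """Generate a seeded table of deliberately messy raw demo data.

    Ages 8-12, mixed gender encodings, step counts spanning the validity
    bounds, mixed 12h/24h clock strings, Likert items, knowledge responses
    as codes or verbatim strings, and sporadic missing values (each field
    independently missing with probability ``missing_prob``).
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    cfg = load_config()

    def clock(hour: int, minute: int) -> str:
        if rng.random() < 0.5:
            meridiem = "am" if hour < 12 else "pm"
            display = hour % 12 or 12
            return f"{display}:{minute:02d} {meridiem}"
        return f"{hour:02d}:{minute:02d}"

    columns: dict[str, list] = {}
    columns["age"] = rng.integers(8, 13, n).tolist()
    columns["gender"] = [_GENDER_ENCODINGS[i] for i in rng.integers(0, len(_GENDER_ENCODINGS), n)]
    columns["pacer_lap_distance"] = rng.choice([15, 20], n).tolist()
    columns["pacer_laps"] = rng.integers(1, 235, n).tolist()
    columns["plank_time"] = rng.integers(5, 301, n).tolist()
    for trial in (1, 2):
        columns[f"camsa_skill_score{trial}"] = rng.integers(0, 15, n).tolist()
        columns[f"camsa_time{trial}"] = rng.integers(10, 41, n).tolist()
    for day in range(1, 8):
        columns[f"steps{day}"] = rng.integers(500, 30001, n).tolist()
        columns[f"time_on{day}"] = [
            clock(int(h), int(m)) for h, m in zip(rng.integers(6, 10, n), rng.integers(0, 60, n))
        ]
        columns[f"time_off{day}"] = [
            clock(int(h), int(m)) for h, m in zip(rng.integers(17, 23, n), rng.integers(0, 60, n))
        ]
        columns[f"non_wear_time{day}"] = rng.integers(0, 121, n).tolist()
    columns["self_report_pa"] = rng.integers(0, 8, n).tolist()
    for item in range(1, 7):
        columns[f"csappa{item}"] = rng.integers(1, 5, n).tolist()
    for item in range(1, 4):
        columns[f"why_active{item}"] = rng.integers(1, 6, n).tolist()
        columns[f"feelings_about_pa{item}"] = rng.integers(1, 6, n).tolist()
    for item in ("pa_guideline", "crf_means", "ms_means", "sports_skill"):
        key = cfg.answer_keys[item]
        codes = rng.integers(1, 5, n)
        as_string = rng.random(n) < 0.25
        columns[item] = [
            key["strings"][0] if use_string and code == key["code"] else int(code)
            for code, use_string in zip(codes, as_string)
        ]
    for blank, accepted in cfg.fill_blank_keys.items():
        pool = [accepted[0], *_WRONG_WORDS]
        weights = [0.55] + [0.45 / len(_WRONG_WORDS)] * len(_WRONG_WORDS)
        columns[blank] = [pool[i] for i in rng.choice(len(pool), n, p=weights)]

    frame = pd.DataFrame({name: columns[name] for name in RAW_VARIABLES})
    mask = rng.random((n, len(RAW_VARIABLES))) < missing_prob
    frame = frame.mask(pd.DataFrame(mask, columns=list(RAW_VARIABLES)))
    return frame
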