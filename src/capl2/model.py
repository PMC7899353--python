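"""Shared data model: variable manifests and controlled vocabularies."""

from __future__ import annotations

#: The 60 raw input variables required to score one child, in canonical order.
RAW_VARIABLES: tuple[str, ...] = (
    "age",
    "gender",
    "pacer_lap_distance",
    "pacer_laps",
    "plank_time",
    "camsa_skill_score1",
    "camsa_time1",
    "camsa_skill_score2",
    "camsa_time2",
    *(
        name
        for day in range(1, 8)
        for name in (
            f"steps{day}",
            f"time_on{day}",
            f"time_off{day}",
            f"non_wear_time{day}",
        )
    ),
    "self_report_pa",
    "csappa1",
    "csappa2",
    "csappa3",
    "csappa4",
    "csappa5",
    "csappa6",
    "why_active1",
    "why_active2",
    "why_active3",
    "feelings_about_pa1",
    "feelings_about_pa2",
    "feelings_about_pa3",
    "pa_guideline",
    "crf_means",
    "ms_means",
    "sports_skill",
    "pa_is",
    "pa_is_also",
    "improve",
    "increase",
    "when_cooling_down",
    "heart_rate",
)

#: The 40 derived variables added by the scoring pipeline, in computation order.
DERIVED_VARIABLES: tuple[str, ...] = (
    "pacer_laps_20m",
    "pacer_score",
    "pacer_interpretation",
    "plank_score",
    "plank_interpretation",
    "camsa_time_score1",
    "camsa_time_score2",
    "camsa_skill_time_score1",
    "camsa_skill_time_score2",
    "camsa_score",
    "camsa_interpretation",
    "pc_score",
    "pc_interpretation",
    "pc_status",
    "step_average",
    "valid_days",
    "step_score",
    "step_interpretation",
    "self_report_pa_score",
    "db_score",
    "db_interpretation",
    "db_status",
    "predilection_score",
    "adequacy_score",
    "intrinsic_motivation_score",
    "pa_competence_score",
    "mc_score",
    "mc_interpretation",
    "mc_status",
    "pa_guideline_score",
    "crf_means_score",
    "ms_means_score",
    "sports_skill_score",
    "fill_in_the_blanks_score",
    "ku_score",
    "ku_interpretation",
    "ku_status",
    "capl_score",
    "capl_interpretation",
    "capl_status",
)

#: Interpretive categories, ordered from lowest to highest attainment.
CATEGORIES: tuple[str, ...] = ("beginning", "progressing", "achieving", "excelling")

#: Domain completeness labels, ordered by check precedence.
DOMAIN_STATUSES: tuple[str, ...] = (
    "incomplete",
    "missing interpretation",
    "missing protocol",
    "complete",
)

#: Per-domain wiring used by domain-status classification: the domain score
#: column, its interpretation column, and the component columns feeding it.
DOMAIN_COMPONENTS: dict[str, dict[str, object]] = {
    "pc": {
        "score": "pc_score",
        "interpretation": "pc_interpretation",
        "components": ("pacer_score", "plank_score", "camsa_score"),
    },
    "db": {
        "score": "db_score",
        "interpretation": "db_interpretation",
        "components": ("step_score", "self_report_pa_score"),
    },
    "mc": {
        "score": "mc_score",
        "interpretation": "mc_interpretation",
        "components": (
            "predilection_score",
            "adequacy_score",
            "intrinsic_motivation_score",
            "pa_competence_score",
        ),
    },
    "ku": {
        "score": "ku_score",
        "interpretation": "ku_interpretation",
        "components": (
            "pa_guideline_score",
            "crf_means_score",
            "ms_means_score",
            "sports_skill_score",
            "fill_in_the_blanks_score",
        ),
    },
    "capl": {
        "score": "capl_score",
        "interpretation": "capl_interpretation",
        "components": ("pc_score", "db_score", "mc_score", "ku_score"),
    },
}
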