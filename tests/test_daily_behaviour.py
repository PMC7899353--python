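import numpy as np
import pytest

from capl2 import (
    score_db,
    score_self_report,
    score_steps,
    step_average,
    validate_steps,
    wear_time,
)

from fixtures_demo import DB_SCORE, SELF_REPORT_PA_SCORE, STEP_SCORE


def make_week(steps, on="7:00 am", off="9:00 pm", non_wear=0):
    """Build a raw pedometer-week dict; steps may hold None for absent days."""
    week = {}
    for day, count in enumerate(steps, start=1):
        week[f"steps{day}"] = count
        week[f"time_on{day}"] = on if count is not None else None
        week[f"time_off{day}"] = off
        week[f"non_wear_time{day}"] = non_wear
    return week


class TestWearTime:
    @pytest.mark.parametrize(
        "on, off, non_wear, expected",
        [
            (7.0, 21.5, 90, 13.0),
            (7.0, 21.5, None, 14.5),
            (21.0, 7.0, 0, None),
            (7.0, 7.0, 0, None),
            ("7:00 am", "9:30 pm", 90, 13.0),
            (None, 21.0, 0, None),
            (8.0, 9.0, 600, None),  # non-wear exceeds the window
        ],
    )
    def test_examples(self, on, off, non_wear, expected):
        result = wear_time(on, off, non_wear)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)


class TestValidateSteps:
    @pytest.mark.parametrize(
        "steps, hours, expected",
        [
            (12000, 12.0, 12000),
            (900, 12.0, None),
            (12000, 8.0, None),
            (30001, 12.0, None),
            (1000, 10.0, 1000),
            (None, 12.0, None),
            (12000, None, None),
            (12000.5, 12.0, None),
        ],
    )
    def test_examples(self, steps, hours, expected, config):
        # bounds oracle: the config entries themselves
        low, high = config.step_bounds
        assert (low, high, config.min_wear_hours) == (1000, 30000, 10.0)
        assert validate_steps(steps, hours, config) == expected


class TestStepAverage:
    def test_seven_constant_days(self, config):
        week = make_week([10000] * 7)
        result = step_average(week, config, np.random.default_rng(1))
        assert result.valid_days == 7
        assert result.step_average == 10000
        assert result.imputed_day_source is None

    def test_three_valid_days_imputes_one(self, config):
        week = make_week([8000, 9000, 10000, None, None, None, None])
        # oracle: enumerate the three possible imputations
        possible = {(8000 + 9000 + 10000 + extra) / 4 for extra in (8000, 9000, 10000)}
        seen = set()
        for seed in range(30):
            result = step_average(week, config, np.random.default_rng(seed))
            assert result.valid_days == 3
            assert result.step_average in possible
            seen.add(result.step_average)
        assert seen == possible  # all three imputations reachable

    def test_two_valid_days_missing(self, config):
        week = make_week([8000, 9000, None, None, None, None, None])
        result = step_average(week, config, np.random.default_rng(1))
        assert result.valid_days == 2
        assert result.step_average is None

    def test_seeded_reproducibility(self, config):
        week = make_week([8000, 9000, 10000, None, None, None, None])
        first = step_average(week, config, np.random.default_rng(42))
        second = step_average(week, config, np.random.default_rng(42))
        assert first.step_average == second.step_average

    def test_imputation_no_effect_when_equal(self, config):
        week = make_week([9000, 9000, 9000, None, None, None, None])
        for seed in range(5):
            result = step_average(week, config, np.random.default_rng(seed))
            assert result.step_average == 9000

    def test_average_within_valid_day_bounds(self, config):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.integers(1000, 30001, size=7).tolist()
            n_drop = int(rng.integers(0, 5))
            for index in rng.choice(7, size=n_drop, replace=False):
                counts[index] = None
            result = step_average(make_week(counts), config, rng)
            valid = [c for c in counts if c is not None]
            if result.step_average is not None:
                assert min(valid) <= result.step_average <= max(valid)

    def test_short_wear_time_invalidates_day(self, config):
        week = make_week([10000] * 7, on="7:00 am", off="3:00 pm")  # 8 h worn
        result = step_average(week, config, np.random.default_rng(1))
        assert result.valid_days == 0
        assert result.step_average is None


class TestScoreSteps:
    def test_range_endpoints(self, config):
        edges = config.step_score_lower_edges
        assert score_steps(edges[-1] + 1, config) == 25
        assert score_steps(edges[0] - 1, config) == 0
        assert score_steps(None, config) is None

    def test_monotone(self, config):
        averages = range(0, 31000, 250)
        scores = [score_steps(a, config) for a in averages]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestScoreSelfReport:
    @pytest.mark.parametrize("days, expected", [(0, 0), (5, 5), (None, None), (8, None)])
    def test_examples(self, days, expected, config):
        assert score_self_report(days, config) == expected

    def test_seven_days_capped(self, config):
        # oracle: the configured mapping
        assert score_self_report(7, config) == config.self_report_map[7]


class TestScoreDb:
    @pytest.mark.parametrize(
        "step, self_report, expected",
        [(25, 1, 26), (25, None, None), (25, 5, 30), (None, 5, None), (26, 5, None)],
    )
    def test_examples(self, step, self_report, expected):
        assert score_db(step, self_report) == expected

    def test_regression_triples(self):
        assert len(STEP_SCORE) == len(SELF_REPORT_PA_SCORE) == len(DB_SCORE) == 250
        for step, self_report, expected in zip(STEP_SCORE, SELF_REPORT_PA_SCORE, DB_SCORE):
            assert score_db(step, self_report) == expected
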