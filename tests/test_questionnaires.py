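import itertools

import pytest

from capl2 import (
    score_binary_item,
    score_breq_subscale,
    score_csappa_subscale,
    score_fill_blanks,
    score_ku,
    score_mc,
)

from fixtures_demo import (
    ADEQUACY_SCORE,
    CRF_MEANS_SCORE,
    FILL_IN_THE_BLANKS_SCORE,
    INTRINSIC_MOTIVATION_SCORE,
    KU_SCORE,
    MS_MEANS_SCORE,
    PA_COMPETENCE_SCORE,
    PA_GUIDELINE_SCORE,
    PREDILECTION_SCORE,
    SPORTS_SKILL_SCORE,
)
from test_physical_competence import oracle_reweighted

POINT_LEVELS = {0.6, 1.2, 1.8, 2.5}


def decomposable(value, levels, k=3, tolerance=1e-9):
    """True when value is a sum of k elements (with repetition) of levels."""
    return any(
        abs(sum(combo) - value) < tolerance
        for combo in itertools.combinations_with_replacement(sorted(levels), k)
    )


class TestCsappaSubscales:
    def test_extremes_over_all_response_triples(self, config):
        for which in ("predilection", "adequacy"):
            scores = [
                score_csappa_subscale(a, b, c, which, config)
                for a, b, c in itertools.product(range(1, 5), repeat=3)
            ]
            assert min(scores) == pytest.approx(1.8)
            assert max(scores) == pytest.approx(7.5)

    def test_specific_point_sum(self, config):
        # build responses earning points {0.6, 1.2, 2.5} on predilection items
        inverse = {}
        for item in ("csappa1", "csappa3", "csappa5"):
            inverse[item] = {}
            for response in range(1, 5):
                effective = response
                if config.csappa_orientation[item] == "reversed":
                    effective = 5 - response
                inverse[item][config.csappa_points[effective]] = response
        responses = (
            inverse["csappa1"][0.6],
            inverse["csappa3"][1.2],
            inverse["csappa5"][2.5],
        )
        assert score_csappa_subscale(*responses, "predilection", config) == pytest.approx(4.3)

    def test_missing_item_missing(self, config):
        assert score_csappa_subscale(1, None, 3, "predilection", config) is None
        assert score_csappa_subscale(1, 5, 3, "adequacy", config) is None

    def test_unknown_subscale_raises(self, config):
        with pytest.raises(ValueError):
            score_csappa_subscale(1, 2, 3, "bogus", config)

    def test_regression_vectors_decompose(self):
        for vector in (PREDILECTION_SCORE, ADEQUACY_SCORE):
            assert len(vector) == 180
            for value in vector:
                if value is not None:
                    assert decomposable(value, POINT_LEVELS), value


class TestBreqSubscales:
    @pytest.mark.parametrize(
        "items, expected", [((1, 1, 1), 1.5), ((5, 5, 5), 7.5), ((3, 4, 5), 6.0)]
    )
    def test_examples(self, items, expected, config):
        assert score_breq_subscale(*items, config) == pytest.approx(expected)

    def test_missing_or_invalid(self, config):
        assert score_breq_subscale(1, None, 3, config) is None
        assert score_breq_subscale(1, 6, 3, config) is None

    def test_regression_vectors_half_point_grid(self):
        for vector in (INTRINSIC_MOTIVATION_SCORE, PA_COMPETENCE_SCORE):
            assert len(vector) == 180
            for value in vector:
                if value is not None:
                    assert 1.5 <= value <= 7.5
                    assert (value * 2) == int(value * 2)


class TestScoreMc:
    @pytest.mark.parametrize(
        "subscales, expected",
        [
            ((7.5, 7.5, 7.5, 7.5), 30.0),
            ((6, 6, 6, None), 24.0),
            ((6, None, None, 6), None),
        ],
    )
    def test_examples(self, subscales, expected):
        result = score_mc(*subscales)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)

    def test_reweighting_oracle_exhaustive(self):
        grid = [None, 1.5, 3.0, 4.5, 7.5]
        for quad in itertools.product(grid, repeat=4):
            expected = oracle_reweighted(quad, (7.5,) * 4, 30)
            result = score_mc(*quad)
            if expected is None:
                assert result is None, quad
            else:
                assert result == pytest.approx(expected), quad


class TestBinaryItems:
    def test_integer_code_match(self, config):
        assert score_binary_item(3, "pa_guideline", config) == 1
        assert score_binary_item(2, "pa_guideline", config) == 0
        assert score_binary_item("3", "pa_guideline", config) == 1

    def test_verbatim_string_match(self, config):
        assert (
            score_binary_item("How well the muscles can push, pull or stretch", "ms_means", config)
            == 1
        )
        assert score_binary_item("how well the muscles can push, pull or stretch", "ms_means", config) == 0
        assert score_binary_item("wrong answer", "ms_means", config) == 0

    def test_all_four_keys(self, config):
        expected_codes = {"pa_guideline": 3, "crf_means": 2, "ms_means": 1, "sports_skill": 4}
        for item, code in expected_codes.items():
            assert score_binary_item(code, item, config) == 1
            assert score_binary_item(config.answer_keys[item]["strings"][0], item, config) == 1

    def test_missing(self, config):
        assert score_binary_item(None, "pa_guideline", config) is None
        assert score_binary_item("", "pa_guideline", config) is None
        assert score_binary_item("   ", "pa_guideline", config) is None


class TestFillBlanks:
    def test_all_correct(self, config):
        answers = {blank: words[0] for blank, words in config.fill_blank_keys.items()}
        assert score_fill_blanks(**answers, config=config) == 6

    def test_none_correct(self, config):
        answers = {blank: "xyzzy" for blank in config.fill_blank_keys}
        assert score_fill_blanks(**answers, config=config) == 0

    def test_blank_counts_zero_not_missing(self, config):
        keys = list(config.fill_blank_keys)
        answers = {blank: config.fill_blank_keys[blank][0] for blank in keys[:3]}
        answers.update({blank: None for blank in keys[3:]})
        assert score_fill_blanks(**answers, config=config) == 3

    def test_all_missing_scores_zero(self, config):
        answers = {blank: None for blank in config.fill_blank_keys}
        assert score_fill_blanks(**answers, config=config) == 0


class TestScoreKu:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ((1, 0, 0, 1, 5), 7),
            ((1, 1, 1, 1, None), 10.0),
            ((None, None, 1, 1, 6), None),
            ((1, 1, 1, 1, 6), 10),
        ],
    )
    def test_examples(self, components, expected):
        result = score_ku(*components)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)

    def test_regression_first_80(self):
        components = zip(
            PA_GUIDELINE_SCORE,
            CRF_MEANS_SCORE,
            MS_MEANS_SCORE,
            SPORTS_SKILL_SCORE,
            FILL_IN_THE_BLANKS_SCORE,
        )
        for row, expected in zip(components, KU_SCORE):
            assert score_ku(*row) == pytest.approx(expected)

    def test_reweighting_oracle_one_missing(self):
        binary_grid = [None, 0, 1]
        fill_grid = [None, 0, 3, 6]
        for q1, q2, q3, q4 in itertools.product(binary_grid, repeat=4):
            for fill in fill_grid:
                values = (q1, q2, q3, q4, fill)
                expected = oracle_reweighted(values, (1, 1, 1, 1, 6), 10)
                result = score_ku(*values)
                if expected is None:
                    assert result is None, values
                else:
                    assert result == pytest.approx(expected), values
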