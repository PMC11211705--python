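"""Coding and quantitative synthesis: tables, sums, series, matrices."""

from datetime import date

import pytest

from wios.aggregate import (
    Code,
    Codebook,
    CodedRecord,
    SummaryItem,
    affected_sums,
    apply_codebook,
    cooccurrence_matrix,
    country_coverage,
    default_codebooks,
    distribution_from_counts,
    monthly_series,
    round_half_up,
    stacked_share_series,
    subevent_distribution,
)
from wios.geo_time import UNRESOLVED


def rec(aid, topic, codes=(), country="IN", month=(2020, 4), count=None, kind=None):
    return CodedRecord(
        article_id=aid, topic_id=topic, codes=tuple(codes),
        country=country, month=month, affected_count=count, affected_kind=kind,
    )


@pytest.fixture(scope="module")
def codebooks():
    return default_codebooks()


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(53.859, 1, 53.9), (6.374, 1, 6.4), (0.05, 1, 0.1), (28.5714, 2, 28.57)],
    )
    def test_half_up(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


class TestDistribution:
    def test_infection_death_percentages(self):
        table = distribution_from_counts(
            {"infections": 307, "deaths": 135, "infections_and_deaths": 128}
        )
        pct = {code: p for code, _, _, p in table.rows}
        assert pct == {
            "infections": 53.9, "deaths": 23.7, "infections_and_deaths": 22.5
        }
        assert table.total == 570

    def test_industrial_action_percentages(self):
        table = distribution_from_counts(
            {"demonstration": 128, "sit_down_walkout": 16, "strike": 107}
        )
        pct = {code: p for code, _, _, p in table.rows}
        assert pct == {"demonstration": 51.0, "sit_down_walkout": 6.4, "strike": 42.6}

    def test_two_decimal_flag(self):
        table = distribution_from_counts({"exhaustion": 332, "rest": 830}, decimals=2)
        pct = {code: p for code, _, _, p in table.rows}
        assert pct["exhaustion"] == 28.57

    def test_single_record_is_hundred_percent(self, codebooks):
        table = subevent_distribution(
            [rec("a", "industrial_action", ["strike"])],
            codebooks["area_of_impact"],
            topic="industrial_action",
        )
        assert table.rows == [("strike", "Strike", 1, 100.0)]

    def test_empty_scope_gives_empty_table(self, codebooks):
        table = subevent_distribution([], codebooks["area_of_impact"], topic="vaccination")
        assert table.total == 0 and table.rows == []

    def test_counts_conserve_and_percentages_close(self, codebooks):
        records = [
            rec(f"a{i}", "mental_health", [code])
            for i, code in enumerate(
                ["anxiety"] * 7 + ["burnout"] * 9 + ["stress"] * 11 + ["trauma"] * 3
            )
        ]
        table = subevent_distribution(records, codebooks["area_of_impact"])
        assert sum(n for _, _, n, _ in table.rows) == table.total == 30
        assert 99.7 <= sum(p for _, _, _, p in table.rows) <= 100.3


class TestApplyCodebook:
    def test_keyword_assigns_code(self, codebooks):
        items = [SummaryItem("a", "mental_health", "Staff reported burnout today.")]
        [r] = apply_codebook(items, codebooks["area_of_impact"])
        assert r.codes == ("burnout",)

    def test_no_keyword_no_codes(self, codebooks):
        items = [SummaryItem("a", "mental_health", "Nothing to see here.")]
        [r] = apply_codebook(items, codebooks["area_of_impact"])
        assert r.codes == ()

    def test_vaccination_without_dose_keyword_is_unspecified(self, codebooks):
        items = [SummaryItem("a", "vaccination", "The vaccination drive continued.")]
        [r] = apply_codebook(items, codebooks["area_of_impact"])
        assert r.codes == ("unspecified",)

    def test_manual_codes_override(self, codebooks):
        items = [SummaryItem("a", "mental_health", "Staff reported burnout today.")]
        [r] = apply_codebook(
            items, codebooks["area_of_impact"], manual_codes={"a": ["stress"]}
        )
        assert r.codes == ("stress",)

    def test_unknown_manual_code_rejected(self, codebooks):
        with pytest.raises(ValueError, match="unknown codes"):
            apply_codebook([], codebooks["area_of_impact"], manual_codes={"a": ["nope"]})

    def test_negative_affected_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rec("a", "vaccination", count=-1, kind="vaccinated")

    def test_count_requires_kind(self):
        with pytest.raises(ValueError, match="affected_kind"):
            rec("a", "vaccination", count=5)


class TestAffectedSums:
    def test_no_counts_all_excluded(self):
        sums = affected_sums([rec("a", "mental_health"), rec("b", "education")])
        assert sums.totals == {} and sums.n_excluded == 2

    def test_strike_total_matches_component_sum(self):
        records = [
            rec("a", "industrial_action", count=3_500_000, kind="striking"),
            rec("b", "industrial_action", count=110_735, kind="striking"),
        ]
        sums = affected_sums(records)
        assert sums.totals["striking"][2020] == 3_610_735

    def test_planted_synthetic_counts_recovered(self, synthetic_corpus):
        corpus, truth = synthetic_corpus
        records, expected = [], {}
        for aid, tr in truth.by_article.items():
            if tr.affected_count is None or tr.duplicate_of is not None:
                continue
            year = 2021
            records.append(
                rec(aid, "any", month=(year, 1), count=tr.affected_count,
                    kind=tr.affected_kind)
            )
            expected[tr.affected_kind] = (
                expected.get(tr.affected_kind, 0) + tr.affected_count
            )
        sums = affected_sums(records)
        assert {k: v[2021] for k, v in sums.totals.items()} == expected


class TestSeriesAndCoverage:
    WINDOW = (date(2020, 1, 1), date(2020, 6, 30))

    def test_empty_records_all_zero_series(self):
        series = monthly_series([], "vaccination", self.WINDOW)
        assert len(series) == 6 and all(v == 0 for v in series.values())

    def test_conservation_over_months(self):
        records = [rec(f"a{i}", "vaccination", month=(2020, 1 + i % 3)) for i in range(9)]
        series = monthly_series(records, "vaccination", self.WINDOW)
        assert sum(series.values()) == len({r.article_id for r in records})

    def test_distinct_articles_counted_once(self):
        records = [
            rec("a", "vaccination", ["first_dose"]),
            rec("a", "vaccination", ["booster_dose"]),
        ]
        series = monthly_series(records, "vaccination")
        assert series[(2020, 4)] == 1

    def test_all_unresolved_gives_zero_coverage(self):
        records = [rec("a", "t", country=UNRESOLVED), rec("b", "t", country=UNRESOLVED)]
        assert country_coverage(records) == 0

    def test_distinct_countries(self):
        records = [rec("a", "t", country="IN"), rec("b", "t", country="IN"),
                   rec("c", "t", country="US")]
        assert country_coverage(records) == 2


class TestCooccurrence:
    def test_disjoint_assignments_zero_matrix(self):
        records = [rec("a", "t1", ["c1"]), rec("b", "t2", ["c2"])]
        cooc = cooccurrence_matrix(records, ["c2"], ["t1"])
        assert cooc.matrix.to_numpy().sum() == 0

    def test_two_codes_two_topics_four_cells(self):
        records = [rec("a", "t1", ["c1", "c2"]), rec("a", "t2", ["c1", "c2"])]
        cooc = cooccurrence_matrix(records, ["c1", "c2"], ["t1", "t2"])
        assert (cooc.matrix.to_numpy() == 1).all()
        assert list(cooc.row_marginals) == [1, 1]
        assert list(cooc.col_marginals) == [1, 1]

    def test_matches_brute_force_pairwise_count(self, synthetic_corpus, codebooks):
        import random

        rnd = random.Random(11)
        codes = list(codebooks["contributing_factor"].codes)
        topics = ["t1", "t2", "t3"]
        records = []
        for i in range(200):
            aid = f"a{i % 80}"  # repeated articles pool codes
            records.append(
                rec(aid, rnd.choice(topics), rnd.sample(codes, rnd.randint(0, 3)))
            )
        cooc = cooccurrence_matrix(records, codes, topics)
        # brute force over distinct articles
        by_article = {}
        for r in records:
            entry = by_article.setdefault(r.article_id, (set(), set()))
            entry[0].update(r.codes)
            entry[1].add(r.topic_id)
        for a_code in codes:
            for b_topic in topics:
                want = sum(
                    1 for cs, ts in by_article.values()
                    if a_code in cs and b_topic in ts
                )
                assert cooc.matrix.loc[a_code, b_topic] == want
                assert cooc.matrix.loc[a_code, b_topic] <= min(
                    cooc.row_marginals[a_code], cooc.col_marginals[b_topic]
                )


class TestStackedShares:
    WINDOW = (date(2020, 1, 1), date(2020, 3, 31))

    def test_single_code_share_one(self):
        records = [rec("a", "t", ["c1"], month=(2020, 2))]
        df = stacked_share_series(records, ["c1"], self.WINDOW)
        assert df.loc["2020-02", "c1"] == 1.0

    def test_share_split(self):
        records = [
            rec("a", "t", ["c1"], month=(2020, 1)),
            rec("b", "t", ["c1"], month=(2020, 1)),
            rec("c", "t", ["c1"], month=(2020, 1)),
            rec("d", "t", ["c2"], month=(2020, 1)),
        ]
        df = stacked_share_series(records, ["c1", "c2"], self.WINDOW)
        assert df.loc["2020-01", "c1"] == 0.75
        assert df.loc["2020-01", "c2"] == 0.25

    def test_empty_months_flagged_zero(self):
        records = [rec("a", "t", ["c1"], month=(2020, 1))]
        df = stacked_share_series(records, ["c1"], self.WINDOW)
        assert bool(df.loc["2020-03", "empty"]) is True
        assert df.loc["2020-03", "c1"] == 0.0

    def test_nonempty_months_sum_to_one(self, synthetic_corpus, codebooks):
        corpus, truth = synthetic_corpus
        codes = list(codebooks["contributing_factor"].codes)
        records = []
        from wios.geo_time import month_bucket

        for a in corpus:
            tr = truth.by_article[a.article_id]
            if tr.factor_codes:
                records.append(
                    rec(a.article_id, "any", tr.factor_codes,
                        month=month_bucket(a.published))
                )
        df = stacked_share_series(records, codes, corpus.date_window)
        nonempty = df[~df["empty"]]
        sums = nonempty[codes].sum(axis=1)
        assert ((sums - 1.0).abs() < 1e-12).all()


class TestCodebookValidation:
    def test_code_without_keywords_rejected(self):
        with pytest.raises(ValueError, match="no keywords"):
            Code("x", "X", keywords=())

    def test_duplicate_code_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate code"):
            Codebook.from_mapping(
                "response",
                {"codes": [{"code": "x", "keywords": ["a"]},
                           {"code": "x", "keywords": ["b"]}]},
            )

    def test_unknown_theme_rejected(self):
        with pytest.raises(ValueError, match="theme"):
            Codebook("sentiment", {})
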