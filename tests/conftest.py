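"""Shared fixtures: small hand-built corpora and a generated corpus."""

from __future__ import annotations

from datetime import date

import pytest

from wios.corpus_model import Corpus, NewsArticle
from wios.rule_engine import parse_ruleset
from wios.synthetic_data import GenerationSpec, default_rule_config, generate_corpus


def make_article(
    article_id: str,
    body: str = "",
    title: str = "",
    published: date = date(2020, 6, 1),
    tags: tuple[str, ...] = (),
) -> NewsArticle:
    return NewsArticle(
        article_id=article_id,
        title=title,
        body=body,
        published=published,
        country_tags=tags,
    )


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            make_article(
                "a1",
                title="Nurses strike over pay",
                body="Hundreds of nurses walked out on Monday. "
                "The dispute concerns unpaid wages.",
                published=date(2020, 3, 5),
                tags=("GB",),
            ),
            make_article(
                "a2",
                title="Vaccine rollout begins",
                body="The first dose campaign started this week. "
                "Health workers queued at the central hospital.",
                published=date(2021, 1, 12),
                tags=("IN", "US"),
            ),
            make_article(
                "a3",
                title="Weather review",
                body="Rainfall was above average. Farmers adjusted planting plans.",
                published=date(2020, 7, 20),
                tags=(),
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_rulesets():
    return parse_ruleset(default_rule_config())


@pytest.fixture(scope="session")
def synthetic_corpus():
    """Mid-size generated corpus with ground truth (seed fixed)."""
    spec = GenerationSpec(n_articles=600, seed=101)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def clean_corpus():
    """No duplicates, no background: every article is topic-labeled."""
    spec = GenerationSpec(
        n_articles=400, seed=55, background_fraction=0.0, duplicate_rate=0.0
    )
    return generate_corpus(spec)
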