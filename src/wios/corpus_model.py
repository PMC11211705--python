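"""Domain types, corpus I/O and corpus-size accounting.

The unit of analysis is a news article record (title, body, publication
date, source, country tags).  A :class:`Corpus` is an ordered collection of
records over a fixed date window; ordering is always the stable
``(published, article_id)`` order so that downstream stages (deduplication
with a keep-earliest policy, seeded sampling) are reproducible.

Corpus size is reported in articles, words and *standardized pages*, a
corpus-accounting unit of 300 whitespace-delimited words (floored).
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger("wios")

WORDS_PER_PAGE = 300

#: Serialized field names, in canonical column order.
ARTICLE_FIELDS = (
    "article_id",
    "title",
    "body",
    "published",
    "source",
    "country_tags",
    "language",
)


class SchemaError(ValueError):
    """A record violated the corpus schema (missing field, bad date...)."""


@dataclass(frozen=True)
class NewsArticle:
    """One media record.

    ``country_tags`` are ISO-3166 alpha-2 codes; an article may carry zero,
    one or several (syndicated wire copy is frequently multi-tagged).
    """

    article_id: str
    title: str
    body: str
    published: date
    source: str = ""
    country_tags: tuple[str, ...] = ()
    language: str = "en"

    def __post_init__(self) -> None:
        if self.title is None or self.body is None:
            raise SchemaError("title and body must be non-null (may be empty)")
        if len(set(self.country_tags)) != len(self.country_tags):
            raise SchemaError(
                f"duplicate country tags on article {self.article_id!r}"
            )

    @property
    def sort_key(self) -> tuple[date, str]:
        return (self.published, self.article_id)

    def to_dict(self) -> dict:
        return {
            "article_id": self.article_id,
            "title": self.title,
            "body": self.body,
            "published": self.published.isoformat(),
            "source": self.source,
            "country_tags": list(self.country_tags),
            "language": self.language,
        }


@dataclass
class Corpus:
    """An ordered sequence of articles within an inclusive date window.

    Iteration order is stable: ``(published, article_id)``.
    """

    articles: list[NewsArticle] = field(default_factory=list)
    date_window: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        self.articles = sorted(self.articles, key=lambda a: a.sort_key)
        ids = [a.article_id for a in self.articles]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise SchemaError(f"duplicate article_id {dup!r} in corpus")
        if self.date_window is None and self.articles:
            self.date_window = (
                min(a.published for a in self.articles),
                max(a.published for a in self.articles),
            )
        if self.date_window is not None:
            lo, hi = self.date_window
            for a in self.articles:
                if not (lo <= a.published <= hi):
                    raise SchemaError(
                        f"article {a.article_id!r} published {a.published} "
                        f"outside window [{lo}, {hi}]"
                    )

    def __iter__(self) -> Iterator[NewsArticle]:
        return iter(self.articles)

    def __len__(self) -> int:
        return len(self.articles)

    def __getitem__(self, i: int) -> NewsArticle:
        return self.articles[i]

    def by_id(self) -> dict[str, NewsArticle]:
        return {a.article_id: a for a in self.articles}

    def subset(self, article_ids: Iterable[str]) -> "Corpus":
        """Sub-corpus restricted to ``article_ids``, order preserved."""
        wanted = set(article_ids)
        return Corpus(
            [a for a in self.articles if a.article_id in wanted],
            date_window=self.date_window,
        )


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _parse_date(value: str | date, line: int) -> date:
    if isinstance(value, date):
        return value
    try:
        # Time-of-day, when present, is discarded: records are dated by
        # calendar day only.
        return datetime.fromisoformat(str(value)).date()
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"line {line}: unparseable date {value!r}") from exc


def _article_from_record(rec: dict, line: int, tags_sep: str | None) -> NewsArticle:
    for fld in ("article_id", "title", "body", "published"):
        if fld not in rec or rec[fld] is None:
            raise SchemaError(f"line {line}: missing required field {fld!r}")
    tags = rec.get("country_tags", ())
    if isinstance(tags, str):
        tags = [t for t in tags.split(tags_sep or "|") if t]
    return NewsArticle(
        article_id=str(rec["article_id"]),
        title=str(rec["title"]),
        body=str(rec["body"]),
        published=_parse_date(rec["published"], line),
        source=str(rec.get("source", "") or ""),
        country_tags=tuple(dict.fromkeys(str(t).upper() for t in tags)),
        language=str(rec.get("language", "en") or "en"),
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSON Lines or CSV.

    Malformed records raise :class:`SchemaError` naming the field and line;
    they are never silently dropped.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    articles: list[NewsArticle] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    rec = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {lineno}: invalid JSON: {exc}") from exc
                articles.append(_article_from_record(rec, lineno, None))
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                articles.append(_article_from_record(rec, lineno, "|"))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    logger.info("read_corpus: %d articles from %s", len(articles), path)
    return Corpus(articles)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSON Lines (default) or CSV with a header row."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for a in corpus:
                fh.write(json.dumps(a.to_dict(), ensure_ascii=False, sort_keys=True))
                fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(ARTICLE_FIELDS))
            writer.writeheader()
            for a in corpus:
                rec = a.to_dict()
                rec["country_tags"] = "|".join(a.country_tags)
                writer.writerow(rec)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


# ---------------------------------------------------------------------------
# Corpus-size accounting
# ---------------------------------------------------------------------------

def word_count(text: str) -> int:
    """Whitespace-delimited token count after trimming; '' counts 0."""
    return len(text.split())


def standardized_pages(total_words: int) -> int:
    """Standardized pages at 300 words per page, floored."""
    if total_words < 0:
        raise ValueError(f"total_words must be >= 0, got {total_words}")
    return total_words // WORDS_PER_PAGE


def corpus_stats(corpus: Corpus | Iterable[NewsArticle], include_title: bool = True) -> dict:
    """Article / word / standardized-page counts for a corpus.

    Words are counted over title + body by default; ``include_title=False``
    restricts the count to bodies (both conventions are defensible for news
    corpora and the choice is recorded in the returned dict).
    """
    n = 0
    words = 0
    for a in corpus:
        n += 1
        words += word_count(a.body)
        if include_title:
            words += word_count(a.title)
    return {
        "articles": n,
        "words": words,
        "pages": standardized_pages(words),
        "include_title": include_title,
    }
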