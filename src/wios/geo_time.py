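"""Country-tag reduction and time clustering.

Source feeds often tag one syndicated article with several countries.  For
per-country synthesis each article needs a single most-relevant country, so
mentions of the tagged countries are cross-checked in the title and body via
a gazetteer (surface form → ISO-3166 alpha-2) and candidates are ranked by
title mentions, then body mentions, then original tag order.  Resolution
only ever *selects among* the article's existing tags; articles whose tags
are never mentioned stay "unresolved" and keep all tags.

Time clustering buckets articles by calendar year-month, the reporting
granularity of the monthly topic series.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

from ._tokens import tokenize
from .corpus_model import NewsArticle

logger = logging.getLogger("wios")

UNRESOLVED = "unresolved"


@dataclass
class Gazetteer:
    """Mapping of surface forms (names, aliases, demonyms) to alpha-2 codes."""

    surface_to_code: dict[str, str]

    def __post_init__(self) -> None:
        # token-tuple index for longest-match scanning
        self._index: dict[tuple[str, ...], str] = {}
        for surface, code in self.surface_to_code.items():
            toks = tuple(tokenize(surface))
            if not toks:
                continue
            if toks in self._index and self._index[toks] != code.upper():
                raise ValueError(f"ambiguous surface form {surface!r}")
            self._index[toks] = code.upper()
        self._max_len = max((len(t) for t in self._index), default=0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Gazetteer":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["surface_form"]] = row["iso2"].upper()
        return cls(mapping)

    @classmethod
    def default(cls) -> "Gazetteer":
        """The gazetteer shipped with the package."""
        with resources.as_file(
            resources.files("wios.data").joinpath("gazetteer.csv")
        ) as p:
            return cls.from_csv(p)

    def scan(self, text: str) -> dict[str, int]:
        """Per-country mention counts via greedy longest-match over tokens."""
        toks = tokenize(text)
        counts: dict[str, int] = {}
        i = 0
        while i < len(toks):
            hit = None
            for n in range(min(self._max_len, len(toks) - i), 0, -1):
                code = self._index.get(tuple(toks[i : i + n]))
                if code is not None:
                    hit = (code, n)
                    break
            if hit:
                counts[hit[0]] = counts.get(hit[0], 0) + 1
                i += hit[1]
            else:
                i += 1
        return counts


@dataclass
class GeoResolution:
    article_id: str
    resolved: str  # alpha-2 code or UNRESOLVED
    evidence: list[tuple[str, str, int]] = field(default_factory=list)
    # (country code, field name, mention count)
    original_tags: tuple[str, ...] = ()


def detect_mentions(
    article: NewsArticle, gazetteer: Gazetteer
) -> dict[str, dict[str, int]]:
    """Mention counts per country, split by field: {code: {title: n, body: m}}."""
    title_counts = gazetteer.scan(article.title)
    body_counts = gazetteer.scan(article.body)
    out: dict[str, dict[str, int]] = {}
    for code in set(title_counts) | set(body_counts):
        out[code] = {
            "title": title_counts.get(code, 0),
            "body": body_counts.get(code, 0),
        }
    return out


def resolve_country(article: NewsArticle, gazetteer: Gazetteer) -> GeoResolution:
    """Reduce the article's tags to the single most relevant country.

    Single-tag articles resolve to that tag without scanning.  Otherwise
    tags are ranked by (title mentions, body mentions, earlier tag order);
    a tag never mentioned anywhere cannot win, and if no tag is mentioned
    the article stays unresolved.
    """
    tags = article.country_tags
    if len(tags) == 1:
        return GeoResolution(article.article_id, tags[0], original_tags=tags)
    if not tags:
        return GeoResolution(article.article_id, UNRESOLVED, original_tags=tags)
    mentions = detect_mentions(article, gazetteer)
    evidence = []
    ranked = []
    for order, tag in enumerate(tags):
        m = mentions.get(tag, {"title": 0, "body": 0})
        if m["title"]:
            evidence.append((tag, "title", m["title"]))
        if m["body"]:
            evidence.append((tag, "body", m["body"]))
        ranked.append((-m["title"], -m["body"], order, tag))
    ranked.sort()
    best = ranked[0]
    if best[0] == 0 and best[1] == 0:  # no tag mentioned at all
        return GeoResolution(article.article_id, UNRESOLVED, evidence, tags)
    return GeoResolution(article.article_id, best[3], evidence, tags)


def month_bucket(
    published: date, window: tuple[date, date] | None = None
) -> tuple[int, int]:
    """Calendar (year, month) cluster of a publication date."""
    if window is not None and not (window[0] <= published <= window[1]):
        warnings.warn(
            f"date {published} outside corpus window {window}; bucketed anyway",
            stacklevel=2,
        )
    return (published.year, published.month)


def month_range(window: tuple[date, date]) -> list[tuple[int, int]]:
    """All (year, month) buckets covering an inclusive date window."""
    start, end = window
    if start > end:
        raise ValueError(f"empty date window {window}")
    months = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        months.append((y, m))
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    return months
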