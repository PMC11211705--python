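"""Coding and quantitative synthesis of summarized records.

A *codebook* maps fine-grained subevent / contributing-factor / response
codes to keyword lists, optionally scoped to topics.  The dictionary-based
auto-coder here is an explicit stand-in for human deductive-inductive
coding: it assigns a code whenever one of its keywords occurs in the
summary text (token-boundary, case-folded); a manual code file, when
supplied, overrides the auto-codes for those articles.

Synthesis outputs mirror a media content analysis report:

* subevent distribution tables — per-code counts and percentages of the
  theme total (half-up rounding, 1 decimal by default);
* yearly sums of "number affected" per kind (vaccinated / striking /
  infected / dead), with an exclusion tally for records lacking counts;
* monthly article-count series per topic;
* country coverage (countries with at least one resolved article);
* code × topic co-occurrence matrices with marginals;
* 100%-stacked monthly share series per code.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._tokens import tokenize
from .geo_time import UNRESOLVED, month_range

logger = logging.getLogger("wios")

THEMES = ("area_of_impact", "contributing_factor", "response")
AFFECTED_KINDS = ("vaccinated", "striking", "infected", "dead")


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Code:
    code_id: str
    label: str
    keywords: tuple[str, ...]
    topics: tuple[str, ...] = ()  # empty = applies to every topic
    manual_only: bool = False
    #: assigned when no other code of the theme matched for the topic
    #: (e.g. "unspecified" vaccination status = absence of any dose keyword)
    default_when_unmatched: bool = False

    def __post_init__(self) -> None:
        if not self.keywords and not (self.manual_only or self.default_when_unmatched):
            raise ValueError(f"code {self.code_id!r} has no keywords and is not manual-only")


@dataclass
class Codebook:
    theme: str
    codes: dict[str, Code]

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise ValueError(f"unknown theme {self.theme!r}; expected one of {THEMES}")

    @classmethod
    def from_mapping(cls, theme: str, data: Mapping) -> "Codebook":
        codes: dict[str, Code] = {}
        for entry in data.get("codes", []):
            cid = str(entry["code"])
            if cid in codes:
                raise ValueError(f"duplicate code id {cid!r}")
            codes[cid] = Code(
                code_id=cid,
                label=str(entry.get("label", cid)),
                keywords=tuple(str(k) for k in entry.get("keywords", [])),
                topics=tuple(str(t) for t in entry.get("topics", [])),
                manual_only=bool(entry.get("manual_only", False)),
                default_when_unmatched=bool(entry.get("default_when_unmatched", False)),
            )
        return cls(theme=theme, codes=codes)


def load_codebooks(path: str | Path) -> dict[str, Codebook]:
    """Load every theme's codebook from one YAML file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    books = {}
    for theme, block in data.get("themes", {}).items():
        books[theme] = Codebook.from_mapping(theme, block)
    return books


def default_codebooks() -> dict[str, Codebook]:
    from importlib import resources

    with resources.as_file(
        resources.files("wios.data").joinpath("codebook.yaml")
    ) as p:
        return load_codebooks(p)


# ---------------------------------------------------------------------------
# Coded records
# ---------------------------------------------------------------------------


@dataclass
class SummaryItem:
    """One article × topic summarized record entering the coding stage."""

    article_id: str
    topic_id: str
    text: str  # summary text (title + selected sentences)
    country: str = UNRESOLVED
    month: tuple[int, int] | None = None
    affected_count: int | None = None
    affected_kind: str | None = None


@dataclass
class CodedRecord:
    """The unit of all synthesis tables: article × topic × codes."""

    article_id: str
    topic_id: str
    codes: tuple[str, ...]
    country: str = UNRESOLVED
    month: tuple[int, int] | None = None
    affected_count: int | None = None
    affected_kind: str | None = None

    def __post_init__(self) -> None:
        if self.affected_count is not None:
            if self.affected_count < 0:
                raise ValueError(
                    f"negative affected_count on article {self.article_id!r}"
                )
            if self.affected_kind is None:
                raise ValueError(
                    f"affected_count without affected_kind on {self.article_id!r}"
                )


def _keyword_tuples(code: Code) -> list[tuple[str, ...]]:
    return [tuple(tokenize(k)) for k in code.keywords if tokenize(k)]


def _contains(tokens: Sequence[str], term: tuple[str, ...]) -> bool:
    n = len(term)
    if n == 0:
        return False
    return any(tuple(tokens[i : i + n]) == term for i in range(len(tokens) - n + 1))


def read_manual_codes(path: str | Path) -> dict[str, list[str]]:
    """Manual code file: CSV with article_id, code_id columns."""
    out: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["article_id"], []).append(row["code_id"])
    return out


def apply_codebook(
    items: Iterable[SummaryItem],
    codebook: Codebook,
    manual_codes: Mapping[str, Sequence[str]] | None = None,
) -> list[CodedRecord]:
    """Auto-code summaries by keyword dictionary; manual codes override.

    A code is assigned iff at least one of its keywords occurs in the
    summary text and the code's topic scoping admits the record's topic.
    """
    if manual_codes:
        unknown = {
            c for cs in manual_codes.values() for c in cs if c not in codebook.codes
        }
        if unknown:
            raise ValueError(
                f"manual code file references unknown codes: {sorted(unknown)}"
            )
    records = []
    kw_cache = {cid: _keyword_tuples(c) for cid, c in codebook.codes.items()}
    for item in items:
        if manual_codes and item.article_id in manual_codes:
            codes = tuple(
                c
                for c in manual_codes[item.article_id]
                if not codebook.codes[c].topics
                or item.topic_id in codebook.codes[c].topics
            )
        else:
            toks = tokenize(item.text)
            codes = tuple(
                cid
                for cid, code in codebook.codes.items()
                if not code.manual_only
                and (not code.topics or item.topic_id in code.topics)
                and any(_contains(toks, kw) for kw in kw_cache[cid])
            )
            if not codes:
                codes = tuple(
                    cid
                    for cid, code in codebook.codes.items()
                    if code.default_when_unmatched
                    and (not code.topics or item.topic_id in code.topics)
                )
        records.append(
            CodedRecord(
                article_id=item.article_id,
                topic_id=item.topic_id,
                codes=codes,
                country=item.country,
                month=item.month,
                affected_count=item.affected_count,
                affected_kind=item.affected_kind,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Distribution tables
# ---------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 at 1 decimal rounds to 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DistributionTable:
    """Per-code counts and percentages of the theme total."""

    theme: str
    topic: str | None
    rows: list[tuple[str, str, int, float]]  # (code_id, label, n, percent)
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["code", "label", "n", "percent"]
        )


def distribution_from_counts(
    counts: Mapping[str, int],
    theme: str = "area_of_impact",
    topic: str | None = None,
    labels: Mapping[str, str] | None = None,
    decimals: int = 1,
) -> DistributionTable:
    """Distribution table straight from per-code counts.

    Percent = 100·n/N with half-up rounding; N is the sum of the counts
    (code-assignment total, not distinct articles).
    """
    total = sum(counts.values())
    rows = []
    for code_id, n in counts.items():
        pct = round_half_up(100.0 * n / total, decimals) if total else 0.0
        rows.append((code_id, (labels or {}).get(code_id, code_id), n, pct))
    return DistributionTable(theme=theme, topic=topic, rows=rows, total=total)


def subevent_distribution(
    records: Iterable[CodedRecord],
    codebook: Codebook,
    topic: str | None = None,
    decimals: int = 1,
) -> DistributionTable:
    """Distribution of codes over records (optionally one topic's records).

    Row units are code assignments: an article carrying several codes
    counts once per code.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if topic is not None and rec.topic_id != topic:
            continue
        for code in rec.codes:
            if code in codebook.codes:
                counts[code] = counts.get(code, 0) + 1
    labels = {cid: c.label for cid, c in codebook.codes.items()}
    return distribution_from_counts(
        counts, theme=codebook.theme, topic=topic, labels=labels, decimals=decimals
    )


# ---------------------------------------------------------------------------
# Affected-count sums
# ---------------------------------------------------------------------------


@dataclass
class AffectedSums:
    totals: dict[str, dict[int, int]]  # kind -> year -> sum
    n_counted: int
    n_excluded: int  # records lacking an affected count

    def to_frame(self) -> pd.DataFrame:
        years = sorted({y for per in self.totals.values() for y in per})
        data = {
            kind: [self.totals.get(kind, {}).get(y, 0) for y in years]
            for kind in self.totals
        }
        return pd.DataFrame(data, index=years).T


def affected_sums(records: Iterable[CodedRecord]) -> AffectedSums:
    """Yearly totals of the reported number affected, per kind.

    Records without a count are excluded from the sums and tallied
    separately (counts often cannot be ascertained from media reports).
    """
    totals: dict[str, dict[int, int]] = {}
    counted = excluded = 0
    for rec in records:
        if rec.affected_count is None:
            excluded += 1
            continue
        if rec.month is None:
            excluded += 1
            continue
        counted += 1
        year = rec.month[0]
        per = totals.setdefault(rec.affected_kind, {})
        per[year] = per.get(year, 0) + rec.affected_count
    return AffectedSums(totals=totals, n_counted=counted, n_excluded=excluded)


# ---------------------------------------------------------------------------
# Series, coverage, co-occurrence
# ---------------------------------------------------------------------------


def monthly_series(
    records: Iterable[CodedRecord],
    topic: str,
    window: tuple[date, date] | None = None,
) -> dict[tuple[int, int], int]:
    """Distinct-article counts per month for one topic; zero months explicit."""
    articles_by_month: dict[tuple[int, int], set[str]] = {}
    for rec in records:
        if rec.topic_id != topic or rec.month is None:
            continue
        articles_by_month.setdefault(rec.month, set()).add(rec.article_id)
    months = (
        month_range(window)
        if window is not None
        else sorted(articles_by_month.keys())
    )
    series = {m: len(articles_by_month.get(m, ())) for m in months}
    for m, ids in articles_by_month.items():
        if m not in series:
            series[m] = len(ids)
    return dict(sorted(series.items()))


def country_coverage(
    records: Iterable[CodedRecord],
    topic: str | None = None,
    code: str | None = None,
) -> int:
    """Number of distinct resolved countries with at least one record."""
    countries = set()
    for rec in records:
        if topic is not None and rec.topic_id != topic:
            continue
        if code is not None and code not in rec.codes:
            continue
        if rec.country and rec.country != UNRESOLVED:
            countries.add(rec.country)
    return len(countries)


@dataclass
class CooccurrenceMatrix:
    matrix: pd.DataFrame  # codes × topics, distinct-article counts
    row_marginals: pd.Series  # distinct articles per code
    col_marginals: pd.Series  # distinct articles per topic


def cooccurrence_matrix(
    records: Iterable[CodedRecord],
    axis_a: Sequence[str],
    axis_b: Sequence[str],
) -> CooccurrenceMatrix:
    """Cell (a, b) = number of distinct articles carrying code a and topic b.

    An article's codes are pooled across its topic records, so a code
    assigned under one topic co-occurs with every topic the article holds.
    """
    codes_by_article: dict[str, set[str]] = {}
    topics_by_article: dict[str, set[str]] = {}
    for rec in records:
        topics_by_article.setdefault(rec.article_id, set()).add(rec.topic_id)
        codes_by_article.setdefault(rec.article_id, set()).update(rec.codes)
    mat = pd.DataFrame(0, index=list(axis_a), columns=list(axis_b))
    row_m = pd.Series(0, index=list(axis_a))
    col_m = pd.Series(0, index=list(axis_b))
    for aid, topics in topics_by_article.items():
        codes = codes_by_article.get(aid, set())
        for a in codes & set(axis_a):
            row_m[a] += 1
        for b in topics & set(axis_b):
            col_m[b] += 1
        for a in codes & set(axis_a):
            for b in topics & set(axis_b):
                mat.loc[a, b] += 1
    return CooccurrenceMatrix(matrix=mat, row_marginals=row_m, col_marginals=col_m)


def stacked_share_series(
    records: Iterable[CodedRecord],
    codes: Sequence[str],
    window: tuple[date, date] | None = None,
) -> pd.DataFrame:
    """Per-month code shares summing to 1 (100%-stacked area chart input).

    Months with no code assignments emit a zero vector and are flagged in
    the ``empty`` column.
    """
    counts: dict[tuple[int, int], dict[str, int]] = {}
    for rec in records:
        if rec.month is None:
            continue
        per = counts.setdefault(rec.month, {})
        for code in rec.codes:
            if code in codes:
                per[code] = per.get(code, 0) + 1
    months = month_range(window) if window is not None else sorted(counts)
    rows = []
    for m in months:
        per = counts.get(m, {})
        total = sum(per.values())
        shares = [per.get(c, 0) / total if total else 0.0 for c in codes]
        rows.append([f"{m[0]:04d}-{m[1]:02d}", *shares, total == 0])
    return pd.DataFrame(rows, columns=["month", *codes, "empty"]).set_index("month")
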