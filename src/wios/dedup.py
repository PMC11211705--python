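"""Near-duplicate removal via word-trigram overlap.

Syndicated wire copy produces near-verbatim repeats of the same article
across outlets.  An article is treated as a duplicate when at least 30% of
its distinct word trigrams (3 consecutive normalized tokens of the body)
already occur in an earlier-kept article; the earliest copy is kept so
first-report timestamps survive for the time-series synthesis.

The overlap denominator is the candidate's own distinct trigram count
(``|cand ∩ ref| / |cand|``); Jaccard is available as an alternative metric.
An inverted index (trigram → kept article) accelerates candidate pairing;
it is exact, and tests anchor it to the O(n²) brute-force pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from ._tokens import tokenize
from .corpus_model import Corpus

logger = logging.getLogger("wios")

DEFAULT_THRESHOLD = 0.30


@dataclass(frozen=True)
class ShingleSet:
    """Distinct word trigrams of one article body."""

    article_id: str
    trigrams: frozenset[tuple[str, str, str]]


def trigrams(body: str, article_id: str = "") -> ShingleSet:
    """Distinct 3-token shingles of ``body``; empty for bodies under 3 tokens."""
    toks = tokenize(body)
    return ShingleSet(
        article_id=article_id,
        trigrams=frozenset(
            (toks[i], toks[i + 1], toks[i + 2]) for i in range(len(toks) - 2)
        ),
    )


def overlap_fraction(
    candidate: ShingleSet,
    reference: ShingleSet,
    metric: Literal["containment", "jaccard"] = "containment",
) -> float:
    """Fraction of the candidate's trigrams repeated in the reference.

    Returns 0.0 for an empty candidate (nothing to repeat).
    """
    if not candidate.trigrams:
        return 0.0
    inter = len(candidate.trigrams & reference.trigrams)
    if metric == "containment":
        return inter / len(candidate.trigrams)
    if metric == "jaccard":
        union = len(candidate.trigrams | reference.trigrams)
        return inter / union
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class DedupReport:
    removed: list[tuple[str, str, float]]  # (removed_id, kept_id, overlap)
    kept_size: int

    def removed_ids(self) -> set[str]:
        return {r for r, _, _ in self.removed}


def deduplicate(
    corpus: Corpus,
    threshold: float = DEFAULT_THRESHOLD,
    metric: Literal["containment", "jaccard"] = "containment",
    use_index: bool = True,
) -> tuple[Corpus, DedupReport]:
    """Single pass in ``(published, article_id)`` order.

    An article is removed iff its overlap with some earlier-kept article
    reaches ``threshold``; attribution goes to the earliest such kept
    article, and kept articles are never re-examined.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    shingles = {a.article_id: trigrams(a.body, a.article_id) for a in corpus}
    kept_ids: list[str] = []
    removed: list[tuple[str, str, float]] = []
    # inverted index: trigram -> ordinal positions (in kept order) of kept articles
    index: dict[tuple[str, str, str], list[int]] = {}
    for article in corpus:
        cand = shingles[article.article_id]
        match: tuple[str, float] | None = None
        if cand.trigrams:
            if use_index:
                counts: dict[int, int] = {}
                for tri in cand.trigrams:
                    for pos in index.get(tri, ()):
                        counts[pos] = counts.get(pos, 0) + 1
                denom = len(cand.trigrams)
                hits = []
                for pos, inter in counts.items():
                    if metric == "containment":
                        frac = inter / denom
                    else:
                        kept_sh = shingles[kept_ids[pos]]
                        frac = inter / len(cand.trigrams | kept_sh.trigrams)
                    if frac >= threshold:
                        hits.append((pos, frac))
                if hits:
                    pos, frac = min(hits)  # earliest kept article wins
                    match = (kept_ids[pos], frac)
            else:
                for kept_id in kept_ids:
                    frac = overlap_fraction(cand, shingles[kept_id], metric)
                    if frac >= threshold:
                        match = (kept_id, frac)
                        break
        if match is not None:
            removed.append((article.article_id, match[0], match[1]))
        else:
            if use_index:
                pos = len(kept_ids)
                for tri in cand.trigrams:
                    index.setdefault(tri, []).append(pos)
            kept_ids.append(article.article_id)
    logger.info(
        "deduplicate: removed %d of %d articles at threshold %.2f",
        len(removed), len(corpus), threshold,
    )
    return corpus.subset(kept_ids), DedupReport(removed=removed, kept_size=len(kept_ids))
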