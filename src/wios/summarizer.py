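"""Extractive summarization: sentence splitting, pseudolabels, scoring, top-k.

Each retained article is reduced to at most 3 sentences per mode.  Two modes
exist: ``global`` (salience against the union of all topic lexicons) and
``topic:<id>`` (salience against one topic's lexicon).  The production-grade
neural extractive scorer is a plug-in point; the shipped reference scorer is
a deterministic lexical one:

    score = (# distinct lexicon terms in the sentence) + 1 / (1 + index)

so content terms dominate and the position bonus favors lead sentences,
consistent with the inverted-pyramid structure of news writing.  The top-k
sentences by score (ties broken by earlier index) form the summary, which is
extractive by construction: every selected sentence is a verbatim substring
of the body.

*Pseudolabels* are the sentences whose rule-engine match caused an article's
inclusion under a topic; they are the weak supervision a trainable scorer
would consume, and a recall anchor for any scorer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

from ._tokens import tokenize

TITLE_SENTENCE_INDEX = -1  # marker for title-scope rule matches

DEFAULT_K = 3


def _load_abbreviations() -> frozenset[str]:
    text = resources.files("wios.data").joinpath("abbreviations.txt").read_text("utf-8")
    abbr = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            abbr.add(line.casefold())
    return frozenset(abbr)


ABBREVIATIONS = _load_abbreviations()


@dataclass(frozen=True)
class Sentence:
    index: int
    text: str
    start: int  # char offset into body
    end: int


@dataclass
class SentenceSplit:
    """Ordered sentences of one article body, with char offsets.

    Invariant: joining ``sentences[i].text`` with the original inter-sentence
    separators reconstructs the body exactly.
    """

    article_id: str
    body: str
    sentences: list[Sentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def texts(self) -> list[str]:
        return [s.text for s in self.sentences]


_BOUNDARY = re.compile(r"[.!?]+[\"'”’)\]]*(\s+)")
_SINGLE_INITIAL = re.compile(r"^[A-Z]\.$")


def _is_guarded(token: str) -> bool:
    """True when a period-final token must not end a sentence."""
    if _SINGLE_INITIAL.match(token):
        return True
    return token.casefold() in ABBREVIATIONS


def split_sentences(body: str, article_id: str = "") -> SentenceSplit:
    """Deterministic rule-based sentence splitting.

    Boundaries are terminal punctuation runs followed by whitespace, unless
    the final token is a known abbreviation or a single capital initial.
    """
    split = SentenceSplit(article_id=article_id, body=body)
    if not body.strip():
        return split
    boundaries: list[tuple[int, int]] = []  # (sentence_end, next_start)
    for m in _BOUNDARY.finditer(body):
        end = m.start(1)  # end of sentence text, exclusive
        token_start = body.rfind(" ", 0, end)
        token = body[token_start + 1 : end]
        if _is_guarded(token.rstrip("\"'”’)]")) or _is_guarded(token):
            continue
        boundaries.append((end, m.end(1)))
    starts = [0] + [nxt for _, nxt in boundaries]
    ends = [e for e, _ in boundaries] + [len(body)]
    idx = 0
    for s, e in zip(starts, ends):
        # trim leading whitespace of the first chunk; offsets stay exact
        while s < e and body[s].isspace():
            s += 1
        text = body[s:e].rstrip()
        e = s + len(text)
        if text:
            split.sentences.append(Sentence(idx, text, s, e))
            idx += 1
    return split


# ---------------------------------------------------------------------------
# Pseudolabels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudolabelSet:
    """Sentence indices that triggered a topic inclusion for one article.

    ``title_match`` is set when the inclusion came from a title-scope rule,
    which maps to no body sentence; the title itself is the evidence.
    """

    article_id: str
    topic_id: str
    sentence_indices: tuple[int, ...]
    title_match: bool = False


def extract_pseudolabels(result, split: SentenceSplit, topic: str) -> PseudolabelSet:
    """Pseudolabels for ``topic`` from a rule-engine classification result.

    Requires the topic flag to be true (there is nothing to label otherwise).
    """
    if not result.topic_flags.get(topic, False):
        raise ValueError(
            f"article {result.article_id!r} is not flagged for topic {topic!r}"
        )
    triggers = result.trigger_sentences.get(topic, ())
    idx = sorted({i for i, _ in triggers if i != TITLE_SENTENCE_INDEX})
    title_match = any(i == TITLE_SENTENCE_INDEX for i, _ in triggers)
    valid = set(range(len(split)))
    if not set(idx) <= valid:
        raise ValueError("trigger sentence index outside the article's split")
    return PseudolabelSet(result.article_id, topic, tuple(idx), title_match)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

ScorerFn = Callable[[SentenceSplit, str, Mapping[str, Sequence[str]]], list[float]]

_SCORERS: dict[str, ScorerFn] = {}


def register_scorer(name: str, fn: ScorerFn) -> None:
    _SCORERS[name] = fn


def _lexicon_terms(lexicon: Sequence[str]) -> list[tuple[str, ...]]:
    return [tuple(tokenize(term)) for term in lexicon]


def _contains(tokens: list[str], term: tuple[str, ...]) -> bool:
    n = len(term)
    if n == 0:
        return False
    if n == 1:
        return term[0] in tokens
    return any(tuple(tokens[i : i + n]) == term for i in range(len(tokens) - n + 1))


def lexical_scorer(
    split: SentenceSplit, mode: str, lexicons: Mapping[str, Sequence[str]]
) -> list[float]:
    """Reference scorer: distinct-lexicon-term count plus 1/(1+index)."""
    if mode == "global":
        terms = []
        seen: set[tuple[str, ...]] = set()
        for lex in lexicons.values():
            for t in _lexicon_terms(lex):
                if t not in seen:
                    seen.add(t)
                    terms.append(t)
    elif mode.startswith("topic:"):
        topic = mode.split(":", 1)[1]
        if topic not in lexicons:
            raise KeyError(f"no lexicon for topic {topic!r}")
        terms = _lexicon_terms(lexicons[topic])
    else:
        raise ValueError(f"unknown summary mode {mode!r}")
    scores = []
    for sent in split.sentences:
        toks = tokenize(sent.text)
        hits = sum(1 for t in terms if _contains(toks, t))
        scores.append(hits + 1.0 / (1.0 + sent.index))
    return scores


register_scorer("lexical", lexical_scorer)


def score_sentences(
    split: SentenceSplit,
    mode: str,
    lexicons: Mapping[str, Sequence[str]],
    scorer: str | ScorerFn = "lexical",
) -> list[float]:
    """Per-sentence scores under the named (or callable) scorer."""
    if callable(scorer):
        fn = scorer
    else:
        try:
            fn = _SCORERS[scorer]
        except KeyError:
            raise KeyError(
                f"unknown scorer {scorer!r}; registered: {sorted(_SCORERS)}"
            ) from None
    scores = fn(split, mode, lexicons)
    if len(scores) != len(split):
        raise ValueError("scorer returned wrong number of scores")
    return list(scores)


# ---------------------------------------------------------------------------
# Top-k selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Summary:
    """Top-k extractive summary of one article in one mode.

    ``selected`` holds (sentence index, score) pairs in rank order; scores
    are non-increasing and ties rank the earlier sentence first.
    """

    article_id: str
    mode: str
    selected: tuple[tuple[int, float], ...]

    def sentences(self, split: SentenceSplit) -> list[str]:
        return [split.sentences[i].text for i, _ in self.selected]

    def text(self, split: SentenceSplit, title: str | None = None) -> str:
        """Summary text; the title, when given, is prepended for review."""
        parts = [] if title is None else [title]
        parts.extend(self.sentences(split))
        return " ".join(parts)


def summarize(
    split: SentenceSplit, scores: Sequence[float], k: int = DEFAULT_K, mode: str = "global"
) -> Summary:
    """Top-``k`` sentences by score; ties broken by earlier index."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(scores) != len(split):
        raise ValueError("scores do not match the sentence split")
    ranked = sorted(
        ((s.index, float(sc)) for s, sc in zip(split.sentences, scores)),
        key=lambda pair: (-pair[1], pair[0]),
    )
    return Summary(split.article_id, mode, tuple(ranked[:k]))
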