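"""Rule-based topic classification.

Each topic carries an ordered list of criteria.  A criterion has a *scope*
(``title``, ``body`` or ``sentence``), a *polarity* (``include`` or
``exclude``) and a Boolean *pattern* over three atom kinds:

``word``
    a single normalized token, matched by equality (``"strike"``);
``phrase``
    a contiguous normalized token sequence
    (``"personal protective equipment"``);
``value``
    a numeric-proximity predicate: a number satisfying a comparison occurs
    within ``k`` tokens of a term (``NUM >= 100 WITHIN 5 OF "nurses"``).

Patterns combine atoms with ``AND``, ``OR``, ``NOT`` and parentheses.  An
article is flagged for a topic iff at least one include criterion matches
and no exclude criterion matches (exclusion veto — the precision-oriented
reading).  Sentence-scope matches record which sentences fired; those are
the pseudolabels the summarizer consumes.

Rule files are YAML::

    topics:
      - topic: vaccination
        criteria:
          - {scope: title, polarity: include, pattern: '"vaccine" OR "vaccination"'}
          - {scope: sentence, polarity: exclude, pattern: '"animal"'}

The pattern grammar (EBNF)::

    expr    = term , { "OR" , term } ;
    term    = factor , { "AND" , factor } ;
    factor  = "NOT" , factor | "(" , expr , ")" | atom ;
    atom    = STRING                        (* word if 1 token else phrase *)
            | "NUM" , CMP , NUMBER ,
              "WITHIN" , NUMBER , "OF" , STRING ;
    CMP     = ">=" | "<=" | ">" | "<" | "=" | "==" ;
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from ._tokens import numeric_value, tokenize
from .corpus_model import Corpus, NewsArticle
from .summarizer import TITLE_SENTENCE_INDEX, SentenceSplit, split_sentences

logger = logging.getLogger("wios")

SCOPES = ("title", "body", "sentence")
POLARITIES = ("include", "exclude")


class RuleSyntaxError(ValueError):
    """Pattern text failed to parse; carries a position for diagnostics."""

    def __init__(self, message: str, pos: int, text: str):
        self.pos = pos
        self.text = text
        super().__init__(f"{message} at column {pos + 1} in pattern {text!r}")


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WordAtom:
    token: str

    def matches(self, tokens: Sequence[str]) -> bool:
        return self.token in tokens

    def unparse(self) -> str:
        return f'"{self.token}"'


@dataclass(frozen=True)
class PhraseAtom:
    tokens: tuple[str, ...]

    def matches(self, tokens: Sequence[str]) -> bool:
        n = len(self.tokens)
        return any(
            tuple(tokens[i : i + n]) == self.tokens
            for i in range(len(tokens) - n + 1)
        )

    def unparse(self) -> str:
        return '"' + " ".join(self.tokens) + '"'


_CMPS = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    "==": lambda a, b: a == b,
    "=": lambda a, b: a == b,
}


@dataclass(frozen=True)
class ValueAtom:
    """A number satisfying ``cmp threshold`` within ``window`` tokens of ``term``."""

    cmp: str
    threshold: float
    window: int
    term: tuple[str, ...]

    def matches(self, tokens: Sequence[str]) -> bool:
        op = _CMPS[self.cmp]
        n = len(self.term)
        term_positions = [
            i
            for i in range(len(tokens) - n + 1)
            if tuple(tokens[i : i + n]) == self.term
        ]
        if not term_positions:
            return False
        for j, tok in enumerate(tokens):
            val = numeric_value(tok)
            if val is None or not op(val, self.threshold):
                continue
            for i in term_positions:
                # distance between the number and the nearest token of the term
                dist = max(i - j, j - (i + n - 1), 0)
                if dist <= self.window:
                    return True
        return False

    def unparse(self) -> str:
        thr = int(self.threshold) if self.threshold == int(self.threshold) else self.threshold
        return f'NUM {self.cmp} {thr} WITHIN {self.window} OF "{" ".join(self.term)}"'


@dataclass(frozen=True)
class Not:
    child: "Expr"

    def matches(self, tokens: Sequence[str]) -> bool:
        return not self.child.matches(tokens)

    def unparse(self) -> str:
        return f"NOT {self.child.unparse()}"


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def matches(self, tokens: Sequence[str]) -> bool:
        return all(c.matches(tokens) for c in self.children)

    def unparse(self) -> str:
        return "(" + " AND ".join(c.unparse() for c in self.children) + ")"


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def matches(self, tokens: Sequence[str]) -> bool:
        return any(c.matches(tokens) for c in self.children)

    def unparse(self) -> str:
        return "(" + " OR ".join(c.unparse() for c in self.children) + ")"


Expr = WordAtom | PhraseAtom | ValueAtom | Not | And | Or


# ---------------------------------------------------------------------------
# Pattern parser (recursive descent)
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> RuleSyntaxError:
        return RuleSyntaxError(msg, self.pos, self.text)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek_word(self) -> str:
        self.skip_ws()
        j = self.pos
        while j < len(self.text) and (self.text[j].isalnum() or self.text[j] in "_"):
            j += 1
        return self.text[self.pos : j].upper()

    def eat_word(self, word: str) -> bool:
        if self.peek_word() == word:
            self.skip_ws()
            self.pos += len(word)
            return True
        return False

    def parse(self) -> Expr:
        expr = self.parse_or()
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("unexpected trailing input")
        return expr

    def parse_or(self) -> Expr:
        children = [self.parse_and()]
        while self.eat_word("OR"):
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> Expr:
        children = [self.parse_factor()]
        while self.eat_word("AND"):
            children.append(self.parse_factor())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_factor(self) -> Expr:
        self.skip_ws()
        if self.eat_word("NOT"):
            return Not(self.parse_factor())
        if self.pos < len(self.text) and self.text[self.pos] == "(":
            open_pos = self.pos
            self.pos += 1
            expr = self.parse_or()
            self.skip_ws()
            if self.pos >= len(self.text) or self.text[self.pos] != ")":
                self.pos = open_pos
                raise self.error("unbalanced parenthesis")
            self.pos += 1
            return expr
        if self.peek_word() == "NUM":
            return self.parse_value_atom()
        return self.parse_string_atom()

    def parse_string_atom(self) -> Expr:
        self.skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] not in "\"'":
            raise self.error("expected a quoted string, NUM, NOT or '('")
        quote = self.text[self.pos]
        end = self.text.find(quote, self.pos + 1)
        if end < 0:
            raise self.error("unterminated string")
        raw = self.text[self.pos + 1 : end]
        self.pos = end + 1
        toks = tuple(tokenize(raw))
        if not toks:
            raise self.error("empty pattern string")
        return WordAtom(toks[0]) if len(toks) == 1 else PhraseAtom(toks)

    def parse_number(self) -> float:
        self.skip_ws()
        j = self.pos
        while j < len(self.text) and (self.text[j].isdigit() or self.text[j] in ".,"):
            j += 1
        val = numeric_value(self.text[self.pos : j])
        if val is None:
            raise self.error("expected a number")
        self.pos = j
        return val

    def parse_value_atom(self) -> ValueAtom:
        assert self.eat_word("NUM")
        self.skip_ws()
        for op in (">=", "<=", "==", ">", "<", "="):
            if self.text.startswith(op, self.pos):
                self.pos += len(op)
                cmp = "==" if op == "=" else op
                break
        else:
            raise self.error("expected a comparison operator after NUM")
        threshold = self.parse_number()
        if not self.eat_word("WITHIN"):
            raise self.error("expected WITHIN")
        window = int(self.parse_number())
        if not self.eat_word("OF"):
            raise self.error("expected OF")
        atom = self.parse_string_atom()
        term = (atom.token,) if isinstance(atom, WordAtom) else atom.tokens
        return ValueAtom(cmp=cmp, threshold=threshold, window=window, term=term)


def parse_pattern(text: str) -> Expr:
    """Parse a pattern string into an expression tree."""
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Criteria and rule sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Criterion:
    scope: str
    polarity: str
    pattern: Expr

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}; expected one of {SCOPES}")
        if self.polarity not in POLARITIES:
            raise ValueError(
                f"unknown polarity {self.polarity!r}; expected one of {POLARITIES}"
            )

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "polarity": self.polarity,
            "pattern": self.pattern.unparse(),
        }


@dataclass(frozen=True)
class RuleSet:
    topic_id: str
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        if not any(c.polarity == "include" for c in self.criteria):
            raise ValueError(
                f"topic {self.topic_id!r} has no include criterion"
            )

    def to_dict(self) -> dict:
        return {
            "topic": self.topic_id,
            "criteria": [c.to_dict() for c in self.criteria],
        }


def parse_ruleset(config: str | Path | Mapping) -> list[RuleSet]:
    """Parse a YAML/JSON rule file (or an already-loaded mapping)."""
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(config)
    if not isinstance(data, dict) or "topics" not in data:
        raise ValueError("rule file must be a mapping with a 'topics' list")
    rulesets = []
    for entry in data["topics"]:
        criteria = []
        for crit in entry.get("criteria", []):
            criteria.append(
                Criterion(
                    scope=str(crit.get("scope", "body")),
                    polarity=str(crit.get("polarity", "include")),
                    pattern=parse_pattern(str(crit["pattern"])),
                )
            )
        rulesets.append(RuleSet(topic_id=str(entry["topic"]), criteria=tuple(criteria)))
    return rulesets


def serialize_ruleset(rulesets: Iterable[RuleSet]) -> dict:
    """Inverse of :func:`parse_ruleset`: re-parsing the result round-trips."""
    return {"topics": [rs.to_dict() for rs in rulesets]}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_criterion(
    article: NewsArticle,
    criterion: Criterion,
    split: SentenceSplit | None = None,
) -> tuple[bool, list[int]]:
    """Evaluate one criterion against one article.

    Returns ``(matched, spans)`` where spans are matched sentence indices
    (``TITLE_SENTENCE_INDEX`` for a title-scope match).  Sentence scope is
    true iff at least one sentence individually satisfies the expression;
    title/body scope evaluates the expression over that section's full token
    stream, and spans then list the sentences that individually satisfy it
    (possibly none, when the match straddles sentences).
    """
    if criterion.scope == "title":
        matched = criterion.pattern.matches(tokenize(article.title))
        return matched, ([TITLE_SENTENCE_INDEX] if matched else [])
    if split is None:
        split = split_sentences(article.body, article.article_id)
    per_sentence = [
        s.index for s in split.sentences if criterion.pattern.matches(tokenize(s.text))
    ]
    if criterion.scope == "sentence":
        return bool(per_sentence), per_sentence
    # body scope
    matched = criterion.pattern.matches(tokenize(article.body))
    return matched, (per_sentence if matched else [])


@dataclass
class ClassificationResult:
    """Per-article topic flags plus the trigger sentences behind each flag."""

    article_id: str
    topic_flags: dict[str, bool] = field(default_factory=dict)
    trigger_sentences: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def flagged_topics(self) -> list[str]:
        return [t for t, f in self.topic_flags.items() if f]


def classify_article(
    article: NewsArticle,
    rulesets: Sequence[RuleSet],
    split: SentenceSplit | None = None,
    require_all_includes: bool = False,
) -> ClassificationResult:
    """Flag ``article`` for each topic; any exclude match vetoes the topic.

    Include criteria combine by OR by default (``require_all_includes``
    switches to joint satisfaction).  Trigger sentences accumulate from
    include matches; a title-scope match contributes ``(-1, title)``.
    """
    if split is None:
        split = split_sentences(article.body, article.article_id)
    result = ClassificationResult(article_id=article.article_id)
    for rs in rulesets:
        include_hits = 0
        n_includes = 0
        excluded = False
        spans: list[int] = []
        for crit in rs.criteria:
            matched, crit_spans = evaluate_criterion(article, crit, split)
            if crit.polarity == "exclude":
                if matched:
                    excluded = True
            else:
                n_includes += 1
                if matched:
                    include_hits += 1
                    spans.extend(crit_spans)
        flag = (
            not excluded
            and include_hits > 0
            and (not require_all_includes or include_hits == n_includes)
        )
        result.topic_flags[rs.topic_id] = flag
        if flag:
            uniq = sorted(set(spans))
            triggers = [
                (i, article.title if i == TITLE_SENTENCE_INDEX else split.sentences[i].text)
                for i in uniq
            ]
            if not triggers:
                # body-scope match straddling sentences: the title stands in
                # as reviewable evidence so triggers are never empty
                triggers = [(TITLE_SENTENCE_INDEX, article.title)]
            result.trigger_sentences[rs.topic_id] = triggers
    return result


def classify_corpus(
    corpus: Corpus,
    rulesets: Sequence[RuleSet],
    require_all_includes: bool = False,
) -> tuple[list[ClassificationResult], Corpus]:
    """Classify every article; retain those with at least one true flag."""
    results = []
    retained_ids = []
    per_topic: dict[str, int] = {rs.topic_id: 0 for rs in rulesets}
    for article in corpus:
        res = classify_article(article, rulesets, require_all_includes=require_all_includes)
        results.append(res)
        flagged = res.flagged_topics()
        for t in flagged:
            per_topic[t] += 1
        if flagged:
            retained_ids.append(article.article_id)
    logger.info(
        "classify_corpus: retained %d/%d articles; per-topic %s",
        len(retained_ids), len(corpus), per_topic,
    )
    return results, corpus.subset(retained_ids)


# ---------------------------------------------------------------------------
# Validation sampling
# ---------------------------------------------------------------------------


def sample_flagged(
    results: Sequence[ClassificationResult],
    topic: str,
    n: int = 50,
    seed: int = 0,
) -> list[str]:
    """Uniform sample without replacement of articles flagged for ``topic``.

    Supports the human relevance check: annotators review the sampled
    articles and judge whether each is truly on-topic.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    known = {t for r in results for t in r.topic_flags}
    if topic not in known:
        raise ValueError(f"unknown topic {topic!r}; known: {sorted(known)}")
    flagged = [r.article_id for r in results if r.topic_flags.get(topic, False)]
    if len(flagged) <= n:
        if len(flagged) < n:
            warnings.warn(
                f"only {len(flagged)} articles flagged for {topic!r}; "
                f"returning all (requested {n})",
                stacklevel=2,
            )
        return list(flagged)
    return random.Random(seed).sample(flagged, n)


@dataclass(frozen=True)
class RelevanceRate:
    rate: float  # percentage
    n_annotated: int
    n_relevant: int


def relevance_rate(annotations: Mapping[str, str]) -> RelevanceRate:
    """Percent of annotated articles judged relevant, with the sample size."""
    if not annotations:
        raise ValueError("annotations must be non-empty")
    bad = {v for v in annotations.values()} - {"relevant", "irrelevant"}
    if bad:
        raise ValueError(f"annotation values must be relevant/irrelevant, got {bad}")
    n = len(annotations)
    rel = sum(1 for v in annotations.values() if v == "relevant")
    return RelevanceRate(rate=100.0 * rel / n, n_annotated=n, n_relevant=rel)
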