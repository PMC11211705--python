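"""Rule parsing, evaluation semantics, classification and sampling."""

import random

import pytest

from wios._tokens import numeric_value, tokenize
from wios.rule_engine import (
    And,
    Criterion,
    Not,
    Or,
    PhraseAtom,
    RuleSet,
    RuleSyntaxError,
    ValueAtom,
    WordAtom,
    classify_article,
    classify_corpus,
    evaluate_criterion,
    parse_pattern,
    parse_ruleset,
    relevance_rate,
    sample_flagged,
    serialize_ruleset,
)
from wios.summarizer import TITLE_SENTENCE_INDEX, split_sentences
from .conftest import make_article


# ---------------------------------------------------------------------------
# Independent brute-force evaluator (the oracle)
# ---------------------------------------------------------------------------

def naive_eval(expr, tokens) -> bool:
    """Direct enumeration semantics, written independently of the engine."""
    if isinstance(expr, WordAtom):
        return any(t == expr.token for t in tokens)
    if isinstance(expr, PhraseAtom):
        n = len(expr.tokens)
        for i in range(len(tokens)):
            if tuple(tokens[i : i + n]) == expr.tokens:
                return True
        return False
    if isinstance(expr, ValueAtom):
        ops = {
            ">=": lambda a, b: a >= b, "<=": lambda a, b: a <= b,
            ">": lambda a, b: a > b, "<": lambda a, b: a < b,
            "==": lambda a, b: a == b,
        }
        n = len(expr.term)
        for j, tok in enumerate(tokens):
            v = numeric_value(tok)
            if v is None or not ops[expr.cmp](v, expr.threshold):
                continue
            for i in range(len(tokens) - n + 1):
                if tuple(tokens[i : i + n]) != expr.term:
                    continue
                span = range(i, i + n)
                if min(abs(j - s) for s in span) <= expr.window:
                    return True
        return False
    if isinstance(expr, Not):
        return not naive_eval(expr.child, tokens)
    if isinstance(expr, And):
        return all(naive_eval(c, tokens) for c in expr.children)
    if isinstance(expr, Or):
        return any(naive_eval(c, tokens) for c in expr.children)
    raise TypeError(expr)


class TestParser:
    def test_single_word_rule(self):
        rulesets = parse_ruleset(
            {"topics": [{"topic": "vaccination",
                         "criteria": [{"scope": "title", "polarity": "include",
                                       "pattern": '"vaccine"'}]}]}
        )
        assert len(rulesets) == 1
        assert rulesets[0].criteria[0].pattern == WordAtom("vaccine")

    def test_unbalanced_parenthesis_reports_location(self):
        with pytest.raises(RuleSyntaxError, match="column"):
            parse_pattern('(("vaccine" OR "jab")')

    def test_nested_tree_structure(self):
        expr = parse_pattern('(("vaccine" OR "vaccination") AND NOT "animal")')
        assert expr == And(
            (Or((WordAtom("vaccine"), WordAtom("vaccination"))),
             Not(WordAtom("animal")))
        )

    def test_phrase_vs_word_atoms(self):
        assert parse_pattern('"personal protective equipment"') == PhraseAtom(
            ("personal", "protective", "equipment")
        )

    def test_value_atom_syntax(self):
        expr = parse_pattern('NUM >= 100 WITHIN 5 OF "nurses"')
        assert expr == ValueAtom(cmp=">=", threshold=100, window=5, term=("nurses",))

    def test_serialize_round_trips(self, default_rulesets):
        again = parse_ruleset(serialize_ruleset(default_rulesets))
        assert [rs.to_dict() for rs in again] == [
            rs.to_dict() for rs in default_rulesets
        ]

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            Criterion(scope="footer", polarity="include", pattern=WordAtom("x"))

    def test_ruleset_requires_an_include(self):
        with pytest.raises(ValueError, match="no include"):
            RuleSet("t", (Criterion("body", "exclude", WordAtom("x")),))


class TestEvaluate:
    def test_title_scope(self):
        art = make_article("x", title="Nurses strike over pay", body="Calm body.")
        crit = Criterion("title", "include", parse_pattern('"strike"'))
        matched, spans = evaluate_criterion(art, crit)
        assert matched and spans == [TITLE_SENTENCE_INDEX]

    def test_phrase_must_not_straddle_sentences(self):
        art = make_article(
            "x", body="They lacked personal protective. Equipment arrived late."
        )
        crit = Criterion(
            "sentence", "include", parse_pattern('"personal protective equipment"')
        )
        matched, spans = evaluate_criterion(art, crit)
        assert not matched and spans == []

    def test_value_atom_with_separated_number(self):
        art = make_article("x", body="About 3,500,000 nurses joined nationwide.")
        crit = Criterion(
            "sentence", "include", parse_pattern('NUM >= 100 WITHIN 5 OF "nurses"')
        )
        matched, spans = evaluate_criterion(art, crit)
        assert matched and spans == [0]

    def test_sentence_match_implies_body_match(self, synthetic_corpus, default_rulesets):
        corpus, _ = synthetic_corpus
        for article in corpus.articles[:40]:
            for rs in default_rulesets:
                for crit in rs.criteria:
                    sent = Criterion("sentence", crit.polarity, crit.pattern)
                    body = Criterion("body", crit.polarity, crit.pattern)
                    m_sent, _ = evaluate_criterion(article, sent)
                    m_body, _ = evaluate_criterion(article, body)
                    if m_sent:
                        assert m_body

    def test_agrees_with_naive_evaluator(self, synthetic_corpus, default_rulesets):
        corpus, _ = synthetic_corpus
        for article in corpus.articles[:60]:
            body_toks = tokenize(article.body)
            title_toks = tokenize(article.title)
            split = split_sentences(article.body, article.article_id)
            for rs in default_rulesets:
                for crit in rs.criteria:
                    got, _ = evaluate_criterion(article, crit, split)
                    if crit.scope == "title":
                        want = naive_eval(crit.pattern, title_toks)
                    elif crit.scope == "body":
                        want = naive_eval(crit.pattern, body_toks)
                    else:
                        want = any(
                            naive_eval(crit.pattern, tokenize(s.text))
                            for s in split.sentences
                        )
                    assert got == want


class TestClassify:
    def test_exclude_vetoes_include(self):
        rs = [
            RuleSet(
                "vax",
                (
                    Criterion("body", "include", parse_pattern('"vaccine"')),
                    Criterion("body", "exclude", parse_pattern('"animal"')),
                ),
            )
        ]
        art = make_article("x", body="An animal vaccine trial began.")
        assert classify_article(art, rs).topic_flags["vax"] is False

    def test_no_match_means_no_flags_no_triggers(self, default_rulesets):
        art = make_article("x", body="Completely unrelated prose.")
        res = classify_article(art, default_rulesets)
        assert not any(res.topic_flags.values())
        assert res.trigger_sentences == {}

    def test_triggers_nonempty_for_every_true_flag(self, synthetic_corpus, default_rulesets):
        corpus, _ = synthetic_corpus
        for article in corpus.articles[:80]:
            res = classify_article(article, default_rulesets)
            for topic, flag in res.topic_flags.items():
                if flag:
                    assert res.trigger_sentences[topic]

    def test_planted_labels_recovered_exactly(self, clean_corpus, default_rulesets):
        corpus, truth = clean_corpus
        results, retained = classify_corpus(corpus, default_rulesets)
        assert len(retained) == len(corpus)
        for res in results:
            assert set(res.flagged_topics()) == set(
                truth.by_article[res.article_id].topics
            )

    def test_adding_excludes_never_flips_false_to_true(self, synthetic_corpus, default_rulesets):
        corpus, _ = synthetic_corpus
        rnd = random.Random(3)
        vocab = ["outbreak", "strike", "vaccination", "burnout", "examinations",
                 "rainfall", "quarterly"]
        for article in corpus.articles[:30]:
            base = classify_article(article, default_rulesets)
            extended = [
                RuleSet(
                    rs.topic_id,
                    rs.criteria
                    + (
                        Criterion(
                            "body", "exclude",
                            parse_pattern(f'"{rnd.choice(vocab)}"'),
                        ),
                    ),
                )
                for rs in default_rulesets
            ]
            harder = classify_article(article, extended)
            for topic in base.topic_flags:
                if not base.topic_flags[topic]:
                    assert not harder.topic_flags[topic]

    def test_classification_is_idempotent(self, synthetic_corpus, default_rulesets):
        corpus, _ = synthetic_corpus
        _, retained = classify_corpus(corpus, default_rulesets)
        _, retained2 = classify_corpus(retained, default_rulesets)
        assert len(retained2) == len(retained)

    def test_all_background_corpus_retains_nothing(self, default_rulesets):
        from wios.synthetic_data import GenerationSpec, generate_corpus

        corpus, _ = generate_corpus(
            GenerationSpec(n_articles=60, seed=9, background_fraction=1.0,
                           duplicate_rate=0.0)
        )
        _, retained = classify_corpus(corpus, default_rulesets)
        assert len(retained) == 0


class TestSampling:
    def _results(self, n_flagged: int):
        out = []
        for i in range(n_flagged):
            out.append(
                classify_article(
                    make_article(f"f{i:03d}", body="A strike happened."),
                    parse_ruleset(
                        {"topics": [{"topic": "industrial_action",
                                     "criteria": [{"scope": "body",
                                                   "polarity": "include",
                                                   "pattern": '"strike"'}]}]}
                    ),
                )
            )
        return out

    def test_fewer_flagged_than_requested_warns_and_returns_all(self):
        results = self._results(30)
        with pytest.warns(UserWarning, match="only 30"):
            sample = sample_flagged(results, "industrial_action", n=50, seed=1)
        assert len(sample) == 30

    def test_same_seed_same_sample(self):
        results = self._results(80)
        s1 = sample_flagged(results, "industrial_action", n=50, seed=42)
        s2 = sample_flagged(results, "industrial_action", n=50, seed=42)
        assert s1 == s2
        assert len(set(s1)) == 50

    def test_unknown_topic_rejected(self):
        with pytest.raises(ValueError, match="unknown topic"):
            sample_flagged(self._results(5), "nope", seed=0)

    def test_sampling_is_uniform(self):
        """Selection frequency of each flagged article is n/N within 3 SE."""
        results = self._results(40)
        n, N, reps = 10, 40, 3000
        counts = {f"f{i:03d}": 0 for i in range(N)}
        for rep in range(reps):
            for aid in sample_flagged(results, "industrial_action", n=n, seed=rep):
                counts[aid] += 1
        p = n / N
        se = (p * (1 - p) / reps) ** 0.5
        for c in counts.values():
            assert abs(c / reps - p) < 3.5 * se


class TestRelevanceRate:
    @pytest.mark.parametrize(
        "relevant,total,expected", [(45, 50, 90.0), (35, 50, 70.0), (0, 10, 0.0)]
    )
    def test_percentage_with_sample_size(self, relevant, total, expected):
        ann = {
            f"a{i}": ("relevant" if i < relevant else "irrelevant")
            for i in range(total)
        }
        rr = relevance_rate(ann)
        assert rr.rate == pytest.approx(expected)
        assert rr.n_annotated == total

    def test_empty_annotations_rejected(self):
        with pytest.raises(ValueError):
            relevance_rate({})
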