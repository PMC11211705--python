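"""End-to-end orchestration with a reproducibility manifest.

Stages run in a fixed order — generate/ingest → classify → summarize →
dedup → geotag → code → synthesize — with each stage's outputs written to
disk before the next begins, so intermediate products can be inspected (the
workflow is supervised: humans review samples of flagged articles and the
coded records).  The run manifest records per-stage record/word/page counts
(the reduction funnel), parameter and seed echoes, and timestamps; identical
config and seeds reproduce identical stage outputs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import aggregate as agg
from . import corpus_model as cm
from . import dedup as dd
from . import geo_time as gt
from . import rule_engine as re_
from . import summarizer as sm
from . import synthetic_data as syn

logger = logging.getLogger("wios")

#: which topic's record carries an article's "number affected" figure
TOPIC_BY_AFFECTED_KIND = {
    "vaccinated": "vaccination",
    "striking": "industrial_action",
    "infected": "infections_deaths",
    "dead": "infections_deaths",
}

STAGES = ("ingest", "classify", "summarize", "dedup", "geotag", "code", "synthesize")


@dataclass
class RunConfig:
    out_dir: str | Path = "wios_run"
    # input: either an existing corpus file or a synthetic generation spec
    corpus_path: str | Path | None = None
    generation: syn.GenerationSpec | None = None
    rules_path: str | Path | None = None  # default: shipped topic rules
    scorer: str = "lexical"
    k: int = 3
    dedup_threshold: float = 0.30
    dedup_metric: str = "containment"
    gazetteer_path: str | Path | None = None
    codebook_path: str | Path | None = None
    annotations_path: str | Path | None = None  # article_id,affected_kind,affected_count
    manual_codes_path: str | Path | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        gen = data.pop("generation", None)
        cfg = cls(**data)
        if gen is not None:
            if "date_window" in gen:
                from datetime import date

                lo, hi = gen["date_window"]
                gen["date_window"] = (
                    date.fromisoformat(str(lo)),
                    date.fromisoformat(str(hi)),
                )
            topics = [syn.TopicSpec(**t) for t in gen.pop("topics", [])]
            cfg.generation = syn.GenerationSpec(**gen)
            if topics:
                cfg.generation.topics = topics
        return cfg


@dataclass
class StageStats:
    articles: int
    words: int
    pages: int
    seconds: float


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    stages: dict[str, StageStats] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
            "extra": self.extra,
            "failed_stage": self.failed_stage,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stats(corpus: cm.Corpus, t0: float) -> StageStats:
    s = cm.corpus_stats(corpus)
    return StageStats(s["articles"], s["words"], s["pages"], round(time.time() - t0, 3))


def _read_annotations(path: str | Path) -> dict[str, tuple[str, int]]:
    out = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            if row.get("affected_count", "") == "":
                continue
            out[row["article_id"]] = (row["affected_kind"], int(row["affected_count"]))
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage; halts on stage failure with the manifest so far
    written and the failing stage named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "scorer": config.scorer,
            "k": config.k,
            "dedup_threshold": config.dedup_threshold,
            "dedup_metric": config.dedup_metric,
            "seed": config.seed,
            "generation_seed": config.generation.seed if config.generation else None,
        }
    )
    manifest_path = out / "manifest.json"
    stage = "ingest"
    try:
        # -- ingest / generate ------------------------------------------------
        t0 = time.time()
        annotations: dict[str, tuple[str, int]] = {}
        if config.generation is not None:
            corpus, truth = syn.generate_corpus(config.generation)
            truth.write(out / "truth.jsonl")
            with open(out / "annotations.csv", "w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["article_id", "affected_kind", "affected_count"])
                for aid in sorted(truth.by_article):
                    t = truth.by_article[aid]
                    if t.affected_count is not None:
                        w.writerow([aid, t.affected_kind, t.affected_count])
            annotations = {
                aid: (t.affected_kind, t.affected_count)
                for aid, t in truth.by_article.items()
                if t.affected_count is not None
            }
        elif config.corpus_path is not None:
            corpus = cm.read_corpus(config.corpus_path)
        else:
            raise ValueError("RunConfig needs corpus_path or generation")
        if config.annotations_path is not None:
            annotations = _read_annotations(config.annotations_path)
        cm.write_corpus(corpus, out / "corpus.jsonl")
        manifest.stages["ingest"] = _stats(corpus, t0)

        # -- classify ---------------------------------------------------------
        stage = "classify"
        t0 = time.time()
        if config.rules_path is not None:
            rulesets = re_.parse_ruleset(config.rules_path)
        else:
            rulesets = re_.parse_ruleset(syn.default_rule_config())
        results, retained = re_.classify_corpus(corpus, rulesets)
        res_by_id = {r.article_id: r for r in results}
        with open(out / "flags.jsonl", "w", encoding="utf-8") as fh:
            for r in results:
                fh.write(
                    json.dumps(
                        {
                            "article_id": r.article_id,
                            "topic_flags": r.topic_flags,
                            "trigger_sentences": r.trigger_sentences,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        cm.write_corpus(retained, out / "retained.jsonl")
        manifest.stages["classify"] = _stats(retained, t0)

        # -- summarize --------------------------------------------------------
        stage = "summarize"
        t0 = time.time()
        lexicons = {rs.topic_id: _ruleset_lexicon(rs) for rs in rulesets}
        splits: dict[str, sm.SentenceSplit] = {}
        summaries: dict[tuple[str, str], sm.Summary] = {}
        with open(out / "summaries.jsonl", "w", encoding="utf-8") as fh:
            for article in retained:
                split = sm.split_sentences(article.body, article.article_id)
                splits[article.article_id] = split
                modes = ["global"] + [
                    f"topic:{t}" for t in res_by_id[article.article_id].flagged_topics()
                ]
                for mode in modes:
                    scores = sm.score_sentences(split, mode, lexicons, config.scorer)
                    summary = sm.summarize(split, scores, k=config.k, mode=mode)
                    summaries[(article.article_id, mode)] = summary
                    fh.write(
                        json.dumps(
                            {
                                "article_id": article.article_id,
                                "mode": mode,
                                "selected": list(summary.selected),
                                "text": summary.text(split, title=article.title),
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
        summary_words = 0
        for article in retained:
            summary = summaries[(article.article_id, "global")]
            summary_words += cm.word_count(
                summary.text(splits[article.article_id], title=article.title)
            )
        manifest.stages["summarize"] = StageStats(
            len(retained), summary_words, cm.standardized_pages(summary_words),
            round(time.time() - t0, 3),
        )
        manifest.extra["summary_words"] = summary_words

        # -- dedup ------------------------------------------------------------
        stage = "dedup"
        t0 = time.time()
        deduped, report = dd.deduplicate(
            retained, threshold=config.dedup_threshold, metric=config.dedup_metric
        )
        cm.write_corpus(deduped, out / "deduped.jsonl")
        with open(out / "dedup_report.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"removed": report.removed, "kept_size": report.kept_size},
                fh, indent=2, sort_keys=True,
            )
        manifest.stages["dedup"] = _stats(deduped, t0)

        # -- geotag -----------------------------------------------------------
        stage = "geotag"
        t0 = time.time()
        gazetteer = (
            gt.Gazetteer.from_csv(config.gazetteer_path)
            if config.gazetteer_path
            else gt.Gazetteer.default()
        )
        resolutions: dict[str, gt.GeoResolution] = {}
        with open(out / "geotagged.jsonl", "w", encoding="utf-8") as fh:
            for article in deduped:
                res = gt.resolve_country(article, gazetteer)
                resolutions[article.article_id] = res
                fh.write(
                    json.dumps(
                        {
                            "article_id": article.article_id,
                            "resolved": res.resolved,
                            "original_tags": list(res.original_tags),
                            "month": gt.month_bucket(article.published),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        manifest.stages["geotag"] = _stats(deduped, t0)

        # -- code -------------------------------------------------------------
        stage = "code"
        t0 = time.time()
        codebooks = (
            agg.load_codebooks(config.codebook_path)
            if config.codebook_path
            else agg.default_codebooks()
        )
        manual = (
            agg.read_manual_codes(config.manual_codes_path)
            if config.manual_codes_path
            else None
        )
        items = []
        for article in deduped:
            res = res_by_id[article.article_id]
            geo = resolutions[article.article_id]
            month = gt.month_bucket(article.published)
            for topic in res.flagged_topics():
                kind_count = annotations.get(article.article_id)
                carries = (
                    kind_count is not None
                    and TOPIC_BY_AFFECTED_KIND.get(kind_count[0]) == topic
                )
                items.append(
                    agg.SummaryItem(
                        article_id=article.article_id,
                        topic_id=topic,
                        text=summaries[(article.article_id, f"topic:{topic}")].text(
                            splits[article.article_id], title=article.title
                        ),
                        country=geo.resolved,
                        month=month,
                        affected_count=kind_count[1] if carries else None,
                        affected_kind=kind_count[0] if carries else None,
                    )
                )
        coded: dict[str, list[agg.CodedRecord]] = {}
        for theme, book in codebooks.items():
            coded[theme] = agg.apply_codebook(items, book, manual_codes=manual)
        with open(out / "coded.jsonl", "w", encoding="utf-8") as fh:
            for theme, records in coded.items():
                for rec in records:
                    if not rec.codes and theme != "area_of_impact":
                        continue
                    fh.write(
                        json.dumps(
                            {"theme": theme, **dataclasses.asdict(rec)}, sort_keys=True
                        )
                        + "\n"
                    )
        manifest.stages["code"] = _stats(deduped, t0)

        # -- synthesize -------------------------------------------------------
        stage = "synthesize"
        t0 = time.time()
        window = corpus.date_window
        area = coded["area_of_impact"]
        area_book = codebooks["area_of_impact"]
        tables = []
        for rs in rulesets:
            table = agg.subevent_distribution(area, area_book, topic=rs.topic_id)
            df = table.to_frame()
            df.insert(0, "topic", rs.topic_id)
            tables.append(df)
        import pandas as pd

        pd.concat(tables, ignore_index=True).to_csv(
            out / "subevent_distribution.csv", index=False
        )
        sums = agg.affected_sums(area)
        sums.to_frame().to_csv(out / "affected_sums.csv")
        series_rows = []
        for rs in rulesets:
            for (y, m), n in agg.monthly_series(area, rs.topic_id, window).items():
                series_rows.append({"topic": rs.topic_id, "month": f"{y:04d}-{m:02d}", "n": n})
        pd.DataFrame(series_rows).to_csv(out / "monthly_series.csv", index=False)
        coverage_rows = [
            {"topic": rs.topic_id, "countries": agg.country_coverage(area, topic=rs.topic_id)}
            for rs in rulesets
        ]
        pd.DataFrame(coverage_rows).to_csv(out / "country_coverage.csv", index=False)
        topics = [rs.topic_id for rs in rulesets]
        for theme in ("contributing_factor", "response"):
            if theme not in coded:
                continue
            codes = list(codebooks[theme].codes)
            cooc = agg.cooccurrence_matrix(coded[theme], codes, topics)
            cooc.matrix.to_csv(out / f"cooccurrence_{theme}.csv")
            agg.stacked_share_series(coded[theme], codes, window).to_csv(
                out / f"stacked_shares_{theme}.csv"
            )
        manifest.stages["synthesize"] = _stats(deduped, t0)
        manifest.extra["retained_per_topic"] = {
            rs.topic_id: sum(
                1 for r in results if r.topic_flags.get(rs.topic_id, False)
            )
            for rs in rulesets
        }
    except Exception:
        manifest.failed_stage = stage
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest


def _ruleset_lexicon(rs: re_.RuleSet) -> list[str]:
    """Positive atoms of a topic's include criteria, as scoring lexicon."""
    terms: list[str] = []

    def walk(expr, negated: bool) -> None:
        if isinstance(expr, re_.Not):
            walk(expr.child, not negated)
        elif isinstance(expr, (re_.And, re_.Or)):
            for c in expr.children:
                walk(c, negated)
        elif isinstance(expr, re_.WordAtom):
            if not negated:
                terms.append(expr.token)
        elif isinstance(expr, re_.PhraseAtom):
            if not negated:
                terms.append(" ".join(expr.tokens))
        elif isinstance(expr, re_.ValueAtom):
            if not negated:
                terms.append(" ".join(expr.term))

    for crit in rs.criteria:
        if crit.polarity == "include":
            walk(crit.pattern, False)
    # de-duplicate, preserve order
    return list(dict.fromkeys(terms))


def report_funnel(manifest: RunManifest) -> str:
    """Human-readable stage-by-stage reduction report."""
    lines = [f"{'stage':<12}{'articles':>10}{'words':>12}{'pages':>8}{'reduction':>11}"]
    # corpus stages compare corpus words; the summarize row compares its
    # summary words against the classify stage's full-text words
    prev_words = None
    for name in STAGES:
        st = manifest.stages.get(name)
        if st is None:
            continue
        if prev_words:
            red = f"{100.0 * (1 - st.words / prev_words):.1f}%"
        else:
            red = "-"
        lines.append(
            f"{name:<12}{st.articles:>10}{st.words:>12}{st.pages:>8}{red:>11}"
        )
        if name != "summarize" and st.words:
            prev_words = st.words
    return "\n".join(lines)
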