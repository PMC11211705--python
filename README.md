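# wios

**Health-workforce intelligence from open-source news media.**

`wios` is a media content analysis pipeline for public-health teams who need
to distill a very large stream of news coverage — for example, epidemic
intelligence feeds collating millions of articles — into quantitative,
reviewable evidence about a topic such as the impact of a pandemic on the
health workforce. The pipeline reduces the corpus in stages, keeping every
intermediate product on disk so human analysts can audit and supervise each
step:

1. **Rule-based classification.** Per-topic Boolean inclusion/exclusion
   criteria (word, phrase, and numeric-proximity atoms, scoped to title,
   body, or sentence) flag topic-relevant articles. A seeded sampler draws
   fixed-size validation samples of flagged articles for human relevance
   review, summarized as a relevance rate (% of the sample judged
   on-topic).
2. **Extractive summarization.** Each retained article is reduced to its
   top-3 sentences per mode (global and topic-focused) under a pluggable
   sentence scorer. The shipped reference scorer is deterministic:
   `score = #distinct lexicon terms + 1/(1+index)`. Sentences that
   triggered a topic rule become *pseudolabels* — weak supervision for a
   trainable scorer plugged into the same interface.
3. **Deduplication.** Syndicated near-copies are removed with a trigram
   rule: an article is dropped when ≥ 30% of its distinct word 3-grams
   already occur in an earlier-kept article (earliest copy wins, so
   first-report dates survive).
4. **Geography and time.** Multi-country tags are reduced to the single
   most relevant country by cross-checking gazetteer mentions in title and
   body (title mentions dominate); articles are bucketed by calendar month.
5. **Coding and synthesis.** A keyword codebook (a stand-in for human
   deductive–inductive coding; manual code files override it) assigns
   subevent, contributing-factor and response codes to summaries, which are
   synthesized into distribution tables (count and % of theme total),
   yearly "number affected" sums, monthly topic series, country coverage,
   co-occurrence matrices, and 100%-stacked monthly share series.

Corpus size is tracked throughout in articles, words, and *standardized
pages* (⌊words / 300⌋).

Because the original intelligence feed is not redistributable, the package
includes a first-class synthetic corpus generator
(`wios.synthetic_data`) that plants topic labels with time-varying
prevalence, subevent/factor/response codes, affected counts, country
mentions, multi-tag noise, and paraphrased syndicated duplicates — with
full ground truth, so every stage is testable offline.

## Worked example

```python
from wios.pipeline import RunConfig, run_pipeline, report_funnel
from wios.synthetic_data import GenerationSpec

cfg = RunConfig(out_dir="demo_run",
                generation=GenerationSpec(n_articles=2000, seed=11), seed=11)
manifest = run_pipeline(cfg)
print(report_funnel(manifest))
```

prints

```
stage         articles       words   pages  reduction
ingest            2179      824660    2748          -
classify          1527      561797    1872      31.9%
summarize         1527       66666     222      88.1%
dedup             1400      515118    1717       8.3%
geotag            1400      515118    1717       0.0%
code              1400      515118    1717       0.0%
synthesize        1400      515118    1717       0.0%
```

Read the funnel row by row: generation produced 2,179 articles (2,000
requested plus syndicated copies), classification kept the 1,527 with at
least one topic flag, summarization cut their 561,797 words of full text to
66,666 words of 3-sentence summaries (an 88.1% reduction), and
deduplication removed 127 syndicated copies. The remaining stages transform
but do not shrink the corpus. `demo_run/` then contains the per-stage
JSONL checkpoints plus the synthesized tables, e.g.
`subevent_distribution.csv`:

```
topic,code,label,n,percent
infections_deaths,infections,Infections,235,57.6
infections_deaths,deaths,Deaths,75,18.4
infections_deaths,infections_and_deaths,Infections and deaths,98,24.0
...
```

— for each impact area, how often each subevent was coded and its share of
the theme total.

The same flow is scriptable from the shell:

```bash
wios generate --seed 11 --n 2000 --out corpus.jsonl
wios classify --in corpus.jsonl --out flags.jsonl
wios dedup --in corpus.jsonl --out deduped.jsonl --report report.json
wios run --out-dir demo_run --seed 11     # full pipeline
```

Custom rules are YAML with an explicit Boolean grammar:

```yaml
topics:
  - topic: vaccination
    criteria:
      - {scope: sentence, polarity: include,
         pattern: '("vaccine" OR "vaccination") AND NOT "animal"'}
      - {scope: sentence, polarity: include,
         pattern: 'NUM >= 100 WITHIN 5 OF "doses"'}
```

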