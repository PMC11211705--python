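# Methods

This note records the models, conventions and design decisions behind
`wios`, in the order the pipeline runs.

## Corpus model and size accounting

A corpus is an ordered set of news records (id, title, body, calendar date,
source, ISO-3166 alpha-2 country tags, language). Ordering is always
`(published, article_id)`; this single convention makes deduplication's
keep-earliest policy, validation sampling, and re-runs reproducible.
Times of day are discarded: all downstream analysis is at day resolution or
coarser.

Words are whitespace-delimited tokens. By default both title and body are
counted; a `include_title=False` mode counts bodies only (sources differ on
the convention, so both are supported and the choice is echoed in the
output). A *standardized page* is ⌊words / 300⌋ — a fixed accounting unit
chosen because it reproduces every published (words, pages) pair this
package is checked against; it is a reporting convention, not a typographic
claim.

## Rule engine

Classification rules are per-topic ordered criteria. Each criterion has a
scope (`title` | `body` | `sentence`), a polarity (`include` | `exclude`),
and a Boolean pattern over three atom kinds:

* **word** — token equality after normalization (case-folded,
  leading/trailing punctuation stripped; internal punctuation kept so
  `3,500,000` is one token);
* **phrase** — contiguous normalized token sequence;
* **value** — numeric proximity: a number satisfying a comparison occurs
  within *k* tokens of a term (`NUM >= 100 WITHIN 5 OF "nurses"`). The
  window is the token distance to the nearest token of the term.

Sentence scope is satisfied iff at least one sentence individually
satisfies the whole expression — a phrase straddling a sentence boundary
does not count. Semantic decisions the rule language leaves open were
resolved as follows and are flag-configurable where noted:

* **Exclusion veto.** Any exclude match vetoes the topic regardless of how
  many includes matched. This is the conservative, precision-oriented
  reading, appropriate when flagged output feeds limited human review.
* **Includes combine by OR** (`require_all_includes=True` switches to joint
  satisfaction).
* **No stemming by default**: exact token matching is reproducible across
  platforms and languages; rule authors can list inflected forms.

Trigger sentences (the sentences that caused inclusion) are captured for
every true flag; a title-scope match is recorded as sentence index −1 with
the title text, so the evidence set is never empty. These triggers are the
pseudolabels handed to the summarizer.

Validation sampling draws `n` (default 50) flagged articles per topic
uniformly without replacement from a named, seeded generator; the
relevance rate is 100 · relevant/annotated, reported with the sample size.

## Summarizer

Sentence splitting is rule-based: terminal punctuation followed by
whitespace ends a sentence unless the final token is a single capital
initial (`A.`) or on the shipped abbreviation list
(`src/wios/data/abbreviations.txt`). Rule-based splitting was chosen over
model-based for determinism; offsets into the body are kept so summaries
are verifiably extractive.

The scorer is a plug-in point. A production system would fine-tune a neural
extractive model on the pseudolabels (first topic-focused, then mixed);
that model is out of scope here, and the reference scorer preserves the
observable contract at desk scale:

```
score(sentence) = #distinct lexicon terms present + 1 / (1 + index)
```

Topic mode uses that topic's lexicon; global mode the union of all
lexicons. The position bonus favors lead sentences (news follows an
inverted pyramid), and breaks ties toward earlier sentences. The top-k
(default 3) sentences in rank order form the summary; both global and
topic-focused summaries are emitted side by side, and the title is
prepended to summary text for human review. Any scorer plugged into the
interface inherits the k-bound, tie, and extractive contracts — only the
ranking changes.

## Deduplication

Shingles are distinct word trigrams of the body (distinct-set rather than
multiset, so within-article repetition cannot inflate overlap). The
overlap of a candidate against a reference is
`|cand ∩ ref| / |cand|` — the fraction of the candidate's trigrams that
are repeats — with Jaccard available behind a flag. A single pass in
corpus order removes an article iff its overlap with some earlier-kept
article reaches the threshold (default 0.30), attributing the removal to
the earliest such article; kept articles are never re-examined, and the
earliest copy always survives so first-report dates remain usable for time
series. An inverted trigram index accelerates candidate pairing; it is
exact (it enumerates precisely the kept articles sharing ≥ 1 trigram) and
the tests anchor it to the O(n²) brute-force pass.

## Geography and time

Country mentions are detected with a greedy longest-match scan of
normalized tokens against a gazetteer (name, aliases, demonyms → alpha-2;
`src/wios/data/gazetteer.csv`), so "South Africa" never also counts a
shorter containing alias. Multi-tag articles are resolved to one country by
ranking the *existing tags* by (title mentions, body mentions, original tag
order). Title-first weighting mirrors newsroom salience and makes
resolution deterministic; resolution can only select among the article's
tags, never invent a country. Articles whose tags are never mentioned stay
`unresolved`: they are excluded from per-country counts but retained in
global counts, which avoids arbitrary assignment. A named-entity backend
can replace the gazetteer scan behind the same interface. Time clusters are
calendar year-months.

## Coding and synthesis

The auto-coder assigns a code when any of its keywords occurs
(token-boundary, case-folded) in the summary text, subject to the code's
topic scoping; it is an explicit stand-in for human deductive–inductive
coding and makes no claim to replicate qualitative judgment. Manual code
files (CSV of article → code) override auto-codes. A code can be marked
`default_when_unmatched` — assigned when no other code of the theme matched
for that topic — which is how "unspecified" vaccination status (absence of
any dose keyword) is operationalized.

Distribution tables count *code assignments* (an article carrying several
codes of a theme counts once per code), matching the convention that theme
totals are report counts rather than distinct articles. Percentages are
100·n/N rounded **half-up** to 1 decimal (2 decimals behind a flag, for
running-text style); at 1-decimal rounding the column sum is guaranteed
within 100 ± 0.3 only by conservation of the underlying counts, which the
tests check.

Affected-count extraction from free text is out of scope (no published
extraction rule exists); counts enter through annotation fields — the
synthetic generator plants them, real use requires manual entry — and are
summed per kind (vaccinated / striking / infected / dead) per calendar
year, with records lacking counts tallied separately rather than imputed.

Monthly series count distinct articles per topic per month with zero months
explicit; co-occurrence cells count distinct articles carrying a code and a
topic (codes pooled across an article's topic records); stacked share
series normalize monthly code counts to 1, flagging empty months instead of
dividing by zero.

## Synthetic data generator

The generator emulates exactly the structure the pipeline consumes, with
full ground truth:

* **Text** is template-based (subject–verb–object with slot-filled terms),
  not language-model based: deterministic, dependency-free, auditable.
  Filler vocabulary is combinatorial (composed tails/places, optional
  adverbs, unique numeric details in half the sentences) so that distinct
  articles share well under 30% of trigrams — the generator reproduces the
  property of real news text that makes the trigram duplicate rule
  meaningful — while verbatim copies overlap fully.
* **Topics**: five impact areas (infections/deaths, mental health,
  industrial action, vaccination, education) with disjoint lexicons. Every
  labeled article carries its topic's marker phrase plus a subevent
  keyword; subevent mixes default to the published frequency distribution
  of each impact area.
* **Prevalence** is a single multinomial draw over the joint (topic, month)
  grid: Gaussian-bump curves with pronounced peaks (widths 1.0–1.2 months)
  at the months the study period exhibited — early-2020 peaks for
  infections/deaths, mental health and education, mid-2020 for industrial
  action (smallest mass), March-2021 for vaccination. The sharp peaks match
  the spiky monthly volumes seen in practice and give peak-month recovery
  tests adequate statistical power at the corpus sizes used.
* **Secondary topics** (multi-topic articles, rate 0.15) are drawn
  proportionally to each topic's own prevalence in the article's month, so
  a topic's label series stays proportional to its curve.
* **Countries**: the true country appears once in the title and at least
  twice in the body; noise tags (multi-tag rate 0.25) contribute one body
  mention, so title dominance resolves every article correctly by
  construction.
* **Duplicates**: selected source articles gain one later-dated copy whose
  sentences are paraphrased independently with probability
  `mutation_rate` (synonym substitution over the filler vocabulary plus
  half-rotation of token order — perturbations with predictable trigram
  effects). Duplicate links are acyclic and one level deep.
* **Randomness**: one stream per concern (labels, text, countries, tags,
  misc), all spawned from the master seed; changing one knob does not
  perturb the draws of another concern, and a fixed spec yields a
  byte-identical corpus.

What the generator does **not** emulate: real news style, outlet mix,
multilingual text, OCR noise, partial syndication (excerpts), or lexical
ambiguity between topic vocabularies. Passing tests therefore demonstrate
the pipeline's mechanics and contracts, not classification accuracy on
real-world prose — on real data, rule quality and the relevance-validation
loop carry that burden.

## Problem sizes and numerical choices

Tests run the generator at 150–2,000 articles and the end-to-end
acceptance run at 5,000 — sizes chosen so the full suite completes in a few
minutes while leaving the binomial/multinomial checks enough power (3
standard errors). Percentage assertions use exact decimal half-up rounding,
share sums are checked to 1e-12, and subevent mixes must sum to 1 within
1e-9. Degenerate inputs are defined, not errors: empty corpora flow through
every stage as zeros; an empty candidate shingle set has overlap 0; an
empty coding scope yields an empty table with N = 0.

## Known limitations

* The reference scorer is lexical; summaries on real prose will be
  lead-biased and lexicon-bound until a trained scorer is plugged in.
* The auto-coder is dictionary-based; nuanced or implicit subevents require
  manual codes.
* The gazetteer covers countries and common demonyms only — no
  sub-national geography, and disputed-territory policy is inherited from
  the gazetteer file.
* Affected counts are not extracted from text.
* Only full re-runs over a date window are supported; there is no
  incremental ingestion.
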