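"""Ground-truthed synthetic news corpora.

The pipeline's source feed (a global epidemic-intelligence extract of news
coverage) is not redistributable, so every downstream stage is exercised on
generated corpora that emulate the statistical structure the pipeline
assumes:

* topic-labeled articles whose bodies are template sentences salted with
  topic-lexicon terms, plus irrelevant background articles;
* time-varying topic prevalence (per-month multinomial draws from
  topic-specific curves over the corpus window);
* planted subevent codes, contributing factors, responses and
  "number affected" figures, mirroring the codebook vocabulary;
* explicit country-name mentions in title and body plus multi-tag noise,
  so country resolution is testable;
* syndicated near-duplicates produced by synonym-substitution paraphrase
  and sentence reordering, which perturb trigram sets predictably.

Generation is deterministic: one pseudo-random stream per concern (labels,
text, countries, tags, duplicates), all spawned from the master seed, so a
fixed spec yields a byte-identical corpus.  Text is template-based rather
than language-model based: auditable, dependency-free and reproducible; it
makes no attempt to mimic real news style beyond the fields the pipeline
consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus_model import Corpus, NewsArticle
from .geo_time import month_range
from .summarizer import split_sentences

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

TOPICS = (
    "infections_deaths",
    "mental_health",
    "industrial_action",
    "vaccination",
    "education",
)

#: Marker phrase planted in every labeled article of the topic (first entry)
#: followed by the rest of the topic lexicon used by rules and scoring.
TOPIC_LEXICONS: dict[str, list[str]] = {
    "infections_deaths": [
        "outbreak", "tested positive", "succumbed", "infections and deaths",
    ],
    "mental_health": [
        "mental health", "burnout", "anxiety", "exhaustion", "insomnia",
        "depression", "stress", "suicide", "trauma",
    ],
    "industrial_action": ["industrial action", "strike", "walkout", "picket"],
    "vaccination": ["vaccination", "first dose", "booster", "fully vaccinated"],
    "education": [
        "medical education", "clinical placements", "examinations",
        "student visa", "classroom teaching", "graduation ceremony",
        "curriculum disruption",
    ],
}


def default_rule_config() -> dict:
    """Rule-file mapping for the shipped topics: one sentence-scope include
    criterion per topic, OR over the topic lexicon."""
    return {
        "topics": [
            {
                "topic": topic,
                "criteria": [
                    {
                        "scope": "sentence",
                        "polarity": "include",
                        "pattern": " OR ".join(f'"{term}"' for term in lexicon),
                    }
                ],
            }
            for topic, lexicon in TOPIC_LEXICONS.items()
        ]
    }

#: Subevent code -> planted keyword phrase (agrees with the default codebook).
SUBEVENT_KEYWORDS: dict[str, str] = {
    # infections & deaths
    "infections": "tested positive",
    "deaths": "succumbed",
    "infections_and_deaths": "infections and deaths",
    # education
    "exam_postponement": "postponed examinations",
    "clinical_training_suspension": "clinical placements",
    "inperson_classes_suspension": "classroom teaching",
    "celebrations_suspension": "graduation ceremony",
    "visa_issues": "student visa",
    "other_disruptions": "curriculum disruption",
    # vaccination ("unspecified" is the absence of any dose keyword)
    "first_dose": "first dose",
    "second_dose": "fully vaccinated",
    "booster_dose": "booster",
    "unspecified": "",
    # industrial action
    "demonstration": "picket",
    "sit_down_walkout": "walkout",
    "strike": "strike",
    # mental health
    "anxiety": "anxiety",
    "burnout": "burnout",
    "depression": "depression",
    "exhaustion": "exhaustion",
    "sleep_issues": "insomnia",
    "stress": "stress",
    "suicide": "suicide",
    "trauma": "trauma",
}

FACTOR_KEYWORDS: dict[str, str] = {
    "remuneration": "unpaid wages",
    "ppe_shortage": "protective equipment",
    "workload": "excessive workload",
    "staff_shortage": "understaffed wards",
    "occupational_risk": "occupational hazards",
    "vaccine_safety_concern": "side effects",
}

RESPONSE_KEYWORDS: dict[str, str] = {
    "students_support": "final-year deployment",
    "personnel_affairs": "salary increment",
    "technology": "telehealth",
    "disciplinary_action": "sanctions",
    "mandates": "compliance mandate",
    "supply_strategy": "priority shipments",
    "therapy_support": "counseling",
    "uptake_campaign": "promotion campaign",
}

AFFECTED_KIND_BY_TOPIC = {
    "vaccination": "vaccinated",
    "industrial_action": "striking",
}
AFFECTED_KIND_BY_SUBEVENT = {
    "infections": "infected",
    "deaths": "dead",
    "infections_and_deaths": "infected",
}
AFFECTED_KIND_WORDS = {
    "vaccinated": "vaccinated",
    "striking": "striking",
    "infected": "infected",
    "dead": "deceased",
}
# lognormal (mu, sigma) of the per-article number affected
AFFECTED_MODELS = {
    "vaccinated": (8.0, 2.0),
    "striking": (7.0, 2.5),
    "infected": (6.0, 2.0),
    "dead": (3.5, 1.5),
}

COUNTRY_POOL: tuple[tuple[str, str], ...] = (
    ("India", "IN"), ("United States", "US"), ("United Kingdom", "GB"),
    ("Kenya", "KE"), ("Nigeria", "NG"), ("South Africa", "ZA"),
    ("Brazil", "BR"), ("Germany", "DE"), ("France", "FR"), ("Spain", "ES"),
    ("Italy", "IT"), ("Poland", "PL"), ("Canada", "CA"), ("Australia", "AU"),
    ("Japan", "JP"), ("Philippines", "PH"), ("Indonesia", "ID"),
    ("Mexico", "MX"), ("Argentina", "AR"), ("Egypt", "EG"), ("Ghana", "GH"),
    ("Thailand", "TH"), ("Vietnam", "VN"), ("Sweden", "SE"),
)
_CODE_TO_NAME = {code: name for name, code in COUNTRY_POOL}

_SUBJECTS = (
    "hospital staff", "frontline nurses", "community doctors", "clinic workers",
    "regional officials", "union representatives", "ward managers", "care teams",
    "district coordinators", "charge midwives", "laboratory technicians",
    "pharmacy assistants", "ambulance crews", "surgical registrars",
    "facility directors", "volunteer aides",
)
_VERBS = (
    "reported", "described", "discussed", "reviewed",
    "observed", "noted", "examined", "documented",
    "summarized", "outlined", "presented", "compared",
    "tabulated", "circulated", "forwarded", "archived",
)
_OBJECTS = (
    "new developments", "daily routines", "local arrangements",
    "regional updates", "service changes", "roster plans",
    "facility conditions", "community programs", "budget figures",
    "transport logistics", "equipment inventories", "meeting agendas",
    "procedural revisions", "referral pathways", "catering contracts",
    "maintenance backlogs",
)
_PREPS = (
    "during", "throughout", "after", "before", "amid", "following",
    "ahead of", "despite",
)
_PERIODS = (
    "week", "fortnight", "review", "quarter", "rotation", "briefing",
    "audit", "cycle", "term", "shift", "season", "session",
)
_PLACE_ADJS = (
    "central", "district", "annex", "outpatient", "coastal", "northern",
    "teaching", "satellite", "supply", "records", "conference", "municipal",
)
_PLACE_NOUNS = (
    "campus", "office", "building", "wing", "region", "province",
    "hospital", "clinic", "depot", "department", "hall", "board",
)
_ADJECTIVES = (
    "preliminary", "consolidated", "routine", "amended", "interim",
    "quarterly", "provisional", "archived", "revised", "detailed",
    "summary", "tentative",
)
_ADVERBS = (
    "promptly", "quietly", "separately", "jointly", "briefly", "formally",
    "informally", "repeatedly", "gradually", "cautiously", "openly", "partly",
)

#: Paraphrase table for duplicate injection; substitutions avoid every
#: lexicon, codebook and gazetteer term so paraphrase never flips a label.
SYNONYMS: dict[str, str] = {
    "hospital": "clinic", "staff": "personnel", "frontline": "bedside",
    "nurses": "attendants", "community": "neighborhood", "doctors": "physicians",
    "clinic": "facility", "workers": "employees", "regional": "provincial",
    "officials": "administrators", "union": "association",
    "representatives": "delegates", "ward": "unit", "managers": "supervisors",
    "care": "support", "teams": "groups",
    "reported": "stated", "described": "portrayed", "discussed": "debated",
    "reviewed": "assessed", "observed": "witnessed", "noted": "recorded",
    "examined": "inspected", "documented": "chronicled",
    "new": "fresh", "daily": "routine", "local": "nearby",
    "developments": "events", "routines": "schedules", "arrangements": "plans",
    "updates": "notices", "service": "operational", "changes": "shifts",
    "roster": "rota", "plans": "outlines", "facility": "site",
    "conditions": "circumstances", "programs": "initiatives",
    "during": "over", "week": "fortnight", "across": "throughout",
    "several": "various", "districts": "precincts", "recent": "preceding",
    "days": "mornings", "latest": "newest", "briefing": "bulletin",
    "period": "interval", "according": "pursuant", "statements": "remarks",
    "while": "whereas", "continued": "proceeded", "adjusted": "amended",
    "schedules": "timetables", "services": "operations", "followed": "tracked",
    "coverage": "reporting", "observers": "onlookers", "situation": "matter",
    "linked": "tied", "responded": "reacted", "authorities": "agencies",
    "counted": "tallied", "members": "workers",
    "district": "zonal", "coordinators": "organizers", "charge": "senior",
    "midwives": "birth-attendants", "laboratory": "diagnostic",
    "technicians": "technologists", "pharmacy": "dispensary",
    "assistants": "aides", "ambulance": "paramedic", "crews": "squads",
    "surgical": "operating", "registrars": "residents",
    "directors": "heads", "volunteer": "auxiliary",
    "summarized": "condensed", "outlined": "sketched", "presented": "shown",
    "compared": "contrasted", "tabulated": "itemized",
    "circulated": "distributed", "forwarded": "relayed", "archived": "filed",
    "budget": "fiscal", "figures": "numbers", "transport": "transit",
    "logistics": "coordination", "equipment": "apparatus",
    "inventories": "stocklists", "meeting": "session", "agendas": "dockets",
    "procedural": "protocol", "revisions": "amendments",
    "referral": "transfer", "pathways": "routes", "catering": "canteen",
    "contracts": "agreements", "maintenance": "upkeep", "backlogs": "queues",
    "quarterly": "periodic", "review": "appraisal", "despite": "notwithstanding",
    "scheduling": "timetabling", "conflicts": "clashes",
    "alongside": "besides", "inspections": "checks", "revised": "amended",
    "timetable": "calendar", "internal": "in-house", "audit": "inspection",
    "minutes": "notes", "central": "main", "campus": "grounds",
    "office": "bureau", "annex": "auxiliary", "building": "premises",
    "outpatient": "ambulatory", "wing": "block", "coastal": "seaside",
    "region": "territory", "northern": "upper", "province": "prefecture",
    "teaching": "academic", "satellite": "outlying", "depot": "warehouse",
    "records": "archives", "department": "division", "conference": "assembly",
    "hall": "chamber", "municipal": "civic", "board": "council",
    "preliminary": "initial", "consolidated": "merged", "amended": "edited",
    "interim": "stopgap", "provisional": "temporary", "detailed": "thorough",
    "summary": "condensed", "tentative": "draft", "notes": "memos",
    "mentioned": "cited", "before": "prior",
}


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


def gaussian_curve(n_months: int, peak: int, width: float) -> list[float]:
    """Unnormalized Gaussian-bump monthly weights."""
    return [math.exp(-0.5 * ((m - peak) / width) ** 2) for m in range(n_months)]


@dataclass
class TopicSpec:
    topic_id: str
    lexicon: list[str]
    prevalence_curve: list[float]  # per-month weight, >= 0
    subevent_mix: dict[str, float]
    mass: float = 1.0  # overall share of labeled articles

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.prevalence_curve):
            raise ValueError("prevalence_curve values must be >= 0")
        total = sum(self.subevent_mix.values())
        if self.subevent_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subevent_mix for {self.topic_id!r} sums to {total}, not 1"
            )


@dataclass
class GenerationSpec:
    n_articles: int = 2000
    date_window: tuple[date, date] = (date(2020, 1, 1), date(2022, 6, 30))
    topics: list[TopicSpec] = field(default_factory=list)
    background_fraction: float = 0.3
    duplicate_rate: float = 0.08
    mutation_rate: float = 0.1
    multi_tag_rate: float = 0.25
    multi_topic_rate: float = 0.15
    factor_rate: float = 0.5
    response_rate: float = 0.4
    affected_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "background_fraction", "duplicate_rate", "mutation_rate",
            "multi_tag_rate", "multi_topic_rate", "factor_rate",
            "response_rate", "affected_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_articles < 0:
            raise ValueError("n_articles must be >= 0")
        if self.date_window[0] > self.date_window[1]:
            raise ValueError(f"empty date window {self.date_window}")
        if not self.topics and self.background_fraction < 1.0:
            self.topics = default_topic_specs(self.date_window)

    @classmethod
    def from_file(cls, path: str | Path) -> "GenerationSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "date_window" in data:
            lo, hi = data["date_window"]
            data["date_window"] = (date.fromisoformat(str(lo)), date.fromisoformat(str(hi)))
        topics = []
        for t in data.pop("topics", []):
            topics.append(TopicSpec(**t))
        spec = cls(**data)
        if topics:
            spec.topics = topics
        return spec


def default_topic_specs(window: tuple[date, date]) -> list[TopicSpec]:
    """Five impact-area topics with bump-shaped prevalence over the window.

    Peaks follow the qualitative temporal pattern of pandemic coverage:
    infections/deaths, mental health and education peak early (spring of
    the first year), industrial action peaks mid-first-year with the
    smallest overall mass, and vaccination peaks ~14 months in.  Subevent
    mixes are the published frequency distribution of each impact area.
    """
    n = len(month_range(window))

    def mix(counts: dict[str, int]) -> dict[str, float]:
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}

    return [
        TopicSpec(
            "infections_deaths", TOPIC_LEXICONS["infections_deaths"],
            gaussian_curve(n, 3, 1.2),
            mix({"infections": 307, "deaths": 135, "infections_and_deaths": 128}),
            mass=0.25,
        ),
        TopicSpec(
            "mental_health", TOPIC_LEXICONS["mental_health"],
            gaussian_curve(n, 3, 1.2),
            mix({
                "anxiety": 166, "burnout": 209, "depression": 65,
                "exhaustion": 332, "sleep_issues": 36, "stress": 238,
                "suicide": 24, "trauma": 92,
            }),
            mass=0.25,
        ),
        TopicSpec(
            "industrial_action", TOPIC_LEXICONS["industrial_action"],
            gaussian_curve(n, 5, 1.0),
            mix({"demonstration": 128, "sit_down_walkout": 16, "strike": 107}),
            mass=0.10,
        ),
        TopicSpec(
            "vaccination", TOPIC_LEXICONS["vaccination"],
            gaussian_curve(n, 14, 1.2),
            mix({"first_dose": 49, "second_dose": 25, "booster_dose": 4, "unspecified": 78}),
            mass=0.25,
        ),
        TopicSpec(
            "education", TOPIC_LEXICONS["education"],
            gaussian_curve(n, 2, 1.0),
            mix({
                "exam_postponement": 23, "clinical_training_suspension": 42,
                "inperson_classes_suspension": 30, "celebrations_suspension": 5,
                "visa_issues": 19, "other_disruptions": 18,
            }),
            mass=0.15,
        ),
    ]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class ArticleTruth:
    article_id: str
    topics: list[str] = field(default_factory=list)
    subevents: dict[str, str] = field(default_factory=dict)  # topic -> code
    country: str | None = None
    factor_codes: list[str] = field(default_factory=list)
    response_codes: list[str] = field(default_factory=list)
    affected_count: int | None = None
    affected_kind: str | None = None
    duplicate_of: str | None = None
    is_background: bool = False


@dataclass
class GroundTruth:
    by_article: dict[str, ArticleTruth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, truth in self.by_article.items():
            dup = truth.duplicate_of
            if dup is not None:
                if dup == aid or self.by_article.get(dup, ArticleTruth(dup)).duplicate_of:
                    raise ValueError("duplicate-of links must be acyclic, one level deep")

    def duplicates(self) -> dict[str, str]:
        return {
            aid: t.duplicate_of
            for aid, t in self.by_article.items()
            if t.duplicate_of is not None
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for aid in sorted(self.by_article):
                fh.write(json.dumps(asdict(self.by_article[aid]), sort_keys=True))
                fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        out = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    out[rec["article_id"]] = ArticleTruth(**rec)
        return cls(out)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[rng.integers(0, len(seq))]


def _tail(rng: np.random.Generator) -> str:
    return f"{_pick(rng, _PREPS)} the {_pick(rng, _ADJECTIVES)} {_pick(rng, _PERIODS)}"


def _place(rng: np.random.Generator) -> str:
    return f"the {_pick(rng, _PLACE_ADJS)} {_pick(rng, _PLACE_NOUNS)}"


def _subj(rng: np.random.Generator) -> str:
    subj = _pick(rng, _SUBJECTS)
    if rng.random() < 0.5:
        subj = f"{subj} {_pick(rng, _ADVERBS)}"
    return subj


def _neutral_sentence(rng: np.random.Generator) -> str:
    """One filler sentence.

    Tails and places are composed combinatorially and half the sentences
    carry a unique numeric detail, so the trigram overlap between unrelated
    articles stays well below the duplicate threshold while verbatim copies
    still overlap almost completely.
    """
    s1, s2 = _subj(rng), _subj(rng)
    v1, v2 = _pick(rng, _VERBS), _pick(rng, _VERBS)
    o1, o2 = _pick(rng, _OBJECTS), _pick(rng, _OBJECTS)
    t1, t2 = _tail(rng), _tail(rng)
    adj = _pick(rng, _ADJECTIVES)
    place = _place(rng)
    shape = rng.integers(0, 4)
    if shape == 0:
        sent = f"{s1.capitalize()} {v1} {o1} {t1}, while {s2} {v2} {o2} {t2}."
    elif shape == 1:
        sent = f"{s1.capitalize()} at {place} {v1} {adj} {o1}, and {s2} {v2} {o2}."
    elif shape == 2:
        sent = f"Notes from {place} mentioned {adj} {o1} before {s2} {v2} {o2} {t1}."
    else:
        sent = f"{s1.capitalize()} {v1} {adj} {o1} at {place} {t1}."
    if rng.random() < 0.5:
        sent = sent[:-1] + f", citing file {int(rng.integers(100, 100000))}."
    return sent


def _salted_sentence(rng: np.random.Generator, term: str, country: str | None = None) -> str:
    subj = _pick(rng, _SUBJECTS)
    verb = _pick(rng, _VERBS)
    tail = _tail(rng)
    where = f" in {country}" if country else ""
    shape = rng.integers(0, 3)
    if shape == 0:
        sent = f"{subj.capitalize()}{where} {verb} the {term} {tail}."
    elif shape == 1:
        sent = (
            f"{subj.capitalize()}{where} at {_place(rng)} "
            f"{verb} the {term}."
        )
    else:
        sent = f"Accounts of the {term}{where} were {verb} by {subj} {tail}."
    if rng.random() < 0.4:
        sent = sent[:-1] + f", citing file {int(rng.integers(100, 100000))}."
    return sent


def _country_sentence(rng: np.random.Generator, cname: str) -> str:
    return (
        f"{_pick(rng, _SUBJECTS).capitalize()} in {cname} {_pick(rng, _VERBS)} "
        f"{_pick(rng, _ADJECTIVES)} {_pick(rng, _OBJECTS)} {_tail(rng)}."
    )


def _month_day(rng: np.random.Generator, ym: tuple[int, int], window: tuple[date, date]) -> date:
    y, m = ym
    first = date(y, m, 1)
    last = (date(y + 1, 1, 1) if m == 12 else date(y, m + 1, 1)) - timedelta(days=1)
    lo = max(first, window[0])
    hi = min(last, window[1])
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def generate_corpus(spec: GenerationSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus ground truth; fixed spec+seed is reproducible.

    Monthly topic counts are a single multinomial draw over the joint
    (topic, month) probability grid built from each topic's prevalence
    curve scaled by its overall mass.  Duplicate injection runs afterwards
    when ``spec.duplicate_rate`` > 0.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_labels, rng_text, rng_country, rng_tags, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    months = month_range(spec.date_window)
    articles: list[NewsArticle] = []
    truth = GroundTruth()

    n_bg = int(round(spec.n_articles * spec.background_fraction))
    n_lab = spec.n_articles - n_bg
    if n_lab > 0 and not spec.topics:
        raise ValueError("topics required when background_fraction < 1")

    # joint (topic, month) allocation
    cells: list[tuple[TopicSpec, tuple[int, int]]] = []
    probs: list[float] = []
    for t in spec.topics:
        curve = t.prevalence_curve
        if len(curve) != len(months):
            raise ValueError(
                f"prevalence_curve for {t.topic_id!r} has {len(curve)} months; "
                f"window has {len(months)}"
            )
        csum = sum(curve)
        for m, w in zip(months, curve):
            cells.append((t, m))
            probs.append(t.mass * (w / csum if csum else 0.0))
    total_p = sum(probs)
    counts = (
        rng_labels.multinomial(n_lab, [p / total_p for p in probs])
        if n_lab and total_p
        else [0] * len(cells)
    )

    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"a{serial:06d}"

    topic_by_id = {t.topic_id: t for t in spec.topics}

    for (tspec, ym), k in zip(cells, counts):
        for _ in range(int(k)):
            aid = next_id()
            t = ArticleTruth(article_id=aid)
            t.topics.append(tspec.topic_id)
            cname, ccode = COUNTRY_POOL[rng_country.integers(0, len(COUNTRY_POOL))]
            t.country = ccode
            marker = tspec.lexicon[0]
            codes = list(tspec.subevent_mix)
            probs_c = [tspec.subevent_mix[c] for c in codes]
            sub = codes[rng_labels.choice(len(codes), p=np.array(probs_c) / sum(probs_c))]
            t.subevents[tspec.topic_id] = sub

            body_sents = [
                _salted_sentence(rng_text, marker, cname),
            ]
            kw = SUBEVENT_KEYWORDS.get(sub, "")
            if kw:
                body_sents.append(_salted_sentence(rng_text, kw))
            # number-affected sentence
            kind = AFFECTED_KIND_BY_SUBEVENT.get(sub) or AFFECTED_KIND_BY_TOPIC.get(tspec.topic_id)
            if kind and rng_misc.random() < spec.affected_rate:
                mu, sigma = AFFECTED_MODELS[kind]
                count = int(rng_misc.lognormal(mu, sigma)) + 1
                t.affected_count = count
                t.affected_kind = kind
                body_sents.append(
                    f"Officials counted {count:,} {AFFECTED_KIND_WORDS[kind]} "
                    f"staff members in {cname}."
                )
            # secondary topic, drawn by each topic's own prevalence in this
            # month so multi-topic articles stay temporally coherent
            if len(spec.topics) > 1 and rng_labels.random() < spec.multi_topic_rate:
                others = [x for x in spec.topics if x.topic_id != tspec.topic_id]
                m_idx = months.index(ym)
                w2 = np.array(
                    [
                        x.mass * (x.prevalence_curve[m_idx] / (sum(x.prevalence_curve) or 1.0))
                        for x in others
                    ]
                )
                if w2.sum() <= 0:
                    w2 = np.ones(len(others))
                t2 = others[rng_labels.choice(len(others), p=w2 / w2.sum())]
                t.topics.append(t2.topic_id)
                body_sents.append(_salted_sentence(rng_text, t2.lexicon[0]))
                codes2 = list(t2.subevent_mix)
                p2 = np.array([t2.subevent_mix[c] for c in codes2])
                sub2 = codes2[rng_labels.choice(len(codes2), p=p2 / p2.sum())]
                t.subevents[t2.topic_id] = sub2
                kw2 = SUBEVENT_KEYWORDS.get(sub2, "")
                if kw2:
                    body_sents.append(_salted_sentence(rng_text, kw2))
            # contributing factor / response planting
            if rng_misc.random() < spec.factor_rate:
                fcode = list(FACTOR_KEYWORDS)[rng_misc.integers(0, len(FACTOR_KEYWORDS))]
                t.factor_codes.append(fcode)
                body_sents.append(
                    f"{_pick(rng_text, _SUBJECTS).capitalize()} "
                    f"{_pick(rng_text, _VERBS)} concerns about "
                    f"{FACTOR_KEYWORDS[fcode]} {_tail(rng_text)}."
                )
            if rng_misc.random() < spec.response_rate:
                rcode = list(RESPONSE_KEYWORDS)[rng_misc.integers(0, len(RESPONSE_KEYWORDS))]
                t.response_codes.append(rcode)
                body_sents.append(
                    f"Authorities {_pick(rng_text, _VERBS)} a plan for "
                    f"{RESPONSE_KEYWORDS[rcode]} {_tail(rng_text)}."
                )
            # second in-body mention of the true country
            body_sents.append(_country_sentence(rng_text, cname))
            # neutral filler up to the target length
            n_target = int(rng_text.integers(16, 25))
            while len(body_sents) < n_target:
                body_sents.append(_neutral_sentence(rng_text))
            # country tags: the true tag plus optional noise tags
            tags = [ccode]
            if rng_tags.random() < spec.multi_tag_rate:
                n_extra = int(rng_tags.integers(1, 3))
                pool = [c for _, c in COUNTRY_POOL if c != ccode]
                extra = [pool[i] for i in rng_tags.choice(len(pool), n_extra, replace=False)]
                for code in extra:
                    tags.append(code)
                    body_sents.append(
                        f"Observers in {_CODE_TO_NAME[code]} "
                        f"{_pick(rng_text, _VERBS)} the coverage "
                        f"{_tail(rng_text)}."
                    )
            tail_sents = body_sents[3:]  # keep lead sentences in front
            rng_text.shuffle(tail_sents)
            body_sents[3:] = tail_sents
            articles.append(
                NewsArticle(
                    article_id=aid,
                    title=f"{cname}: {_SUBJECTS[rng_text.integers(0, len(_SUBJECTS))]} "
                    f"{_VERBS[rng_text.integers(0, len(_VERBS))]} the {marker}",
                    body=" ".join(body_sents),
                    published=_month_day(rng_misc, ym, spec.date_window),
                    source=f"outlet-{int(rng_misc.integers(1, 40)):02d}",
                    country_tags=tuple(tags),
                )
            )
            truth.by_article[aid] = t

    # background articles: neutral vocabulary only, uniform months
    for _ in range(n_bg):
        aid = next_id()
        cname, ccode = COUNTRY_POOL[rng_country.integers(0, len(COUNTRY_POOL))]
        ym = months[rng_labels.integers(0, len(months))]
        n_target = int(rng_text.integers(16, 25))
        body_sents = [_neutral_sentence(rng_text) for _ in range(n_target)]
        body_sents.insert(1, _country_sentence(rng_text, cname))
        articles.append(
            NewsArticle(
                article_id=aid,
                title=f"{cname}: {_SUBJECTS[rng_text.integers(0, len(_SUBJECTS))]} "
                f"{_VERBS[rng_text.integers(0, len(_VERBS))]} "
                f"{_OBJECTS[rng_text.integers(0, len(_OBJECTS))]}",
                body=" ".join(body_sents),
                published=_month_day(rng_misc, ym, spec.date_window),
                source=f"outlet-{int(rng_misc.integers(1, 40)):02d}",
                country_tags=(ccode,),
            )
        )
        truth.by_article[aid] = ArticleTruth(
            article_id=aid, country=ccode, is_background=True
        )

    corpus = Corpus(articles, date_window=spec.date_window)
    if spec.duplicate_rate > 0:
        corpus, truth = inject_duplicates(
            corpus, truth, spec.duplicate_rate, spec.mutation_rate,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
        )
    return corpus, truth


# ---------------------------------------------------------------------------
# Duplicate injection
# ---------------------------------------------------------------------------


def paraphrase_sentence(sentence: str, synonyms: Mapping[str, str] = SYNONYMS) -> str:
    """Substitute every token with a synonym-table entry (case preserved on
    the first word) and rotate the token order, perturbing nearly all
    trigrams of the sentence."""
    toks = sentence.split()
    out = []
    for tok in toks:
        bare = tok.strip(".,;:!?").casefold()
        rep = synonyms.get(bare)
        if rep is None:
            out.append(tok)
        else:
            trail = tok[len(tok.rstrip(".,;:!?")):]
            out.append(rep + trail)
    if len(out) > 4:  # rotate halves to break boundary trigrams
        half = len(out) // 2
        tail = out[half:]
        head = out[:half]
        if tail[-1].endswith((".", "!", "?")):
            tail[-1] = tail[-1].rstrip(".!?") + ","
        head[-1] = head[-1] + "."
        out = tail + head
    text = " ".join(out)
    return text[0].upper() + text[1:] if text else text


def inject_duplicates(
    corpus: Corpus,
    truth: GroundTruth,
    duplicate_rate: float,
    mutation_rate: float,
    seed: int = 0,
    synonyms: Mapping[str, str] = SYNONYMS,
) -> tuple[Corpus, GroundTruth]:
    """Give each selected article one later-dated syndicated near-copy.

    Each sentence of the copy is paraphrased independently with
    probability ``mutation_rate``; the copy's truth records the
    duplicate-of link back to its source.
    """
    if not (0 <= duplicate_rate <= 1 and 0 <= mutation_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    new_articles = list(corpus.articles)
    new_truth = GroundTruth(dict(truth.by_article))
    window = corpus.date_window
    for article in corpus:
        if truth.by_article.get(article.article_id, ArticleTruth("")).duplicate_of:
            continue
        if rng.random() >= duplicate_rate:
            continue
        split = split_sentences(article.body, article.article_id)
        sents = []
        for s in split.sentences:
            if rng.random() < mutation_rate:
                sents.append(paraphrase_sentence(s.text, synonyms))
            else:
                sents.append(s.text)
        pub = article.published + timedelta(days=1)
        if window is not None and pub > window[1]:
            pub = article.published  # same day; id suffix keeps copy later
        copy_id = article.article_id + "d"
        new_articles.append(
            NewsArticle(
                article_id=copy_id,
                title=article.title,
                body=" ".join(sents),
                published=pub,
                source=f"wire-{int(rng.integers(1, 10)):02d}",
                country_tags=article.country_tags,
            )
        )
        src_truth = truth.by_article[article.article_id]
        copy_truth = ArticleTruth(**{**asdict(src_truth), "article_id": copy_id})
        copy_truth.duplicate_of = article.article_id
        new_truth.by_article[copy_id] = copy_truth
    return Corpus(new_articles, date_window=window), new_truth
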