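"""Seeded synthetic corpus: paired preprint/journal records, decoys, registries.

The generator emulates the *structure* of a preprint corpus — never real
scientific prose — so the full matching pipeline and its evaluation are
testable offline:

* each preprint gets a topic: a small random subset of a fixed pseudo-word
  lexicon shipped with the package; titles are 6–14 topic tokens, abstracts
  80–150. Distinct documents share almost no vocabulary, so the hashed
  3-gram backend separates twins from everything else;
* a configurable fraction of preprints is *published*: the journal twin
  copies title/abstract/authors, then applies exactly the configured
  perturbations — ``title_edit_tokens`` token substitutions in the title,
  per-token ``abstract_dropout`` in the abstract, author-format conversion
  (a preprint server may list initials only; the journal and the registry
  always carry full given names), and a positive date offset;
* *decoys* reproduce the dominant real-world error mode: an article sharing
  the preprint's first and last author but describing a different (related
  in authorship, unrelated in text) topic;
* the preprint-server and registry link tables cover disjoint strata of the
  published preprints, so the resolution cascade's priority order is
  observable from the source tags.

Determinism: one ``random.Random(spec.seed)`` stream drives everything; for
each preprint the sub-draws happen in a fixed documented order (authors →
topic → title → abstract → date → covid flag → twin perturbations → decoys),
and twin perturbation draws are consumed even for unpublished preprints so
that stratum boundaries do not reshuffle later records.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

from .errors import CorpusSpecError
from .records import (
    AuthorName,
    CandidateArticle,
    PreprintRecord,
    Server,
    write_articles,
    write_records,
)
from .similarity import EmbeddingBackend, SimilarityConfig, cosine
from .sources import (
    FixtureRegistry,
    FixtureSearchSource,
    FixtureServer,
    RegistryLink,
    SourceBundle,
    write_registry,
)
from .textnorm import StopwordList

__all__ = [
    "CorpusSpec",
    "SyntheticCorpus",
    "ToleranceEnvelope",
    "generate",
    "tolerance_envelope",
    "sources_from_corpus",
    "write_corpus",
    "load_lexicon",
]

_FAMILY_BASES = [
    "Bar", "Chen", "Dal", "Fern", "Gold", "Hart", "Ino", "Jan", "Kov", "Lin",
    "Mora", "Nov", "Ols", "Pet", "Quin", "Rey", "Sato", "Tam", "Ulr", "Vas",
    "Wag", "Xu", "Yam", "Zem", "Bren", "Cas", "Dur", "Fab", "Grim", "Hol",
]
_FAMILY_SUFFIXES = [
    "", "a", "er", "ez", "ik", "man", "ov", "sen", "son", "ström", "ti", "wal", "ari", "ino",
]
_GIVEN_NAMES = [
    "Ana", "Boris", "Carla", "Devi", "Elena", "Farid", "Greta", "Hiro", "Inés",
    "Jonas", "Kira", "Liam", "Mara", "Nils", "Olga", "Pavel", "Rosa", "Stefan",
    "Tara", "Umar", "Vera", "Wei", "Yuki", "Zara",
]

_TOPIC_SIZE = 30
_TITLE_LEN = (6, 14)
_ABSTRACT_LEN = (80, 150)
_BASE_DATE = _dt.date(2019, 1, 1)
_DATE_SPAN_DAYS = 1095  # posting dates spread across 2019-2021


def load_lexicon() -> list[str]:
    """The fixed pseudo-word lexicon shipped as package data."""
    text = (resources.files("pre2pub") / "data" / "wordlist.txt").read_text("utf-8")
    return [w for w in (line.strip() for line in text.splitlines())
            if w and not w.startswith("#")]


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    ``n_decoys_per_author`` is the number of decoy articles planted per
    preprint, each sharing that preprint's first and last author.
    """

    n_preprints: int = 200
    frac_published: float = 0.6
    frac_server_linked: float = 0.25
    frac_registry_linked: float = 0.15
    author_style: str = "initials"  # "initials" | "full_given"
    title_edit_tokens: int = 1
    abstract_dropout: float = 0.05
    n_decoys_per_author: int = 1
    date_offset_days: tuple[int, int] = (30, 365)
    frac_covid: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_published", "frac_server_linked", "frac_registry_linked",
                     "abstract_dropout", "frac_covid"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CorpusSpecError(f"{name} must be in [0, 1], got {v}")
        if self.frac_server_linked + self.frac_registry_linked > self.frac_published + 1e-9:
            raise CorpusSpecError(
                "frac_server_linked + frac_registry_linked must not exceed frac_published"
            )
        if self.n_preprints < 1:
            raise CorpusSpecError("n_preprints must be >= 1")
        if self.author_style not in ("initials", "full_given"):
            raise CorpusSpecError(f"unknown author_style {self.author_style!r}")
        lo, hi = self.date_offset_days
        if not (1 <= lo <= hi):
            raise CorpusSpecError("date_offset_days must be a positive (lo, hi) range")
        if self.title_edit_tokens < 0 or self.n_decoys_per_author < 0:
            raise CorpusSpecError("counts must be non-negative")


@dataclass
class SyntheticCorpus:
    preprints: list[PreprintRecord]
    articles: list[CandidateArticle]
    registry: dict[str, RegistryLink]
    server_links: dict[str, str]
    truth: dict[str, Optional[str]]

    def published_dois(self) -> list[str]:
        return [doi for doi, target in self.truth.items() if target is not None]


def _person_pool(rng: random.Random, size: int) -> list[tuple[str, str]]:
    combos = [(base + suf, given)
              for base in _FAMILY_BASES for suf in _FAMILY_SUFFIXES for given in _GIVEN_NAMES]
    rng.shuffle(combos)
    if size > len(combos):
        raise CorpusSpecError(f"corpus too large for the name pool ({len(combos)} persons)")
    return combos[:size]


def _display_author(person: tuple[str, str], style: str) -> AuthorName:
    family, given = person
    if style == "initials":
        return AuthorName(family=family, given=f"{given[0]}.")
    return AuthorName(family=family, given=given)


def generate(spec: CorpusSpec) -> SyntheticCorpus:
    """Deterministically generate one corpus from its spec (see module docs)."""
    rng = random.Random(spec.seed)
    lexicon = load_lexicon()
    n = spec.n_preprints
    n_pub = round(spec.frac_published * n)
    n_srv = round(spec.frac_server_linked * n)
    n_reg = round(spec.frac_registry_linked * n)
    if n_srv + n_reg > n_pub:  # rounding can nudge the strata past each other
        n_reg = n_pub - n_srv
    pool = _person_pool(rng, max(30, 2 * n))

    preprints: list[PreprintRecord] = []
    articles: list[CandidateArticle] = []
    registry: dict[str, RegistryLink] = {}
    server_links: dict[str, str] = {}
    truth: dict[str, Optional[str]] = {}

    lo_off, hi_off = spec.date_offset_days
    for i in range(n):
        # Fixed draw order; see module docstring.
        n_authors = rng.randint(2, 6)
        persons = rng.sample(pool, n_authors)
        topic = rng.sample(lexicon, _TOPIC_SIZE)
        title_tokens = [rng.choice(topic) for _ in range(rng.randint(*_TITLE_LEN))]
        abstract_tokens = [rng.choice(topic) for _ in range(rng.randint(*_ABSTRACT_LEN))]
        pre_date = _BASE_DATE + _dt.timedelta(days=rng.randrange(_DATE_SPAN_DAYS))
        covid = rng.random() < spec.frac_covid
        twin_offset = rng.randint(lo_off, hi_off)
        k_edit = min(spec.title_edit_tokens, len(title_tokens))
        edit_positions = rng.sample(range(len(title_tokens)), k_edit)
        edit_words = [rng.choice(lexicon) for _ in edit_positions]
        dropout_draws = [rng.random() for _ in abstract_tokens]

        doi = f"10.1101/{2019 + i % 3}.{i:05d}"
        title = " ".join(title_tokens)
        abstract = " ".join(abstract_tokens)
        preprints.append(
            PreprintRecord(
                doi=doi,
                title=title.capitalize(),
                abstract=abstract,
                authors=[_display_author(p, spec.author_style) for p in persons],
                publication_date=pre_date,
                server=Server.BIORXIV if i % 2 == 0 else Server.MEDRXIV,
                covid_related=covid,
            )
        )

        published = i < n_pub
        journal_doi = f"10.1200/art.{i:05d}" if published else None
        truth[doi] = journal_doi
        if published:
            twin_title = list(title_tokens)
            for pos, word in zip(edit_positions, edit_words):
                twin_title[pos] = word
            twin_abstract = [t for t, u in zip(abstract_tokens, dropout_draws)
                             if u >= spec.abstract_dropout]
            if not twin_abstract:
                twin_abstract = abstract_tokens[:1]
            articles.append(
                CandidateArticle(
                    pmid=f"9{i:07d}",
                    doi=journal_doi,
                    title=" ".join(twin_title).capitalize(),
                    abstract=" ".join(twin_abstract),
                    authors=[_display_author(p, "full_given") for p in persons],
                    publication_date=pre_date + _dt.timedelta(days=twin_offset),
                )
            )
        if i < n_srv:
            server_links[doi] = journal_doi  # server stratum ⊂ published
            reg_doi = None
        elif i < n_srv + n_reg:
            reg_doi = journal_doi
        else:
            reg_doi = None
        registry[doi] = RegistryLink(
            preprint_doi=doi,
            journal_doi=reg_doi,
            full_authors=tuple(_display_author(p, "full_given") for p in persons),
        )

        # Decoys: same first and last author, unrelated topic, later date.
        for j in range(spec.n_decoys_per_author):
            n_mid = rng.randint(1, 3)
            mids = rng.sample(pool, n_mid)
            decoy_persons = [persons[0], *mids, persons[-1]]
            decoy_topic = rng.sample(lexicon, _TOPIC_SIZE)
            decoy_title = [rng.choice(decoy_topic) for _ in range(rng.randint(*_TITLE_LEN))]
            decoy_abstract = [rng.choice(decoy_topic) for _ in range(rng.randint(*_ABSTRACT_LEN))]
            decoy_offset = rng.randint(lo_off, hi_off)
            articles.append(
                CandidateArticle(
                    pmid=f"8{i:05d}{j:02d}",
                    doi=f"10.1300/decoy.{i:05d}.{j}",
                    title=" ".join(decoy_title).capitalize(),
                    abstract=" ".join(decoy_abstract),
                    authors=[_display_author(p, "full_given") for p in decoy_persons],
                    publication_date=pre_date + _dt.timedelta(days=decoy_offset),
                )
            )

    return SyntheticCorpus(
        preprints=preprints, articles=articles, registry=registry,
        server_links=server_links, truth=truth,
    )


def sources_from_corpus(
    corpus: SyntheticCorpus,
    stopwords: StopwordList | None = None,
    retmax: int = 5,
    unindexed_title_pmids: tuple[str, ...] = (),
) -> SourceBundle:
    """Wrap a corpus in the offline fixture sources the pipeline consumes."""
    return SourceBundle(
        search=FixtureSearchSource(
            corpus.articles, stopwords=stopwords, retmax=retmax,
            unindexed_title_pmids=unindexed_title_pmids,
        ),
        registry=FixtureRegistry(corpus.registry.values()),
        server=FixtureServer(corpus.server_links),
    )


@dataclass(frozen=True)
class ToleranceEnvelope:
    """Maximal perturbation settings under which every planted twin still
    passes both similarity thresholds on a given backend (brute-forced, not
    assumed)."""

    max_title_edit_tokens: int
    max_abstract_dropout: float
    spec_inside: bool


def _min_twin_scores(corpus: SyntheticCorpus, backend: EmbeddingBackend) -> tuple[float, float]:
    by_doi = {a.doi: a for a in corpus.articles if a.doi}
    min_title = min_abs = 1.0
    for pre in corpus.preprints:
        target = corpus.truth.get(pre.doi)
        if target is None:
            continue
        twin = by_doi[target]
        min_title = min(min_title, cosine(backend.embed(pre.title), backend.embed(twin.title)))
        min_abs = min(min_abs, cosine(backend.embed(pre.abstract), backend.embed(twin.abstract)))
    return min_title, min_abs


def tolerance_envelope(
    spec: CorpusSpec,
    backend: EmbeddingBackend,
    sim_cfg: SimilarityConfig | None = None,
    title_edit_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 6),
    dropout_grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.3),
) -> ToleranceEnvelope:
    """Scan one perturbation axis at a time (the other held at zero) and
    report the largest contiguous settings at which all twins still pass."""
    sim_cfg = sim_cfg or SimilarityConfig()
    max_edit = -1
    for t in sorted(title_edit_grid):
        corp = generate(replace(spec, title_edit_tokens=t, abstract_dropout=0.0))
        min_title, _ = _min_twin_scores(corp, backend)
        if min_title >= sim_cfg.title_threshold:
            max_edit = t
        else:
            break
    max_drop = -1.0
    for d in sorted(dropout_grid):
        corp = generate(replace(spec, title_edit_tokens=0, abstract_dropout=d))
        _, min_abs = _min_twin_scores(corp, backend)
        if min_abs > sim_cfg.abstract_threshold:
            max_drop = d
        else:
            break
    return ToleranceEnvelope(
        max_title_edit_tokens=max_edit,
        max_abstract_dropout=max_drop,
        spec_inside=(spec.title_edit_tokens <= max_edit and spec.abstract_dropout <= max_drop),
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write the corpus as plain-text fixtures: three JSONL files plus TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "preprints": outdir / "preprints.jsonl",
        "articles": outdir / "articles.jsonl",
        "registry": outdir / "registry.jsonl",
        "server_links": outdir / "server_links.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_records(corpus.preprints, paths["preprints"], fmt="jsonl")
    write_articles(corpus.articles, paths["articles"], fmt="jsonl")
    write_registry(corpus.registry.values(), paths["registry"])
    with paths["server_links"].open("w", encoding="utf-8") as fh:
        for doi, journal in corpus.server_links.items():
            fh.write(f"{doi}\t{journal}\n")
    with paths["truth"].open("w", encoding="utf-8") as fh:
        for doi, journal in corpus.truth.items():
            if journal is not None:
                fh.write(f"{doi}\t{journal}\n")
    return paths
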