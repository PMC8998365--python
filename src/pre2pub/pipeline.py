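"""The matching algorithm and the link-resolution cascade.

One matching attempt (:func:`find_journal_article`) runs five steps:

1. search the literature index in the *title* field with the stopword-cleaned
   preprint title, capped at ``retmax`` (5) candidates;
2. if the title search returned candidates, verify each by comparing ordered
   author lists (5-rule fuzzy comparison), preferring the registry's complete
   author names over the preprint server's possibly initials-only forms;
3. otherwise search in the *author* field and verify each candidate by
   embedding-cosine title similarity (≥ 0.95);
4. drop candidates whose publication date is not after the preprint's
   (configurable to allow same-day);
5. embed the abstracts, keep the candidate with the highest cosine to the
   preprint's abstract, and accept it iff that score strictly exceeds 0.9.

Ties at step 5 keep the earlier source rank. Candidates with no abstract are
excluded at step 5 (they can never be the argmax); a preprint with no
abstract yields a rejected decision flagged ``missing_abstract``.

:func:`resolve_link` is the cascade a curation service runs: preprint-server
metadata first, then the registry relation, then the matcher; the first
stage that answers tags the link (``server`` > ``crossref`` > ``pre2pub``).
:func:`update_links` applies the refresh policy: links from the server or
registry are frozen; algorithm-found links and unlinked preprints are
re-checked, and an algorithmic link is replaced the moment an authoritative
source provides one.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .authors import AuthorMatchConfig, authors_match
from .errors import ConsistencyError, Pre2PubError, SourceError
from .records import (
    AuthorRule,
    CandidateArticle,
    LinkRecord,
    LinkSource,
    MatchDecision,
    PreprintRecord,
    Route,
)
from .similarity import EmbeddingBackend, SimilarityConfig, abstracts_similar, titles_similar
from .sources import SourceBundle
from .textnorm import StopwordList, clean_title, load_stopwords

__all__ = [
    "DateStrictness",
    "PipelineConfig",
    "date_check",
    "find_journal_article",
    "resolve_link",
    "update_links",
]


class DateStrictness(str, Enum):
    STRICTLY_OLDER = "strictly_older"
    OLDER_OR_EQUAL = "older_or_equal"


@dataclass
class PipelineConfig:
    author_cfg: AuthorMatchConfig = field(default_factory=AuthorMatchConfig)
    sim_cfg: SimilarityConfig = field(default_factory=SimilarityConfig)
    retmax: int = 5
    date_strictness: DateStrictness = DateStrictness.STRICTLY_OLDER
    stopwords: Optional[StopwordList] = None

    def __post_init__(self) -> None:
        if self.retmax < 1:
            raise ValueError("retmax must be >= 1")
        self.date_strictness = DateStrictness(self.date_strictness)
        if self.stopwords is None:
            self.stopwords = load_stopwords()


def date_check(
    preprint_date: _dt.date, article_date: _dt.date, cfg: PipelineConfig | None = None
) -> bool:
    """The preprint must predate the journal article (strict by default)."""
    cfg = cfg or PipelineConfig()
    if cfg.date_strictness is DateStrictness.OLDER_OR_EQUAL:
        return preprint_date <= article_date
    return preprint_date < article_date


def find_journal_article(
    preprint: PreprintRecord,
    sources: SourceBundle,
    backend: EmbeddingBackend,
    cfg: PipelineConfig | None = None,
) -> MatchDecision:
    """Run one matching attempt; always returns a full audit decision."""
    cfg = cfg or PipelineConfig()
    if not preprint.title.strip():
        raise Pre2PubError(f"{preprint.doi}: matching requires a non-empty title")
    if not preprint.authors:
        raise Pre2PubError(f"{preprint.doi}: matching requires at least one author")

    # Step 1: title-field search on the cleaned title. An all-stopword title
    # cleans to the empty string, which counts as an unsuccessful search.
    cleaned = clean_title(preprint.title, cfg.stopwords)
    title_candidates: list[CandidateArticle] = (
        sources.search.search_by_title(cleaned) if cleaned else []
    )

    # (candidate, rule_fired or None, title_score or None), in source rank order
    verified: list[tuple[CandidateArticle, Optional[AuthorRule], Optional[float]]] = []

    if title_candidates:
        route = Route.TITLE_FIRST
        pre_authors = list(preprint.authors)
        try:
            reg = sources.registry.lookup(preprint.doi)
            if reg.full_authors:
                pre_authors = list(reg.full_authors)
        except SourceError:
            pass  # enrichment is a workaround, not a dependency
        for cand in title_candidates:
            if not cand.authors:
                continue
            res = authors_match(pre_authors, cand.authors, cfg.author_cfg)
            if res.matched:
                verified.append((cand, res.rule_fired, None))
    else:
        author_candidates = sources.search.search_by_authors(preprint.authors)
        if not author_candidates:
            return MatchDecision(preprint_doi=preprint.doi, route=Route.NONE, accepted=False)
        route = Route.AUTHOR_FIRST
        for cand in author_candidates:
            ok, score = titles_similar(preprint.title, cand.title, backend, cfg.sim_cfg)
            if ok:
                verified.append((cand, None, score))

    if not verified:
        return MatchDecision(preprint_doi=preprint.doi, route=route, accepted=False)

    # Step 4: date ordering.
    dated = [
        entry
        for entry in verified
        if entry[0].publication_date is not None
        and preprint.publication_date is not None
        and date_check(preprint.publication_date, entry[0].publication_date, cfg)
    ]
    if not dated:
        cand, rule, tscore = verified[0]
        return MatchDecision(
            preprint_doi=preprint.doi, route=route, accepted=False, candidate=cand,
            author_rule_fired=rule, title_similarity=tscore, date_ok=False,
        )

    # Step 5: abstract similarity, argmax wins (ties keep earlier rank).
    if not preprint.abstract.strip():
        cand, rule, tscore = dated[0]
        return MatchDecision(
            preprint_doi=preprint.doi, route=route, accepted=False, candidate=cand,
            author_rule_fired=rule, title_similarity=tscore, date_ok=True,
            missing_abstract=True,
        )
    best: Optional[tuple[CandidateArticle, Optional[AuthorRule], Optional[float]]] = None
    best_score: Optional[float] = None
    for cand, rule, tscore in dated:
        if not cand.abstract.strip():
            continue  # never scored, never the argmax
        _, score = abstracts_similar(preprint.abstract, cand.abstract, backend, cfg.sim_cfg)
        if score is not None and (best_score is None or score > best_score):
            best, best_score = (cand, rule, tscore), score
    if best is None:
        cand, rule, tscore = dated[0]
        return MatchDecision(
            preprint_doi=preprint.doi, route=route, accepted=False, candidate=cand,
            author_rule_fired=rule, title_similarity=tscore, date_ok=True,
        )
    cand, rule, tscore = best
    accepted = best_score > cfg.sim_cfg.abstract_threshold
    return MatchDecision(
        preprint_doi=preprint.doi, route=route, accepted=accepted, candidate=cand,
        author_rule_fired=rule, title_similarity=tscore,
        abstract_similarity=best_score, date_ok=True,
    )


def resolve_link(
    preprint: PreprintRecord,
    sources: SourceBundle,
    backend: EmbeddingBackend,
    cfg: PipelineConfig | None = None,
    now: Optional[_dt.datetime] = None,
    audit: Optional[list[MatchDecision]] = None,
) -> Optional[LinkRecord]:
    """The resolution cascade: server → registry → matcher; first answer wins.

    ``now`` stamps the returned link (defaults to the current UTC time);
    ``audit``, when given, collects the matcher's decision for logging.
    """
    cfg = cfg or PipelineConfig()
    stamp = now or _dt.datetime.now(_dt.timezone.utc)

    server_doi = sources.server.lookup(preprint.doi)
    if server_doi:
        return LinkRecord(preprint.doi, server_doi, LinkSource.SERVER, stamp)

    reg = sources.registry.lookup(preprint.doi)
    if reg.journal_doi:
        return LinkRecord(preprint.doi, reg.journal_doi, LinkSource.CROSSREF, stamp)

    decision = find_journal_article(preprint, sources, backend, cfg)
    if audit is not None:
        audit.append(decision)
    if decision.accepted and decision.candidate is not None and decision.candidate.doi:
        return LinkRecord(preprint.doi, decision.candidate.doi, LinkSource.PRE2PUB, stamp)
    return None


def update_links(
    store: Iterable[LinkRecord] | Mapping[str, LinkRecord],
    preprints: Iterable[PreprintRecord],
    sources: SourceBundle,
    backend: EmbeddingBackend,
    cfg: PipelineConfig | None = None,
    now: Optional[_dt.datetime] = None,
) -> dict[str, LinkRecord]:
    """One refresh pass over a link store.

    Server/registry links are frozen (never re-examined). Algorithm-found
    links are re-checked against the server and registry only, and upgraded
    when one of those now stores a link (the algorithmic target is replaced
    even if it differs). Unlinked preprints go through the full cascade.
    """
    cfg = cfg or PipelineConfig()
    stamp = now or _dt.datetime.now(_dt.timezone.utc)
    if isinstance(store, Mapping):
        current = dict(store)
    else:
        current = {}
        for link in store:
            if link.preprint_doi in current:
                raise ConsistencyError(f"duplicate link for {link.preprint_doi}")
            current[link.preprint_doi] = link

    updated: dict[str, LinkRecord] = {}
    for preprint in preprints:
        existing = current.get(preprint.doi)
        if existing is not None and existing.source in (LinkSource.SERVER, LinkSource.CROSSREF):
            updated[preprint.doi] = existing  # frozen
            continue
        if existing is not None:  # source == pre2pub: authoritative re-check only
            server_doi = sources.server.lookup(preprint.doi)
            if server_doi:
                updated[preprint.doi] = LinkRecord(
                    preprint.doi, server_doi, LinkSource.SERVER, stamp
                )
                continue
            reg = sources.registry.lookup(preprint.doi)
            if reg.journal_doi:
                updated[preprint.doi] = LinkRecord(
                    preprint.doi, reg.journal_doi, LinkSource.CROSSREF, stamp
                )
                continue
            updated[preprint.doi] = existing
            continue
        link = resolve_link(preprint, sources, backend, cfg, now=stamp)
        if link is not None:
            updated[preprint.doi] = link
    # Links for preprints not in this batch pass through untouched.
    for doi, link in current.items():
        updated.setdefault(doi, link)
    return updated
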