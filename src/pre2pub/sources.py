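"""Metadata sources: search service, DOI registry, preprint servers.

Three contracts, each satisfied by an offline fixture implementation and a
live HTTP client:

* a *search source* with field-restricted title and author queries, capped at
  ``retmax`` results (default 5 — a deliberately small cap that limits
  false-positive candidates);
* a *registry* that may store an ``is-preprint-of`` relation for a preprint
  DOI, and often carries the complete author names (used to enrich
  initials-only preprint-server names before comparison);
* a *server* lookup returning the journal DOI a preprint server itself
  advertises, when it does.

All tests and offline runs use the fixture implementations; the live clients
(NCBI E-utilities, Crossref, bioRxiv/medRxiv details API) go through a rate
limiter, an on-disk response cache keyed by (endpoint, query), and bounded
retries with exponential backoff. Their response parsing is factored into
pure functions so it can be exercised on canned payloads without a network.

The fixture search source emulates a search engine deterministically: title
queries rank exact cleaned-title matches first, then by token overlap
(Jaccard ≥ 0.5 to count as a hit at all); author queries rank by the number
of query authors present in the article's author list (family name plus
first given initial), requiring at least one. Ties break by PMID.
"""

from __future__ import annotations

import hashlib
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence
from xml.etree import ElementTree

from .errors import SourceError
from .records import (
    AuthorName,
    CandidateArticle,
    authors_from_str,
    authors_to_str,
    normalize_doi,
)
from .textnorm import StopwordList, clean_title, fold_text, load_stopwords

__all__ = [
    "RegistryLink",
    "SearchSource",
    "RegistrySource",
    "ServerSource",
    "SourceBundle",
    "FixtureSearchSource",
    "FixtureRegistry",
    "FixtureServer",
    "RateLimiter",
    "ResponseCache",
    "EntrezSearchSource",
    "CrossrefRegistry",
    "RxivServer",
    "read_registry",
    "write_registry",
]

DEFAULT_RETMAX = 5


@dataclass(frozen=True)
class RegistryLink:
    """What the DOI registry knows about one preprint."""

    preprint_doi: str
    journal_doi: Optional[str] = None
    full_authors: Optional[tuple[AuthorName, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "preprint_doi", normalize_doi(self.preprint_doi))
        if self.journal_doi is not None:
            object.__setattr__(self, "journal_doi", normalize_doi(self.journal_doi))
        if self.full_authors is not None:
            object.__setattr__(self, "full_authors", tuple(self.full_authors))


class SearchSource(Protocol):
    name: str
    retmax: int

    def search_by_title(self, cleaned_title: str) -> list[CandidateArticle]: ...

    def search_by_authors(self, authors: Sequence[AuthorName]) -> list[CandidateArticle]: ...


class RegistrySource(Protocol):
    def lookup(self, doi: str) -> RegistryLink: ...


class ServerSource(Protocol):
    def lookup(self, doi: str) -> Optional[str]: ...


@dataclass
class SourceBundle:
    """The three sources the resolution cascade consults, bundled."""

    search: SearchSource
    registry: RegistrySource
    server: ServerSource


# ---------------------------------------------------------------------------
# Fixture (offline) implementations


class FixtureSearchSource:
    """In-memory search over a candidate-article corpus with deterministic ranking.

    ``unindexed_title_pmids`` emulates a real-world quirk: an article present
    in the index but not retrievable through the title field, which forces
    the pipeline onto its author-search fallback.
    """

    def __init__(
        self,
        articles: Iterable[CandidateArticle],
        stopwords: StopwordList | None = None,
        retmax: int = DEFAULT_RETMAX,
        min_title_overlap: float = 0.5,
        unindexed_title_pmids: Iterable[str] = (),
        name: str = "fixture",
    ):
        if retmax < 1:
            raise ValueError("retmax must be >= 1")
        self.name = name
        self.retmax = int(retmax)
        self.min_title_overlap = float(min_title_overlap)
        self._unindexed = frozenset(str(p) for p in unindexed_title_pmids)
        sw = stopwords or load_stopwords()
        self._articles = list(articles)
        self._title_tokens = [frozenset(clean_title(a.title, sw).split()) for a in self._articles]
        self._cleaned_titles = [clean_title(a.title, sw) for a in self._articles]
        self._author_keys = [
            frozenset(_author_key(auth) for auth in a.authors) for a in self._articles
        ]

    def search_by_title(self, cleaned_title: str) -> list[CandidateArticle]:
        if not cleaned_title.strip():
            raise ValueError("search_by_title requires a non-empty cleaned title")
        query_tokens = frozenset(cleaned_title.split())
        ranked: list[tuple[int, float, str, CandidateArticle]] = []
        for art, tokens, cleaned in zip(
            self._articles, self._title_tokens, self._cleaned_titles
        ):
            if art.pmid in self._unindexed:
                continue
            if cleaned == cleaned_title:
                ranked.append((0, 0.0, art.pmid, art))
                continue
            union = query_tokens | tokens
            overlap = len(query_tokens & tokens) / len(union) if union else 0.0
            if overlap >= self.min_title_overlap:
                ranked.append((1, -overlap, art.pmid, art))
        ranked.sort(key=lambda t: t[:3])
        return [art for *_, art in ranked[: self.retmax]]

    def search_by_authors(self, authors: Sequence[AuthorName]) -> list[CandidateArticle]:
        if not authors:
            raise ValueError("search_by_authors requires a non-empty author list")
        query_keys = frozenset(_author_key(a) for a in authors)
        ranked: list[tuple[int, str, CandidateArticle]] = []
        for art, keys in zip(self._articles, self._author_keys):
            hits = len(query_keys & keys)
            if hits >= 1:
                ranked.append((-hits, art.pmid, art))
        ranked.sort(key=lambda t: t[:2])
        return [art for *_, art in ranked[: self.retmax]]


def _author_key(author: AuthorName) -> tuple[str, str]:
    """Family name plus first given-initial; tolerant of initials-only forms."""
    given = fold_text(author.given).strip()
    return (fold_text(author.family).strip(), given[:1])


class FixtureRegistry:
    """Dict-backed registry; unknown DOIs yield an empty :class:`RegistryLink`."""

    def __init__(self, links: Iterable[RegistryLink] = ()):
        self._links = {link.preprint_doi: link for link in links}

    def lookup(self, doi: str) -> RegistryLink:
        doi = normalize_doi(doi)
        return self._links.get(doi, RegistryLink(preprint_doi=doi))


class FixtureServer:
    """Dict-backed preprint-server lookup: preprint DOI → journal DOI (or None)."""

    def __init__(self, links: dict[str, str] | None = None):
        self._links = {
            normalize_doi(k): normalize_doi(v) for k, v in (links or {}).items()
        }

    def lookup(self, doi: str) -> Optional[str]:
        return self._links.get(normalize_doi(doi))


def write_registry(links: Iterable[RegistryLink], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for link in links:
            fh.write(
                json.dumps(
                    {
                        "preprint_doi": link.preprint_doi,
                        "journal_doi": link.journal_doi or "",
                        "full_authors": authors_to_str(link.full_authors or ()),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_registry(path: str | Path) -> list[RegistryLink]:
    out: list[RegistryLink] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            authors = authors_from_str(d.get("full_authors") or "")
            out.append(
                RegistryLink(
                    preprint_doi=d["preprint_doi"],
                    journal_doi=d.get("journal_doi") or None,
                    full_authors=tuple(authors) if authors else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Live clients (never exercised by the test suite; parsing is pure/testable)


class RateLimiter:
    """Minimum-interval limiter shared by a client's calls."""

    def __init__(self, per_sec: float = 3.0):
        if per_sec <= 0:
            raise ValueError("per_sec must be positive")
        self._interval = 1.0 / per_sec
        self._last: Optional[float] = None

    def wait(self, now: float | None = None, sleep=time.sleep) -> None:
        t = time.monotonic() if now is None else now
        if self._last is not None:
            delta = self._interval - (t - self._last)
            if delta > 0:
                sleep(delta)
                t += delta
        self._last = t


class ResponseCache:
    """On-disk cache keyed by (endpoint, sorted query); replays bit-identically."""

    def __init__(self, cache_dir: str | Path | None):
        self._dir = Path(cache_dir) if cache_dir else None
        if self._dir:
            self._dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(endpoint: str, params: dict) -> str:
        canon = endpoint + "?" + urllib.parse.urlencode(sorted(params.items()))
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()

    def get(self, endpoint: str, params: dict) -> Optional[str]:
        if not self._dir:
            return None
        p = self._dir / (self.key(endpoint, params) + ".txt")
        return p.read_text("utf-8") if p.exists() else None

    def put(self, endpoint: str, params: dict, body: str) -> None:
        if self._dir:
            (self._dir / (self.key(endpoint, params) + ".txt")).write_text(body, "utf-8")


def _http_get(
    endpoint: str,
    params: dict,
    cache: ResponseCache,
    limiter: RateLimiter,
    attempts: int = 3,
    timeout: float = 30.0,
) -> str:  # pragma: no cover - network path
    cached = cache.get(endpoint, params)
    if cached is not None:
        return cached
    url = endpoint + "?" + urllib.parse.urlencode(params)
    last_exc: Exception | None = None
    for attempt in range(attempts):
        limiter.wait()
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                body = resp.read().decode("utf-8")
            cache.put(endpoint, params, body)
            return body
        except (urllib.error.URLError, OSError) as exc:
            last_exc = exc
            time.sleep(2.0**attempt)
    raise SourceError(f"GET {endpoint} failed after {attempts} attempts: {last_exc}")


def parse_esearch_ids(body: str) -> list[str]:
    """Extract the ID list from an E-utilities esearch JSON response."""
    data = json.loads(body)
    return [str(i) for i in data.get("esearchresult", {}).get("idlist", [])]


def parse_efetch_articles(xml_text: str) -> list[CandidateArticle]:
    """Parse an E-utilities efetch PubmedArticleSet XML into candidates."""
    root = ElementTree.fromstring(xml_text)
    out: list[CandidateArticle] = []
    for art in root.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID") or ""
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (node.text or "") for node in art.findall(".//Abstract/AbstractText")
        ).strip()
        doi = None
        for eloc in art.findall(".//ELocationID"):
            if eloc.get("EIdType") == "doi" and eloc.text:
                doi = eloc.text
        authors = []
        for a in art.findall(".//AuthorList/Author"):
            family = a.findtext("LastName") or ""
            given = a.findtext("ForeName") or a.findtext("Initials") or ""
            if family:
                authors.append(AuthorName(family=family, given=given))
        date = None
        pubdate = art.find(".//ArticleDate")
        if pubdate is None:
            pubdate = art.find(".//PubDate")
        if pubdate is not None:
            y = pubdate.findtext("Year")
            m = pubdate.findtext("Month") or "1"
            d = pubdate.findtext("Day") or "1"
            if y:
                months = {
                    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
                    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
                }
                mnum = months.get(m[:3].lower(), None) if not m.isdigit() else int(m)
                import datetime as _dt

                date = _dt.date(int(y), mnum or 1, int(d) if d.isdigit() else 1)
        if pmid and title:
            out.append(
                CandidateArticle(
                    pmid=pmid, title=title, abstract=abstract, authors=authors,
                    publication_date=date, doi=doi,
                )
            )
    return out


def parse_crossref_work(message: dict, preprint_doi: str) -> RegistryLink:
    """Extract the is-preprint-of relation and full author names from a
    Crossref work message."""
    journal = None
    for rel in message.get("relation", {}).get("is-preprint-of", []):
        if rel.get("id-type", "doi") == "doi" and rel.get("id"):
            journal = rel["id"]
            break
    authors = tuple(
        AuthorName(family=a.get("family", ""), given=a.get("given", ""))
        for a in message.get("author", [])
        if a.get("family")
    )
    return RegistryLink(
        preprint_doi=preprint_doi,
        journal_doi=journal,
        full_authors=authors or None,
    )


def parse_rxiv_details(data: dict) -> Optional[str]:
    """Extract the 'published' journal DOI from a bioRxiv/medRxiv details payload."""
    for entry in data.get("collection", []):
        published = entry.get("published")
        if published and published != "NA":
            return published
    return None


class EntrezSearchSource:  # pragma: no cover - network client
    """Field-restricted PubMed search through NCBI E-utilities."""

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(
        self,
        retmax: int = DEFAULT_RETMAX,
        cache_dir: str | Path | None = None,
        rate_limit_per_sec: float = 3.0,
        api_key: str | None = None,
    ):
        self.name = "entrez"
        self.retmax = int(retmax)
        self._cache = ResponseCache(cache_dir)
        self._limiter = RateLimiter(rate_limit_per_sec)
        self._api_key = api_key

    def _search(self, term: str, fieldname: str) -> list[CandidateArticle]:
        params = {
            "db": "pubmed", "term": term, "field": fieldname,
            "retmax": self.retmax, "retmode": "json",
        }
        if self._api_key:
            params["api_key"] = self._api_key
        ids = parse_esearch_ids(
            _http_get(f"{self.BASE}/esearch.fcgi", params, self._cache, self._limiter)
        )
        if not ids:
            return []
        fetch = {"db": "pubmed", "id": ",".join(ids), "retmode": "xml"}
        if self._api_key:
            fetch["api_key"] = self._api_key
        articles = parse_efetch_articles(
            _http_get(f"{self.BASE}/efetch.fcgi", fetch, self._cache, self._limiter)
        )
        order = {pmid: i for i, pmid in enumerate(ids)}
        articles.sort(key=lambda a: order.get(a.pmid, len(order)))
        return articles[: self.retmax]

    def search_by_title(self, cleaned_title: str) -> list[CandidateArticle]:
        if not cleaned_title.strip():
            raise ValueError("search_by_title requires a non-empty cleaned title")
        return self._search(cleaned_title, "title")

    def search_by_authors(self, authors: Sequence[AuthorName]) -> list[CandidateArticle]:
        if not authors:
            raise ValueError("search_by_authors requires a non-empty author list")
        term = " AND ".join(f"{a.family} {a.given}".strip() for a in authors)
        return self._search(term, "author")


class CrossrefRegistry:  # pragma: no cover - network client
    BASE = "https://api.crossref.org/works"

    def __init__(self, cache_dir: str | Path | None = None, rate_limit_per_sec: float = 2.0):
        self._cache = ResponseCache(cache_dir)
        self._limiter = RateLimiter(rate_limit_per_sec)

    def lookup(self, doi: str) -> RegistryLink:
        doi = normalize_doi(doi)
        try:
            body = _http_get(f"{self.BASE}/{doi}", {}, self._cache, self._limiter)
        except SourceError:
            raise
        try:
            message = json.loads(body).get("message", {})
        except json.JSONDecodeError:
            return RegistryLink(preprint_doi=doi)
        return parse_crossref_work(message, doi)


class RxivServer:  # pragma: no cover - network client
    BASE = "https://api.biorxiv.org/details"

    def __init__(
        self, server: str = "biorxiv", cache_dir: str | Path | None = None,
        rate_limit_per_sec: float = 1.0,
    ):
        self._server = server
        self._cache = ResponseCache(cache_dir)
        self._limiter = RateLimiter(rate_limit_per_sec)

    def lookup(self, doi: str) -> Optional[str]:
        doi = normalize_doi(doi)
        body = _http_get(f"{self.BASE}/{self._server}/{doi}", {}, self._cache, self._limiter)
        try:
            published = parse_rxiv_details(json.loads(body))
        except json.JSONDecodeError:
            return None
        return normalize_doi(published) if published else None
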