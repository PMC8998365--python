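"""Core record types, DOI normalization, and (de)serialization.

Every module trades in these types:

* :class:`AuthorName` — one author, with a canonical comparison form.
* :class:`PreprintRecord` — the query object: a preprint's metadata plus any
  already-known journal link and where that link came from.
* :class:`CandidateArticle` — one journal-article record returned by a search.
* :class:`LinkRecord` — an accepted preprint→journal link with a source tag.
* :class:`MatchDecision` — the full audit trail of one matching attempt.

DOIs are compared by normalized form only (lowercase, URL prefix stripped).
Normalization deliberately never "repairs" a DOI — truncated identifiers seen
in the wild must stay distinct from the correct ones so that evaluation
counts them as mismatches.

Serialized formats are plain text: JSONL (one record per line) and CSV with a
fixed header; author lists serialize as ``;``-joined ``family|given`` pairs
and dates as ISO-8601 ``YYYY-MM-DD``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .errors import ConsistencyError, InvalidDOIError, InvalidNameError, SchemaError
from .textnorm import standardize_name

__all__ = [
    "Server",
    "LinkSource",
    "Route",
    "AuthorRule",
    "AuthorName",
    "PreprintRecord",
    "CandidateArticle",
    "LinkRecord",
    "MatchDecision",
    "normalize_doi",
    "authors_to_str",
    "authors_from_str",
    "read_records",
    "write_records",
    "read_articles",
    "write_articles",
    "read_links",
    "write_links",
]


class Server(str, Enum):
    BIORXIV = "biorxiv"
    MEDRXIV = "medrxiv"
    OTHER = "other"


class LinkSource(str, Enum):
    """Where an accepted link came from, in cascade priority order."""

    SERVER = "server"
    CROSSREF = "crossref"
    PRE2PUB = "pre2pub"


class Route(str, Enum):
    """Which search route a matching attempt took."""

    TITLE_FIRST = "title_first"
    AUTHOR_FIRST = "author_first"
    NONE = "none"


class AuthorRule(str, Enum):
    """The author-list comparison rule that fired (title route diagnostics)."""

    POSITIONAL = "positional"
    CONSENSUS_MAJORITY = "consensus_majority"
    FIRST_THREE = "first_three"
    FIRST_AND_LAST = "first_and_last"
    FIRST_LAST_ANYWHERE = "first_last_anywhere"


_DOI_RE = re.compile(r"^10\.[^/\s]+/\S+$")


def normalize_doi(raw: str) -> str:
    """Canonicalize a DOI: strip URL prefix/whitespace, lowercase.

    The result always matches ``10.<registrant>/<suffix>``. Raises
    :class:`InvalidDOIError` when no ``10.`` prefix (with a suffix) is found.
    Idempotent: normalizing a normalized DOI is a no-op.
    """
    s = str(raw).strip().lower()
    idx = s.find("10.")
    if idx < 0:
        raise InvalidDOIError(f"no '10.' prefix found in {raw!r}")
    s = s[idx:]
    if not _DOI_RE.match(s):
        raise InvalidDOIError(f"not a DOI after normalization: {raw!r}")
    return s


@dataclass(frozen=True)
class AuthorName:
    """One author. ``family`` is required whenever any content is present;
    ``given`` may be full given names or initials, exactly as received."""

    family: str
    given: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        if self.raw and not self.family.strip():
            raise InvalidNameError(f"author with raw form {self.raw!r} has empty family name")

    @classmethod
    def parse(cls, raw: str) -> "AuthorName":
        """Parse ``"Family, Given"`` or ``"Given Family"`` (last token = family)."""
        text = raw.strip()
        if not text:
            raise InvalidNameError("empty author name")
        if "," in text:
            family, _, given = text.partition(",")
            return cls(family=family.strip(), given=given.strip(), raw=raw)
        parts = text.split()
        if len(parts) == 1:
            return cls(family=parts[0], raw=raw)
        return cls(family=parts[-1], given=" ".join(parts[:-1]), raw=raw)

    @property
    def normalized(self) -> str:
        """Canonical comparison form, ``"family given"`` (see textnorm)."""
        return standardize_name(self.family, self.given)


def authors_to_str(authors: Sequence[AuthorName]) -> str:
    return ";".join(f"{a.family}|{a.given}" for a in authors)


def authors_from_str(text: str) -> list[AuthorName]:
    out: list[AuthorName] = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        family, _, given = chunk.partition("|")
        out.append(AuthorName(family=family.strip(), given=given.strip()))
    return out


def _parse_date(value: str | _dt.date | None) -> Optional[_dt.date]:
    if value is None or value == "":
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


@dataclass
class PreprintRecord:
    """One preprint's metadata, plus any already-known journal link."""

    doi: str
    title: str
    abstract: str = ""
    authors: list[AuthorName] = field(default_factory=list)
    publication_date: Optional[_dt.date] = None
    server: Server = Server.OTHER
    covid_related: bool = False
    linked_journal_doi: Optional[str] = None
    link_source: Optional[LinkSource] = None

    def __post_init__(self) -> None:
        self.doi = normalize_doi(self.doi)
        if self.linked_journal_doi is not None:
            self.linked_journal_doi = normalize_doi(self.linked_journal_doi)
        if (self.linked_journal_doi is None) != (self.link_source is None):
            raise ConsistencyError(
                f"{self.doi}: linked_journal_doi and link_source must be set together"
            )
        self.server = Server(self.server)
        if self.link_source is not None:
            self.link_source = LinkSource(self.link_source)
        self.publication_date = _parse_date(self.publication_date)


@dataclass
class CandidateArticle:
    """One journal-article record retrieved from a search route."""

    pmid: str
    title: str
    abstract: str = ""
    authors: list[AuthorName] = field(default_factory=list)
    publication_date: Optional[_dt.date] = None
    doi: Optional[str] = None

    def __post_init__(self) -> None:
        if not str(self.pmid).strip():
            raise ConsistencyError("candidate article requires a non-empty pmid")
        self.pmid = str(self.pmid)
        if self.doi is not None:
            self.doi = normalize_doi(self.doi)
        self.publication_date = _parse_date(self.publication_date)


@dataclass(frozen=True)
class LinkRecord:
    """An accepted preprint→journal link and the stage that produced it."""

    preprint_doi: str
    journal_doi: str
    source: LinkSource
    resolved_at: _dt.datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "preprint_doi", normalize_doi(self.preprint_doi))
        object.__setattr__(self, "journal_doi", normalize_doi(self.journal_doi))
        object.__setattr__(self, "source", LinkSource(self.source))
        if self.preprint_doi == self.journal_doi:
            raise ConsistencyError(f"link maps {self.preprint_doi} onto itself")


@dataclass
class MatchDecision:
    """Audit trail of one matching attempt, including rejections.

    Invariants: ``accepted`` implies a candidate is present, the date check
    passed, and the abstract similarity is strictly above threshold; the
    title route records which author rule fired, the author route records the
    title similarity.
    """

    preprint_doi: str
    route: Route
    accepted: bool
    candidate: Optional[CandidateArticle] = None
    author_rule_fired: Optional[AuthorRule] = None
    title_similarity: Optional[float] = None
    abstract_similarity: Optional[float] = None
    date_ok: Optional[bool] = None
    missing_abstract: bool = False

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        if self.author_rule_fired is not None:
            self.author_rule_fired = AuthorRule(self.author_rule_fired)
        if self.accepted:
            if self.candidate is None or self.date_ok is not True:
                raise ConsistencyError(f"{self.preprint_doi}: accepted decision missing evidence")
            if self.route is Route.TITLE_FIRST and self.author_rule_fired is None:
                raise ConsistencyError(f"{self.preprint_doi}: title route accepted without a rule")
            if self.route is Route.AUTHOR_FIRST and self.title_similarity is None:
                raise ConsistencyError(
                    f"{self.preprint_doi}: author route accepted without a title score"
                )

    def to_json(self) -> str:
        """One-line JSON form for the audit log; stable key order."""
        d = {
            "preprint_doi": self.preprint_doi,
            "route": self.route.value,
            "accepted": self.accepted,
            "candidate_pmid": self.candidate.pmid if self.candidate else None,
            "candidate_doi": self.candidate.doi if self.candidate else None,
            "author_rule_fired": self.author_rule_fired.value if self.author_rule_fired else None,
            "title_similarity": self.title_similarity,
            "abstract_similarity": self.abstract_similarity,
            "date_ok": self.date_ok,
            "missing_abstract": self.missing_abstract,
        }
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# Serialization

PREPRINT_FIELDS = [
    "doi",
    "title",
    "abstract",
    "authors",
    "publication_date",
    "server",
    "covid_related",
    "linked_journal_doi",
    "link_source",
]

ARTICLE_FIELDS = ["pmid", "doi", "title", "abstract", "authors", "publication_date"]

LINK_FIELDS = ["preprint_doi", "journal_doi", "source", "resolved_at"]

_TRUTHY = {"true", "1", "yes"}


def _record_to_dict(rec: PreprintRecord) -> dict:
    return {
        "doi": rec.doi,
        "title": rec.title,
        "abstract": rec.abstract,
        "authors": authors_to_str(rec.authors),
        "publication_date": rec.publication_date.isoformat() if rec.publication_date else "",
        "server": rec.server.value,
        "covid_related": str(rec.covid_related).lower(),
        "linked_journal_doi": rec.linked_journal_doi or "",
        "link_source": rec.link_source.value if rec.link_source else "",
    }


def _record_from_dict(d: dict, where: str) -> PreprintRecord:
    for key in ("doi", "title"):
        if key not in d or d[key] in (None, ""):
            raise SchemaError(f"{where}: missing required field '{key}'")
    return PreprintRecord(
        doi=d["doi"],
        title=d["title"],
        abstract=d.get("abstract") or "",
        authors=authors_from_str(d.get("authors") or ""),
        publication_date=_parse_date(d.get("publication_date") or None),
        server=Server(d.get("server") or "other"),
        covid_related=str(d.get("covid_related") or "false").lower() in _TRUTHY,
        linked_journal_doi=d.get("linked_journal_doi") or None,
        link_source=LinkSource(d["link_source"]) if d.get("link_source") else None,
    )


def _article_to_dict(art: CandidateArticle) -> dict:
    return {
        "pmid": art.pmid,
        "doi": art.doi or "",
        "title": art.title,
        "abstract": art.abstract,
        "authors": authors_to_str(art.authors),
        "publication_date": art.publication_date.isoformat() if art.publication_date else "",
    }


def _article_from_dict(d: dict, where: str) -> CandidateArticle:
    for key in ("pmid", "title"):
        if key not in d or d[key] in (None, ""):
            raise SchemaError(f"{where}: missing required field '{key}'")
    return CandidateArticle(
        pmid=d["pmid"],
        doi=d.get("doi") or None,
        title=d["title"],
        abstract=d.get("abstract") or "",
        authors=authors_from_str(d.get("authors") or ""),
        publication_date=_parse_date(d.get("publication_date") or None),
    )


def _iter_rows(path: str | Path, fmt: str) -> Iterator[tuple[dict, str]]:
    path = Path(path)
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    yield json.loads(line), f"{path.name}:{lineno}"
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                yield {k: v for k, v in row.items() if k is not None}, f"{path.name}:{lineno}"
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'jsonl' or 'csv')")


def read_records(path: str | Path, fmt: str = "jsonl") -> list[PreprintRecord]:
    """Read preprint records from JSONL or headed CSV; unknown fields ignored."""
    return [_record_from_dict(d, where) for d, where in _iter_rows(path, fmt)]


def write_records(records: Iterable[PreprintRecord], path: str | Path, fmt: str = "jsonl") -> None:
    _write_rows((_record_to_dict(r) for r in records), path, fmt, PREPRINT_FIELDS)


def read_articles(path: str | Path, fmt: str = "jsonl") -> list[CandidateArticle]:
    return [_article_from_dict(d, where) for d, where in _iter_rows(path, fmt)]


def write_articles(articles: Iterable[CandidateArticle], path: str | Path, fmt: str = "jsonl") -> None:
    _write_rows((_article_to_dict(a) for a in articles), path, fmt, ARTICLE_FIELDS)


def _write_rows(rows: Iterable[dict], path: str | Path, fmt: str, fields: list[str]) -> None:
    path = Path(path)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for row in rows:
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'jsonl' or 'csv')")


def write_links(links: Iterable[LinkRecord], path: str | Path) -> None:
    """Write accepted links as headed CSV; round-trips through :func:`read_links`."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LINK_FIELDS)
        for link in links:
            writer.writerow(
                [link.preprint_doi, link.journal_doi, link.source.value,
                 link.resolved_at.isoformat()]
            )


def read_links(path: str | Path) -> list[LinkRecord]:
    out: list[LinkRecord] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "preprint_doi" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing required column 'preprint_doi'")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    LinkRecord(
                        preprint_doi=row["preprint_doi"],
                        journal_doi=row["journal_doi"],
                        source=LinkSource(row["source"]),
                        resolved_at=_dt.datetime.fromisoformat(row["resolved_at"]),
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"{path}:{lineno}: missing required field {exc}") from exc
    return out
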