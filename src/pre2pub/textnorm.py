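"""Title cleaning and author-name standardization.

Search queries are built from *cleaned* titles: lowercased, punctuation
replaced by spaces (never deleted, so hyphenated tokens do not glue
together), stopwords removed. Author names are compared in a canonical
``"family given"`` form with diacritics folded; initials are kept verbatim —
robustness against ``"k."`` vs ``"karl"`` is the job of the downstream
Levenshtein ratio, not of normalization.

The stopword list is frozen package data (``data/stopwords_en.txt``) so runs
are hermetic and reproducible; a newline-delimited file can be supplied to
override it.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import InvalidNameError

__all__ = [
    "StopwordList",
    "load_stopwords",
    "clean_title",
    "fold_text",
    "standardize_name",
    "standardize_author",
]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")
_SPACES = re.compile(r"\s+")


@dataclass(frozen=True)
class StopwordList:
    """A frozen set of lowercase stopword tokens plus a tag naming the edition."""

    words: frozenset[str]
    source_tag: str = "custom"

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("stopword list must be non-empty")
        for w in self.words:
            if w != w.lower() or _SPACES.search(w):
                raise ValueError(f"stopword {w!r} must be lowercase with no whitespace")

    def __contains__(self, token: str) -> bool:
        return token in self.words


def load_stopwords(path: str | Path | None = None) -> StopwordList:
    """Load the packaged stopword list, or a newline-delimited override file.

    Lines starting with ``#`` are treated as comments; the first comment line
    of the packaged file carries the edition tag.
    """
    if path is None:
        text = (resources.files("pre2pub") / "data" / "stopwords_en.txt").read_text("utf-8")
        tag = "pre2pub-english-v1"
    else:
        text = Path(path).read_text("utf-8")
        tag = str(path)
    words = frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
    return StopwordList(words=words, source_tag=tag)


def fold_text(text: str) -> str:
    """Lowercase and strip diacritics (NFKD fold, combining marks removed)."""
    decomposed = unicodedata.normalize("NFKD", text.lower())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def clean_title(title: str, stopwords: StopwordList) -> str:
    """Turn a title into a search query: fold, strip punctuation, drop stopwords.

    Deterministic and idempotent on its own output; an empty title yields an
    empty query (the pipeline treats that as an unsuccessful title search).
    """
    folded = fold_text(title)
    tokens = _NON_ALNUM.sub(" ", folded).split()
    return " ".join(t for t in tokens if t not in stopwords)


def standardize_name(family: str, given: str = "") -> str:
    """Canonical comparison form: lowercase ``"family given"``, diacritics folded.

    Initials are kept as-is (``"Müller", "K."`` → ``"muller k."``); multiple
    spaces collapse to one.
    """
    if not (family.strip() or given.strip()):
        raise InvalidNameError("author name has neither family nor given part")
    combined = f"{family} {given}".strip()
    return _SPACES.sub(" ", fold_text(combined)).strip()


def standardize_author(author) -> str:
    """Standardize anything with ``.family`` / ``.given`` attributes (an AuthorName)."""
    return standardize_name(author.family, author.given)
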