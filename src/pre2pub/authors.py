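"""Fuzzy author-name similarity and the 5-rule author-list comparison.

Two standardized names are scored with the Levenshtein *ratio*:

    ratio(a, b) = (|a| + |b| - D(a, b)) / (|a| + |b|)

where ``D`` is the edit distance with insertion/deletion cost 1 and
substitution cost 2 — the variant common string-matching libraries call
``ratio``. With substitution costing as much as a delete+insert, ``D``
collapses to ``|a| + |b| - 2·LCS(a, b)``, so the ratio is computed here via a
longest-common-subsequence dynamic program. The ratio of two empty strings is
defined as 1.0, and equals 1.0 exactly when the strings are identical. A pair
of authors counts as "the same person" when the ratio is *strictly* greater
than the pair threshold (default 0.9).

Two ordered author lists match when the first of these rules succeeds, tried
in configured order:

1. ``positional`` — equal lengths and every aligned pair matches;
2. ``consensus_majority`` — walking aligned positions up to the shorter
   length, matched pairs strictly outnumber unmatched ones;
3. ``first_three`` — both lists have ≥3 authors and the first three aligned
   pairs all match;
4. ``first_and_last`` — first-vs-first and last-vs-last both match;
5. ``first_last_anywhere`` — the preprint's first and last author each match
   *some* member of the article list, at any position.

The fired rule is diagnostic; only the boolean outcome drives the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .errors import Pre2PubError
from .records import AuthorName, AuthorRule

__all__ = [
    "AuthorMatchConfig",
    "AuthorMatchResult",
    "levenshtein_ratio",
    "pair_is_same",
    "authors_match",
    "DEFAULT_RULE_ORDER",
]

DEFAULT_RULE_ORDER: tuple[AuthorRule, ...] = (
    AuthorRule.POSITIONAL,
    AuthorRule.CONSENSUS_MAJORITY,
    AuthorRule.FIRST_THREE,
    AuthorRule.FIRST_AND_LAST,
    AuthorRule.FIRST_LAST_ANYWHERE,
)


@dataclass(frozen=True)
class AuthorMatchConfig:
    pair_threshold: float = 0.9
    rule_order: tuple[AuthorRule, ...] = DEFAULT_RULE_ORDER

    def __post_init__(self) -> None:
        if not (0.0 < self.pair_threshold <= 1.0):
            raise ValueError("pair_threshold must be in (0, 1]")
        rules = tuple(AuthorRule(r) for r in self.rule_order)
        if not rules or len(set(rules)) != len(rules):
            raise ValueError("rule_order must be non-empty with no duplicates")
        object.__setattr__(self, "rule_order", rules)


@dataclass(frozen=True)
class AuthorMatchResult:
    matched: bool
    rule_fired: Optional[AuthorRule] = None
    pair_ratios: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.matched and self.rule_fired is None:
            raise ValueError("matched result must name the rule that fired")


def levenshtein_ratio(a: str, b: str) -> float:
    """Normalized similarity in [0, 1]; symmetric; 1.0 iff ``a == b``.

    Inputs are expected to be pre-standardized; no further normalization is
    applied here.
    """
    la, lb = len(a), len(b)
    if la + lb == 0:
        return 1.0
    if la == 0 or lb == 0:
        return 0.0
    # LCS length via a rolling-row DP; D = la + lb - 2*lcs under sub-cost 2.
    if lb > la:
        a, b, la, lb = b, a, lb, la
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = cur[j - 1] if cur[j - 1] >= prev[j] else prev[j]
        prev = cur
    return 2.0 * prev[lb] / (la + lb)


NameLike = Union[AuthorName, str]


def _normalize(name: NameLike) -> str:
    return name.normalized if isinstance(name, AuthorName) else name


def pair_is_same(a: NameLike, b: NameLike, cfg: AuthorMatchConfig | None = None) -> bool:
    """Strictly-greater-than comparison of the ratio against the threshold."""
    cfg = cfg or AuthorMatchConfig()
    return levenshtein_ratio(_normalize(a), _normalize(b)) > cfg.pair_threshold


def authors_match(
    pre_authors: Sequence[NameLike],
    art_authors: Sequence[NameLike],
    cfg: AuthorMatchConfig | None = None,
) -> AuthorMatchResult:
    """Compare two ordered author lists; first successful rule wins."""
    cfg = cfg or AuthorMatchConfig()
    if not pre_authors or not art_authors:
        raise Pre2PubError("authors_match requires two non-empty author lists")
    pre = [_normalize(a) for a in pre_authors]
    art = [_normalize(a) for a in art_authors]
    thr = cfg.pair_threshold

    n_aligned = min(len(pre), len(art))
    ratios = tuple(levenshtein_ratio(pre[i], art[i]) for i in range(n_aligned))
    aligned_ok = [r > thr for r in ratios]

    def positional() -> bool:
        return len(pre) == len(art) and all(aligned_ok)

    def consensus_majority() -> bool:
        matched = sum(aligned_ok)
        return matched > n_aligned - matched

    def first_three() -> bool:
        return len(pre) >= 3 and len(art) >= 3 and all(aligned_ok[:3])

    def first_and_last() -> bool:
        return (
            levenshtein_ratio(pre[0], art[0]) > thr
            and levenshtein_ratio(pre[-1], art[-1]) > thr
        )

    def first_last_anywhere() -> bool:
        first_found = any(levenshtein_ratio(pre[0], x) > thr for x in art)
        last_found = any(levenshtein_ratio(pre[-1], x) > thr for x in art)
        return first_found and last_found

    predicates = {
        AuthorRule.POSITIONAL: positional,
        AuthorRule.CONSENSUS_MAJORITY: consensus_majority,
        AuthorRule.FIRST_THREE: first_three,
        AuthorRule.FIRST_AND_LAST: first_and_last,
        AuthorRule.FIRST_LAST_ANYWHERE: first_last_anywhere,
    }
    for rule in cfg.rule_order:
        if predicates[rule]():
            return AuthorMatchResult(matched=True, rule_fired=rule, pair_ratios=ratios)
    return AuthorMatchResult(matched=False, pair_ratios=ratios)
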