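"""Independent brute-force oracles used by the test suite.

Deliberately written against the *definitions*, not the library code paths:
the edit distance here is the classic weighted dynamic program (insert and
delete cost 1, substitute cost 2), whereas the library computes the same
ratio through a longest-common-subsequence recurrence; the author-rule
oracle evaluates all five list predicates directly and independently.
"""

from __future__ import annotations


def edit_distance_sub2(a: str, b: str) -> int:
    """Weighted edit distance: ins/del cost 1, substitution cost 2."""
    m, n = len(a), len(b)
    dp = list(range(n + 1))
    for i in range(1, m + 1):
        prev_diag = dp[0]
        dp[0] = i
        for j in range(1, n + 1):
            cur = dp[j]
            sub = prev_diag + (0 if a[i - 1] == b[j - 1] else 2)
            dp[j] = min(dp[j] + 1, dp[j - 1] + 1, sub)
            prev_diag = cur
    return dp[n]


def ratio_oracle(a: str, b: str) -> float:
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return (total - edit_distance_sub2(a, b)) / total


def author_rules_oracle(pre: list[str], art: list[str], threshold: float = 0.9) -> dict[str, bool]:
    """Evaluate all five author-list predicates directly on normalized names."""

    def same(x: str, y: str) -> bool:
        return ratio_oracle(x, y) > threshold

    n = min(len(pre), len(art))
    aligned = [same(pre[i], art[i]) for i in range(n)]
    matched = sum(aligned)
    return {
        "positional": len(pre) == len(art) and all(aligned),
        "consensus_majority": matched > n - matched,
        "first_three": len(pre) >= 3 and len(art) >= 3 and all(aligned[:3]),
        "first_and_last": same(pre[0], art[0]) and same(pre[-1], art[-1]),
        "first_last_anywhere": (
            any(same(pre[0], x) for x in art) and any(same(pre[-1], x) for x in art)
        ),
    }


def confusion_oracle(items: list[tuple[str, str | None]]) -> tuple[int, int, int]:
    """(tp, fp, fn) from (gold, predicted) pairs, recounted from scratch."""
    tp = fp = fn = 0
    for gold, predicted in items:
        if predicted is None:
            fn += 1
        elif predicted == gold:
            tp += 1
        else:
            fp += 1
            fn += 1
    return tp, fp, fn
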