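"""Walk through the fuzzy author-list comparison rules.

Shows the Levenshtein ratio on name pairs (threshold 0.9, strict) and which
of the five list rules fires for typical preprint-vs-journal author list
differences: reordered middle authors, truncated lists, added collaborators.
"""

from pre2pub import AuthorName, authors_match, levenshtein_ratio, standardize_author

pairs = [
    ("Alvarez, Maria", "Alvarez, Maria"),
    ("Alvarez, Maria", "Alvarez, Mario"),   # one letter off, long names
    ("Chen, Wei", "Chen, W."),              # initials vs full given name
    ("Müller, Karl", "Muller, Karl"),       # diacritic folded away
]
print("pairwise Levenshtein ratios (match requires ratio > 0.9):")
for a, b in pairs:
    na = standardize_author(AuthorName.parse(a))
    nb = standardize_author(AuthorName.parse(b))
    r = levenshtein_ratio(na, nb)
    print(f"  {na!r:22} vs {nb!r:22} -> {r:.3f} {'match' if r > 0.9 else 'no match'}")

A, B, C, D, X, Y = (AuthorName.parse(n) for n in (
    "Alvarez, Maria", "Bianchi, Luca", "Chen, Wei",
    "Dubois, Claire", "Xu, Ming", "Yamada, Kenji",
))
cases = [
    ("identical lists", [A, B, C], [A, B, C]),
    ("one middle author changed", [A, B, C], [A, X, C]),
    ("middle authors replaced", [A, B, C, D], [A, X, Y, D]),
    ("first and last shuffled into a longer list", [A, B], [X, B, Y, A]),
    ("different teams", [A, B], [X, Y]),
]
print("\nlist comparison (first rule to succeed wins):")
for label, pre, art in cases:
    res = authors_match(pre, art)
    fired = res.rule_fired.value if res.matched else "-"
    print(f"  {label:45} matched={res.matched!s:5} rule={fired}")
print()
print("The positional rule handles unchanged lists; the fallbacks absorb the")
print("author-list edits journals routinely introduce, while fully different")
print("teams never match.")
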