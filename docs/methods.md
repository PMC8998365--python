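# Methods

## Problem and model

`pre2pub` performs record linkage between two bibliographic sources: a
preprint record (DOI, title, abstract, ordered author list, posting date,
server, COVID flag) and journal-article records retrievable from a
literature search index (PMID, DOI, title, abstract, authors, date). Two
records are declared the same study when they survive a conjunction of
checks — candidate retrieval, author-list (or title) verification, date
ordering, and abstract similarity — each individually permissive but jointly
strict. The stack is tuned so that errors fall on the false-negative side: a
missed link hides information a reader could find manually; a wrong link
actively misleads.

Link resolution is a cascade with a freeze rule. Authoritative sources
(preprint-server metadata, then the registry's is-preprint-of relation) are
consulted before the matching algorithm, the winning stage is recorded as a
source tag, and on refresh passes authoritative links are never re-opened;
algorithmic links are re-checked against the authoritative sources and
replaced the moment one of them answers, and unlinked preprints go through
the full cascade again. `update_links` is a pure function over a link
store; scheduling is the caller's concern.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `source.retmax` | 5 | candidates kept per search; deliberately small to cap false-positive exposure |
| `author.pair_threshold` | 0.9 | strict (`>`) lower bound on the name-pair Levenshtein ratio |
| `author.rule_order` | positional, consensus_majority, first_three, first_and_last, first_last_anywhere | fallback order of the list rules; first success wins |
| `similarity.title_threshold` | 0.95 | inclusive (`≥`) cosine bound for the author-route title check |
| `similarity.abstract_threshold` | 0.9 | strict (`>`) cosine bound for the final abstract check |
| `similarity.hash_dim` | 512 | bucket count of the hashed 3-gram backend |
| `date_strictness` | strictly_older | preprint must predate the article; `older_or_equal` available because same-day pairs occur in practice |

Threshold strictness was a genuinely open choice: the abstract check is
strict (the accept condition is that the score *exceeds* the threshold) and
is applied strictly here; the title bound's direction is not similarly
pinned, so it is inclusive. Both are configurable, and boundary behaviour
is unit-tested at exact equality.

## Levenshtein ratio

"Levenshtein ratio" is implemented as the substitution-cost-2 variant
`(|a|+|b|−D)/(|a|+|b|)` — the meaning the term carries in the common string
matching libraries of this ecosystem. With substitution costing a
delete-plus-insert, `D = |a|+|b|−2·LCS(a,b)`, so the implementation runs a
longest-common-subsequence dynamic program; the test oracle independently
computes the weighted edit distance. The ratio of two empty strings is
defined as 1.0; the ratio is 1.0 exactly for identical strings, which makes
the pair predicate reflexive at any threshold ≤ 1. The alternative reading
(`1 − D/max(|a|,|b|)`) can be swapped in behind the same operation without
touching the rules.

Author names are standardized to lowercase `"family given"` with diacritics
folded and spaces collapsed; initials are kept verbatim (no expansion).
Initials-only names fall well below the 0.9 pair threshold against full
given names (e.g. `chen w.` vs `chen wei` scores 0.8), which is why the
pipeline enriches preprint author lists with the registry's complete names
when available — enrichment is a workaround, not a dependency, and the
comparison falls back to the server-provided names when the registry has
nothing.

List-rule semantics where the rules underdetermine edge cases: the
positional rule requires equal lengths; the consensus rule walks aligned
positions up to the shorter length, ignores the surplus of the longer list,
and requires a *strict* majority (ties fail); the first/last-anywhere rule
allows one article author to satisfy both ends when the preprint has a
single author. The fired rule is diagnostic only — the pipeline consumes
the boolean.

## Embedding backends

The hermetic default embeds text as signed counts of character 3-grams
hashed (BLAKE2b, stable across processes and platforms) into a fixed-width
vector, L2-normalized; text is lowercased and whitespace-collapsed first,
so the embedding is deterministic and case/spacing-insensitive. Empty text
embeds to the zero vector; cosine of two zero vectors is an undefined-
similarity error which every caller treats as a non-match, and a zero
vector against anything else scores 0 — a candidate with a missing abstract
is excluded from the final argmax rather than scored, so it can never win,
and a preprint with no abstract produces a rejected decision flagged
`missing_abstract` rather than an exception.

An optional sentence-transformer backend loads the pretrained biomedical
model family the default thresholds were calibrated for. It satisfies the
same contract (deterministic, fixed dimensionality, finite entries) and is
never used in the test path; swapping backends changes scores, never the
accept/reject logic.

## Candidate retrieval

The fixture search source emulates a field-restricted search engine
deterministically: title queries rank an exact cleaned-title match first,
then token-set Jaccard overlap (a hit requires ≥ 0.5), ties broken by PMID;
author queries rank by the number of query authors present in the article's
list, where presence is folded family name plus first given-initial (so
initials-only queries still hit full-name records). `unindexed_title_pmids`
reproduces a documented real-world quirk — an article present in the index
but not retrievable through the title field — and is how tests exercise the
author-search fallback route. Live clients (E-utilities search, registry
works lookup, server details endpoint) implement the same contracts behind
a rate limiter, an on-disk response cache keyed by endpoint and query, and
three retry attempts with exponential backoff; their response parsing is
factored into pure functions tested on canned payloads.

Tie-breaking at the final argmax (two candidates with identical maximal
abstract scores) keeps the earlier source rank, making decisions
deterministic byte-for-byte for fixed inputs.

## Evaluation conventions

The confusion convention is asymmetric: correct DOI → TP; no prediction →
FN; wrong DOI → FP **and** FN. Consequently `tp + fn` always equals the
number of gold pairs, and the resulting F1 is not comparable with the
symmetric convention — corrupting k correct predictions raises both FP and
FN by exactly k, a metamorphic property the tests check end-to-end.
Percentages are rounded half-away-from-zero to 2 decimals, the rule that
reproduces every published republication percentage exactly from its
printed numerator and denominator. Precision/recall with zero denominators
raise an undefined-metric error rather than returning a sentinel. Year
assignment for republication rates uses the preprint's posting date, never
the journal date.

## Synthetic corpus

The generator emulates corpus *structure*, not scientific prose: documents
draw a 30-word topic from a fixed 900-pseudo-word lexicon shipped as
package data (titles 6–14 tokens, abstracts 80–150 tokens — long enough for
3-gram profiles to separate unrelated documents). Defaults describe the
study conditions: 60% of preprints published, of which the server link
table covers 25 points and the registry 15 (disjoint strata, so the cascade
priority is observable from source tags); initials-only preprint author
names with full names in the registry and the journal records; one token
substituted per twin title; 5% token dropout per twin abstract; one
same-first-and-last-author decoy per preprint; journal dates 30–365 days
after posting; 20% COVID-flagged. A single seeded RNG stream drives
generation in a documented per-preprint draw order, and twin-perturbation
draws are consumed even for unpublished preprints so stratum boundaries do
not reshuffle later records.

`tolerance_envelope` brute-forces, one perturbation axis at a time, the
largest settings at which *every* planted twin still passes both similarity
thresholds on a given backend. On the hashed backend the abstract check
tolerates at least 30% token dropout, while the 0.95 title bound tolerates
no token substitutions on titles this short — one substituted token in a
6-token title moves too much of its 3-gram mass. That asymmetry is the
backend's, not the pipeline's: perturbed titles are still found by the
title *search* (token overlap well above 0.5), verified by authors, and
accepted on the abstract score, so end-to-end recall survives title edits
the embedding bound would reject, and precision is unaffected either way.

What the generator does not emulate — and hence what passing tests do not
show about real corpora: natural-language paraphrase between preprint and
journal abstracts (pseudo-word dropout is a crude stand-in), journals not
covered by the search index (the dominant real source of false negatives),
truncated or wrong gold links in server metadata, author disambiguation
beyond name strings, and the day-to-day drift of live search indexes.

## Problem sizes and numerical checks

The test suite runs the author-rule oracle exhaustively over all list pairs
of lengths ≤ 2 from a 6-name pool plus 3000 seeded random instances up to
4 authors a side; the ratio against an independent DP oracle on 10,000
random string pairs; the confusion convention against a brute-force recount
on 1000-pair fixtures; and the end-to-end cascade on 200-preprint corpora
(zero-perturbation: 100% recall at precision 1.0; perturbed inside the
envelope and at study conditions: precision 1.0). The acceptance script
uses the same 200-preprint corpus size and reconstructs the published
stratum counts (30,094–40,862 records per stratum) as in-memory records to
recompute the derived percentages through the library.

## Known limitations

* The matcher requires the journal version to be indexed by the search
  source; links to journals outside the index are unreachable by design.
* DOI normalization canonicalizes case and URL prefixes but never repairs
  truncated identifiers; a broken gold DOI therefore counts as a mismatch.
* The hashed backend measures lexical, not semantic, similarity; its
  thresholds inherit the published values, which were calibrated for a
  transformer backend. The contract isolates this choice.
* `update_links` trusts authoritative sources unconditionally; a wrong
  server-provided link is frozen, mirroring the curation policy it models.
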