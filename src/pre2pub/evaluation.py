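"""Evaluation: confusion counting, precision/recall/F1, splits, corpus stats.

The counting convention is asymmetric, and deliberately so: for each
gold-standard preprint→journal pair,

* predicted DOI equals the gold DOI → one true positive;
* no prediction → one false negative;
* a *different* DOI → one false positive **and** one false negative.

A wrong link therefore costs twice, which makes the resulting F1 slightly
stricter than (and not comparable with) the usual symmetric convention.
Precision is favoured over recall by design: a missing link merely hides
information, a wrong link spreads misinformation.

All reported percentages are rounded half-away-from-zero to 2 decimals,
which reproduces every printed republication percentage exactly from its
printed numerator/denominator.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Set

import pandas as pd

from .errors import SchemaError, UndefinedMetricError
from .records import PreprintRecord, normalize_doi

__all__ = [
    "ConfusionCounts",
    "GoldPair",
    "VennCounts",
    "round_half_up",
    "count_confusion",
    "precision_recall_f1",
    "f1_from_percentages",
    "split_train_test",
    "publication_rate",
    "rate_percent",
    "venn_counts",
    "count_by_year",
    "read_gold_tsv",
    "read_predictions_tsv",
    "write_predictions_tsv",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (68.955 → 68.96), not banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class GoldPair:
    """One evaluation item: the gold journal DOI and the system's prediction."""

    preprint_doi: str
    journal_doi: str
    predicted_doi: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "preprint_doi", normalize_doi(self.preprint_doi))
        object.__setattr__(self, "journal_doi", normalize_doi(self.journal_doi))
        if self.predicted_doi is not None:
            object.__setattr__(self, "predicted_doi", normalize_doi(self.predicted_doi))


def count_confusion(pairs: Sequence[GoldPair]) -> ConfusionCounts:
    """Tally TP/FP/FN under the asymmetric convention (wrong DOI counts twice)."""
    tp = fp = fn = 0
    for pair in pairs:
        if pair.journal_doi is None:
            raise SchemaError(f"{pair.preprint_doi}: gold journal DOI is required")
        if pair.predicted_doi is None:
            fn += 1
        elif pair.predicted_doi == pair.journal_doi:
            tp += 1
        else:
            fp += 1
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Percentages rounded to 2 decimals; F1 computed from unrounded P and R."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predictions made")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no gold pairs")
    p = 100.0 * c.tp / (c.tp + c.fp)
    r = 100.0 * c.tp / (c.tp + c.fn)
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    f1 = 2 * p * r / (p + r)
    return round_half_up(p), round_half_up(r), round_half_up(f1)


def f1_from_percentages(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of already-printed percentages, rounded to 2 decimals."""
    if precision_pct + recall_pct == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    return round_half_up(2 * precision_pct * recall_pct / (precision_pct + recall_pct))


def split_train_test(
    gold: Sequence[GoldPair], n_each: int, seed: int
) -> tuple[list[GoldPair], list[GoldPair]]:
    """Disjoint random train/test sets of exactly ``n_each`` pairs each."""
    if len(gold) < 2 * n_each:
        raise ValueError(f"need at least {2 * n_each} gold pairs, have {len(gold)}")
    order = list(gold)
    random.Random(seed).shuffle(order)
    return order[:n_each], order[n_each : 2 * n_each]


def rate_percent(published: int, total: int) -> float:
    if total == 0:
        raise UndefinedMetricError("publication rate undefined for zero records")
    return round_half_up(100.0 * published / total)


def publication_rate(
    records: Iterable[PreprintRecord], year: int, covid_flag: Optional[bool] = None
) -> tuple[int, int, float]:
    """(total, published, percent) for preprints *posted* in ``year``.

    Year assignment uses the preprint's posting date, never the journal date;
    ``covid_flag`` filters when given. A preprint counts as published when it
    carries a journal link, from any source.
    """
    total = published = 0
    for rec in records:
        if rec.publication_date is None or rec.publication_date.year != year:
            continue
        if covid_flag is not None and rec.covid_related != covid_flag:
            continue
        total += 1
        if rec.linked_journal_doi is not None:
            published += 1
    return total, published, rate_percent(published, total)


@dataclass(frozen=True)
class VennCounts:
    """Set sizes for three link-finding methods and all their intersections."""

    totals: Mapping[str, int]
    pairwise: Mapping[frozenset, int]
    triple: int
    unique: Mapping[str, int]
    union_total: int

    def check_inclusion_exclusion(self) -> None:
        methods = list(self.totals)
        total = sum(self.totals.values())
        total -= sum(self.pairwise[frozenset((a, b))]
                     for i, a in enumerate(methods) for b in methods[i + 1 :])
        total += self.triple
        if total != self.union_total:
            raise AssertionError("inclusion-exclusion violated")


def venn_counts(links_by_method: Mapping[str, Set[str]]) -> VennCounts:
    """Exact set algebra over per-method sets of linked preprint DOIs."""
    if len(links_by_method) != 3:
        raise ValueError("venn_counts expects exactly three methods")
    methods = list(links_by_method)
    sets = {m: set(links_by_method[m]) for m in methods}
    totals = {m: len(sets[m]) for m in methods}
    pairwise = {
        frozenset((a, b)): len(sets[a] & sets[b])
        for i, a in enumerate(methods)
        for b in methods[i + 1 :]
    }
    triple = len(sets[methods[0]] & sets[methods[1]] & sets[methods[2]])
    union = set().union(*sets.values())
    unique = {
        m: len(sets[m] - set().union(*(sets[o] for o in methods if o != m))) for m in methods
    }
    vc = VennCounts(
        totals=totals, pairwise=pairwise, triple=triple, unique=unique, union_total=len(union)
    )
    vc.check_inclusion_exclusion()
    return vc


_GROUPERS = {
    "year": lambda r: r.publication_date.year if r.publication_date else None,
    "covid_flag": lambda r: r.covid_related,
    "server": lambda r: r.server.value,
    "linked": lambda r: r.linked_journal_doi is not None,
}


def count_by_year(
    records: Sequence[PreprintRecord], group_by: Sequence[str] = ("year",)
) -> pd.DataFrame:
    """Contingency counts over record attributes; marginals sum to the total.

    ``group_by`` draws from ``year``, ``covid_flag``, ``server``, ``linked``.
    """
    unknown = [g for g in group_by if g not in _GROUPERS]
    if unknown:
        raise ValueError(f"unknown grouping(s): {unknown}; choose from {sorted(_GROUPERS)}")
    if not records:
        return pd.DataFrame(columns=[*group_by, "n"])
    rows = [{g: _GROUPERS[g](r) for g in group_by} for r in records]
    df = pd.DataFrame(rows)
    return df.groupby(list(group_by), dropna=False).size().rename("n").reset_index()


# ---------------------------------------------------------------------------
# Gold-standard / prediction TSV I/O


def read_gold_tsv(path: str | Path) -> list[GoldPair]:
    """``preprint_doi<TAB>journal_doi`` per line; no header."""
    out: list[GoldPair] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise SchemaError(f"{path}:{lineno}: expected preprint_doi<TAB>journal_doi")
            out.append(GoldPair(preprint_doi=parts[0], journal_doi=parts[1]))
    return out


def read_predictions_tsv(path: str | Path) -> dict[str, Optional[str]]:
    """``preprint_doi<TAB>predicted_doi`` (second field may be empty)."""
    out: dict[str, Optional[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if not parts[0].strip():
                raise SchemaError(f"{path}:{lineno}: missing preprint_doi")
            pred = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            out[normalize_doi(parts[0])] = normalize_doi(pred) if pred else None
    return out


def write_predictions_tsv(predictions: Mapping[str, Optional[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doi, pred in predictions.items():
            fh.write(f"{doi}\t{pred or ''}\n")
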