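import datetime as dt
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import confusion_oracle
from pre2pub import (
    ConfusionCounts,
    GoldPair,
    PreprintRecord,
    count_by_year,
    count_confusion,
    f1_from_percentages,
    precision_recall_f1,
    publication_rate,
    split_train_test,
    venn_counts,
)
from pre2pub.errors import UndefinedMetricError
from pre2pub.evaluation import rate_percent, round_half_up


def _pair(i, predicted):
    return GoldPair(
        preprint_doi=f"10.1101/p{i}", journal_doi=f"10.1200/g{i}",
        predicted_doi=predicted,
    )


class TestCountConfusion:
    def test_correct_prediction_is_tp(self):
        c = count_confusion([_pair(0, "10.1200/g0")])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_no_prediction_is_fn(self):
        c = count_confusion([_pair(0, None)])
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_wrong_doi_counts_twice(self):
        c = count_confusion([_pair(0, "10.1200/other")])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    @given(st.lists(st.sampled_from(["correct", "wrong", "none"]), max_size=60))
    def test_agrees_with_brute_force_recount(self, outcomes):
        pairs = [
            _pair(i, {"correct": f"10.1200/g{i}", "wrong": "10.1200/x", "none": None}[o])
            for i, o in enumerate(outcomes)
        ]
        c = count_confusion(pairs)
        items = [(p.journal_doi, p.predicted_doi) for p in pairs]
        assert (c.tp, c.fp, c.fn) == confusion_oracle(items)
        assert c.tp + c.fn == len(pairs)  # every gold pair lands in tp or fn


class TestPrecisionRecallF1:
    def test_perfect(self):
        assert precision_recall_f1(ConfusionCounts(1, 0, 0)) == (100.0, 100.0, 100.0)

    def test_zero_denominators_are_errors(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall_f1(ConfusionCounts(0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            precision_recall_f1(ConfusionCounts(0, 5, 0))

    def test_half_right_under_asymmetric_convention(self):
        # gold of 2: one correct, one wrong DOI → tp=1, fp=1, fn=1
        c = count_confusion([_pair(0, "10.1200/g0"), _pair(1, "10.1200/nope")])
        p, r, f1 = precision_recall_f1(c)
        assert (p, r, f1) == (50.0, 50.0, 50.0)

    def test_f1_is_harmonic_mean_of_reported_percentages(self):
        assert f1_from_percentages(99.27, 81.14) == 89.29

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_agrees_with_direct_recomputation(self, tp, fp, fn):
        if tp + fp == 0 or tp + fn == 0:
            return
        p, r, f1 = precision_recall_f1(ConfusionCounts(tp, fp, fn))
        assert p == round_half_up(100 * tp / (tp + fp))
        assert r == round_half_up(100 * tp / (tp + fn))


class TestRounding:
    def test_half_rounds_away_from_zero(self):
        assert round_half_up(0.125) == 0.13  # banker's would give 0.12
        assert round_half_up(68.955) == 68.96
        assert rate_percent(1, 800) == 0.13

    @pytest.mark.parametrize(
        "published,total,expected",
        [
            (22776, 30094, 75.68),
            (28177, 40862, 68.96),
            (6920, 11918, 58.06),
            (13489, 40441, 33.35),
            (3518, 9024, 38.98),
        ],
    )
    def test_reported_republication_percentages_reproduced(self, published, total, expected):
        assert rate_percent(published, total) == expected


def _records(year, n, n_linked, covid=False):
    out = []
    for i in range(n):
        linked = i < n_linked
        out.append(
            PreprintRecord(
                doi=f"10.1101/{year}.{covid:d}.{i:06d}", title="t",
                publication_date=dt.date(year, 1 + i % 12, 1),
                covid_related=covid,
                linked_journal_doi=f"10.1200/{year}.{covid:d}.{i:06d}" if linked else None,
                link_source="server" if linked else None,
            )
        )
    return out


class TestPublicationRate:
    def test_single_linked_record(self):
        recs = _records(2019, 1, 1)
        assert publication_rate(recs, 2019) == (1, 1, 100.0)

    def test_covid_flag_filters(self):
        recs = _records(2020, 40, 10, covid=False) + _records(2020, 60, 30, covid=True)
        assert publication_rate(recs, 2020, covid_flag=True) == (60, 30, 50.0)
        assert publication_rate(recs, 2020, covid_flag=False) == (40, 10, 25.0)
        assert publication_rate(recs, 2020) == (100, 40, 40.0)

    def test_year_uses_posting_date(self):
        recs = _records(2019, 5, 5)
        with pytest.raises(UndefinedMetricError):
            publication_rate(recs, 2021)


class TestSplitTrainTest:
    def test_disjoint_exact_sizes(self):
        gold = [_pair(i, None) for i in range(10)]
        train, test = split_train_test(gold, n_each=2, seed=1)
        assert len(train) == len(test) == 2
        assert not set(p.preprint_doi for p in train) & set(p.preprint_doi for p in test)

    def test_reproducible_under_seed(self):
        gold = [_pair(i, None) for i in range(20)]
        assert split_train_test(gold, 5, seed=7) == split_train_test(gold, 5, seed=7)
        assert split_train_test(gold, 5, seed=7) != split_train_test(gold, 5, seed=8)

    def test_insufficient_gold_is_size_error(self):
        with pytest.raises(ValueError):
            split_train_test([_pair(i, None) for i in range(5)], n_each=3, seed=0)


class TestVennCounts:
    def test_identical_sets_all_in_triple(self):
        s = {"a", "b", "c"}
        vc = venn_counts({"server": s, "crossref": s, "pre2pub": s})
        assert vc.triple == 3 and vc.union_total == 3
        assert all(u == 0 for u in vc.unique.values())

    def test_disjoint_sets_all_unique(self):
        vc = venn_counts({"server": {"a"}, "crossref": {"b"}, "pre2pub": {"c", "d"}})
        assert vc.triple == 0
        assert vc.unique == {"server": 1, "crossref": 1, "pre2pub": 2}
        assert vc.union_total == 4

    def test_requires_three_methods(self):
        with pytest.raises(ValueError):
            venn_counts({"a": set(), "b": set()})

    @given(st.data())
    def test_inclusion_exclusion_on_random_triples(self, data):
        universe = [f"d{i}" for i in range(30)]
        sets = {
            m: set(data.draw(st.lists(st.sampled_from(universe), max_size=30)))
            for m in ("server", "crossref", "pre2pub")
        }
        vc = venn_counts(sets)
        # independent set-algebra oracle
        a, b, c = (sets[m] for m in ("server", "crossref", "pre2pub"))
        assert vc.union_total == len(a | b | c)
        assert vc.triple == len(a & b & c)
        assert vc.unique["pre2pub"] == len(c - (a | b))


class TestCountByYear:
    def test_marginals_sum_to_total(self):
        recs = _records(2019, 7, 3) + _records(2020, 5, 2, covid=True)
        table = count_by_year(recs, group_by=("year", "covid_flag"))
        assert table["n"].sum() == 12

    def test_empty_input_empty_table(self):
        table = count_by_year([], group_by=("year",))
        assert len(table) == 0

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            count_by_year(_records(2019, 1, 0), group_by=("colour",))
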