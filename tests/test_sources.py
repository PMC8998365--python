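import datetime as dt
import json

import pytest

from pre2pub import AuthorName, CandidateArticle, RegistryLink
from pre2pub.errors import InvalidDOIError
from pre2pub.sources import (
    FixtureRegistry,
    FixtureSearchSource,
    FixtureServer,
    RateLimiter,
    ResponseCache,
    parse_crossref_work,
    parse_efetch_articles,
    parse_esearch_ids,
    parse_rxiv_details,
)


def _article(pmid, title, authors=("Chen, Wei",), date=dt.date(2020, 6, 1)):
    return CandidateArticle(
        pmid=pmid,
        title=title,
        abstract="abstract text",
        authors=[AuthorName.parse(a) for a in authors],
        publication_date=date,
    )


@pytest.fixture()
def corpus():
    shared = ["Alvarez, Maria", "Chen, Wei"]
    arts = [_article("1", "Spike protein binding kinetics", shared)]
    # seven near-duplicates of one title, to exercise the retmax cap
    arts += [
        _article(str(10 + i), f"Receptor occupancy imaging study {i}", shared) for i in range(7)
    ]
    arts += [_article("30", "Unrelated botanical survey of alpine flora", ["Yamada, Kenji"])]
    return arts


class TestFixtureSearch:
    def test_exact_title_single_hit_ranked_first(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords)
        hits = src.search_by_title("spike protein binding kinetics")
        assert [h.pmid for h in hits][:1] == ["1"]

    def test_retmax_caps_title_results(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords, retmax=5)
        hits = src.search_by_title("receptor occupancy imaging study 0")
        assert len(hits) == 5

    def test_empty_cleaned_title_is_precondition_error(self, corpus):
        with pytest.raises(ValueError):
            FixtureSearchSource(corpus).search_by_title("  ")

    def test_no_token_overlap_empty_result(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords)
        assert src.search_by_title("completely different nonexistent topic") == []

    def test_unindexed_pmid_invisible_to_title_search_only(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords, unindexed_title_pmids=("1",))
        assert src.search_by_title("spike protein binding kinetics") == []
        by_author = src.search_by_authors([AuthorName.parse("Alvarez, Maria")])
        assert "1" in [h.pmid for h in by_author]

    def test_author_search_exact_hit(self, corpus):
        src = FixtureSearchSource(corpus)
        hits = src.search_by_authors([AuthorName.parse("Yamada, Kenji")])
        assert [h.pmid for h in hits] == ["30"]

    def test_author_search_no_overlap_empty(self, corpus):
        src = FixtureSearchSource(corpus)
        assert src.search_by_authors([AuthorName.parse("Nobody, At All")]) == []

    def test_author_search_retmax_cap(self, corpus):
        src = FixtureSearchSource(corpus, retmax=5)
        hits = src.search_by_authors([AuthorName.parse("Chen, Wei")])
        assert len(hits) == 5

    def test_initials_match_full_given_names(self, corpus):
        # bioRxiv-style initials find the full-name article records
        hits = FixtureSearchSource(corpus).search_by_authors([AuthorName("Yamada", "K.")])
        assert [h.pmid for h in hits] == ["30"]

    def test_retmax_validation(self, corpus):
        with pytest.raises(ValueError):
            FixtureSearchSource(corpus, retmax=0)


class TestFixtureLookups:
    def test_registry_with_relation(self):
        reg = FixtureRegistry([RegistryLink("10.1101/1", journal_doi="10.1200/a")])
        assert reg.lookup("10.1101/1").journal_doi == "10.1200/a"

    def test_registry_without_relation(self):
        reg = FixtureRegistry([])
        link = reg.lookup("10.1101/2")
        assert link.journal_doi is None and link.full_authors is None

    def test_registry_malformed_doi(self):
        with pytest.raises(InvalidDOIError):
            FixtureRegistry([]).lookup("not-a-doi")

    def test_server_lookup_three_cases(self):
        srv = FixtureServer({"10.1101/1": "10.1200/a"})
        assert srv.lookup("10.1101/1") == "10.1200/a"
        assert srv.lookup("10.1101/2") is None
        with pytest.raises(InvalidDOIError):
            srv.lookup("broken")


class TestSourceContract:
    """Shape contract every search source must satisfy (run on the fixture)."""

    def test_results_are_candidates_within_retmax(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords, retmax=3)
        for hits in (
            src.search_by_title("receptor occupancy imaging study 1"),
            src.search_by_authors([AuthorName.parse("Chen, Wei")]),
        ):
            assert len(hits) <= 3
            for h in hits:
                assert isinstance(h, CandidateArticle) and h.pmid and h.title

    def test_deterministic_ranking(self, corpus, stopwords):
        src = FixtureSearchSource(corpus, stopwords=stopwords)
        q = "receptor occupancy imaging study 3"
        assert [h.pmid for h in src.search_by_title(q)] == [
            h.pmid for h in src.search_by_title(q)
        ]


class TestLiveClientPlumbing:
    def test_response_cache_replays_bit_identical(self, tmp_path):
        cache = ResponseCache(tmp_path)
        cache.put("https://x/api", {"q": "title"}, "payload-bytes")
        assert cache.get("https://x/api", {"q": "title"}) == "payload-bytes"
        assert cache.get("https://x/api", {"q": "other"}) is None

    def test_cache_key_depends_on_endpoint_and_query(self):
        k1 = ResponseCache.key("https://x/a", {"q": "1"})
        k2 = ResponseCache.key("https://x/b", {"q": "1"})
        k3 = ResponseCache.key("https://x/a", {"q": "2"})
        assert len({k1, k2, k3}) == 3

    def test_rate_limiter_sleeps_to_minimum_interval(self):
        limiter = RateLimiter(per_sec=2.0)
        naps = []
        limiter.wait(now=0.0, sleep=naps.append)
        limiter.wait(now=0.1, sleep=naps.append)
        assert naps == [pytest.approx(0.4)]

    def test_parse_esearch_ids(self):
        body = json.dumps({"esearchresult": {"idlist": ["123", "456"]}})
        assert parse_esearch_ids(body) == ["123", "456"]

    def test_parse_efetch_articles(self):
        xml = """<PubmedArticleSet><PubmedArticle>
          <MedlineCitation><PMID>123</PMID><Article>
            <ArticleTitle>A title</ArticleTitle>
            <Abstract><AbstractText>Part one.</AbstractText></Abstract>
            <ELocationID EIdType="doi">10.1200/abc</ELocationID>
            <AuthorList><Author><LastName>Chen</LastName><ForeName>Wei</ForeName></Author></AuthorList>
            <ArticleDate><Year>2020</Year><Month>6</Month><Day>1</Day></ArticleDate>
          </Article></MedlineCitation>
        </PubmedArticle></PubmedArticleSet>"""
        (art,) = parse_efetch_articles(xml)
        assert art.pmid == "123" and art.doi == "10.1200/abc"
        assert art.authors == [AuthorName("Chen", "Wei")]
        assert art.publication_date == dt.date(2020, 6, 1)

    def test_parse_crossref_relation_and_authors(self):
        message = {
            "relation": {"is-preprint-of": [{"id-type": "doi", "id": "10.1200/J.X"}]},
            "author": [{"family": "Chen", "given": "Wei"}],
        }
        link = parse_crossref_work(message, "10.1101/1")
        assert link.journal_doi == "10.1200/j.x"
        assert link.full_authors == (AuthorName("Chen", "Wei"),)

    def test_parse_rxiv_details(self):
        assert parse_rxiv_details({"collection": [{"published": "10.1200/a"}]}) == "10.1200/a"
        assert parse_rxiv_details({"collection": [{"published": "NA"}]}) is None
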