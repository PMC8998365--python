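import dataclasses
import json

import pytest

from pre2pub import CorpusSpec, generate, sources_from_corpus, tolerance_envelope
from pre2pub.errors import CorpusSpecError
from pre2pub.records import authors_to_str


def corpus_fingerprint(corpus):
    """Serialize everything deterministic about a corpus for byte comparison."""
    return json.dumps(
        {
            "preprints": [
                (p.doi, p.title, p.abstract, authors_to_str(p.authors),
                 str(p.publication_date), p.server.value, p.covid_related)
                for p in corpus.preprints
            ],
            "articles": [
                (a.pmid, a.doi, a.title, a.abstract, authors_to_str(a.authors),
                 str(a.publication_date))
                for a in corpus.articles
            ],
            "server_links": corpus.server_links,
            "truth": corpus.truth,
        },
        sort_keys=True,
    )


class TestSpecValidation:
    def test_fractions_must_fit_inside_published(self):
        with pytest.raises(CorpusSpecError):
            CorpusSpec(frac_published=0.3, frac_server_linked=0.2, frac_registry_linked=0.2)

    def test_fraction_range(self):
        with pytest.raises(CorpusSpecError):
            CorpusSpec(frac_published=1.2)

    def test_date_offsets_positive(self):
        with pytest.raises(CorpusSpecError):
            CorpusSpec(date_offset_days=(0, 10))


class TestGenerate:
    def test_zero_perturbation_twins_identical_except_date(self):
        spec = CorpusSpec(
            n_preprints=10, frac_published=1.0, frac_server_linked=0.0,
            frac_registry_linked=0.0, title_edit_tokens=0, abstract_dropout=0.0,
            author_style="full_given", n_decoys_per_author=0, seed=7,
        )
        corpus = generate(spec)
        assert len(corpus.truth) == 10 and all(corpus.truth.values())
        by_doi = {a.doi: a for a in corpus.articles}
        for pre in corpus.preprints:
            twin = by_doi[corpus.truth[pre.doi]]
            assert twin.title == pre.title
            assert twin.abstract == pre.abstract
            assert twin.authors == pre.authors
            assert twin.publication_date > pre.publication_date

    def test_unpublished_corpus_has_only_decoys(self):
        spec = CorpusSpec(n_preprints=8, frac_published=0.0, frac_server_linked=0.0,
                          frac_registry_linked=0.0, seed=3)
        corpus = generate(spec)
        assert all(target is None for target in corpus.truth.values())
        assert all(a.doi.startswith("10.1300/decoy") for a in corpus.articles)

    def test_same_seed_byte_identical_different_seed_not(self):
        spec = CorpusSpec(n_preprints=12, seed=11)
        assert corpus_fingerprint(generate(spec)) == corpus_fingerprint(generate(spec))
        other = dataclasses.replace(spec, seed=12)
        assert corpus_fingerprint(generate(spec)) != corpus_fingerprint(generate(other))

    def test_truth_targets_exist_and_are_unique(self):
        corpus = generate(CorpusSpec(n_preprints=30, seed=5))
        article_dois = {a.doi for a in corpus.articles}
        targets = [t for t in corpus.truth.values() if t is not None]
        assert len(targets) == len(set(targets))
        assert set(targets) <= article_dois

    def test_unpublished_preprints_have_no_twin(self):
        corpus = generate(CorpusSpec(n_preprints=30, frac_published=0.5,
                                     frac_server_linked=0.2, frac_registry_linked=0.1, seed=5))
        unpublished = {d for d, t in corpus.truth.items() if t is None}
        assert unpublished  # stratum non-empty at these settings
        twin_dois = {a.doi for a in corpus.articles if not a.doi.startswith("10.1300/decoy")}
        assert len(twin_dois) == len(corpus.truth) - len(unpublished)

    def test_decoys_share_first_and_last_author(self):
        corpus = generate(CorpusSpec(n_preprints=10, n_decoys_per_author=2, seed=9))
        decoys_by_pre = {}
        for art in corpus.articles:
            if art.doi.startswith("10.1300/decoy"):
                idx = int(art.doi.split(".")[-2])
                decoys_by_pre.setdefault(idx, []).append(art)
        for i, pre in enumerate(corpus.preprints):
            for decoy in decoys_by_pre[i]:
                assert decoy.authors[0].family == pre.authors[0].family
                assert decoy.authors[-1].family == pre.authors[-1].family

    def test_link_strata_are_disjoint_and_sized(self):
        spec = CorpusSpec(n_preprints=40, frac_published=0.6, frac_server_linked=0.25,
                          frac_registry_linked=0.15, seed=2)
        corpus = generate(spec)
        server = set(corpus.server_links)
        registry = {d for d, l in corpus.registry.items() if l.journal_doi is not None}
        assert len(server) == 10 and len(registry) == 6
        assert not server & registry
        published = {d for d, t in corpus.truth.items() if t is not None}
        assert server | registry <= published

    def test_initials_style_hides_full_names_on_preprint_only(self):
        corpus = generate(CorpusSpec(n_preprints=6, author_style="initials", seed=4))
        for pre in corpus.preprints:
            assert all(len(a.given) == 2 and a.given.endswith(".") for a in pre.authors)
            reg = corpus.registry[pre.doi]
            assert all(len(a.given) > 2 for a in reg.full_authors)


class TestToleranceEnvelope:
    def test_zero_perturbation_trivially_inside(self, backend):
        spec = CorpusSpec(n_preprints=15, title_edit_tokens=0, abstract_dropout=0.0, seed=6)
        env = tolerance_envelope(spec, backend)
        assert env.spec_inside
        assert env.max_title_edit_tokens >= 0 and env.max_abstract_dropout >= 0.0

    def test_heavy_title_edits_reported_outside(self, backend):
        spec = CorpusSpec(n_preprints=15, title_edit_tokens=6, abstract_dropout=0.0, seed=6)
        env = tolerance_envelope(spec, backend)
        assert not env.spec_inside
        assert env.max_title_edit_tokens < 6

    def test_envelope_is_brute_forced_from_twin_scores(self, backend):
        # at zero title edits and light dropout all twins must stay recoverable
        spec = CorpusSpec(n_preprints=15, title_edit_tokens=0, abstract_dropout=0.05, seed=6)
        env = tolerance_envelope(spec, backend)
        assert env.max_abstract_dropout >= 0.05
        assert env.spec_inside


class TestFixtureWiring:
    def test_sources_from_corpus_cascade_tags(self, backend):
        from pre2pub import resolve_link

        corpus = generate(CorpusSpec(n_preprints=20, title_edit_tokens=0,
                                     abstract_dropout=0.0, seed=13))
        sources = sources_from_corpus(corpus)
        tags = {}
        for pre in corpus.preprints:
            link = resolve_link(pre, sources, backend)
            if link:
                tags[pre.doi] = link.source.value
        for doi in corpus.server_links:
            assert tags[doi] == "server"
        for doi, reg in corpus.registry.items():
            if reg.journal_doi is not None:
                assert tags[doi] == "crossref"
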