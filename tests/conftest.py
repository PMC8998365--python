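import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from pre2pub import (
    AuthorName,
    CandidateArticle,
    HashedNgramBackend,
    PreprintRecord,
)
from pre2pub.textnorm import load_stopwords

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture(scope="session")
def backend():
    return HashedNgramBackend(dim=512)


@pytest.fixture()
def authors():
    """Six distinct authors, by key, for hand-built list-comparison cases."""
    return {
        k: AuthorName.parse(v)
        for k, v in {
            "A": "Alvarez, Maria",
            "B": "Bianchi, Luca",
            "C": "Chen, Wei",
            "D": "Dubois, Claire",
            "X": "Xu, Ming",
            "Y": "Yamada, Kenji",
        }.items()
    }


def make_pair(
    doi="10.1101/2020.00001",
    journal_doi="10.1200/art.00001",
    title="Spike protein binding dynamics in cultured airway epithelium",
    abstract=(
        "We measure binding kinetics of the viral spike protein against cultured "
        "human airway epithelial cells and quantify receptor occupancy over time "
        "using single molecule imaging across repeated exposure conditions."
    ),
    pre_date=dt.date(2020, 3, 1),
    art_date=dt.date(2020, 6, 1),
    art_title=None,
    art_abstract=None,
):
    """One preprint and its journal twin; identical text unless overridden."""
    names = [AuthorName.parse(n) for n in ("Alvarez, Maria", "Chen, Wei", "Dubois, Claire")]
    preprint = PreprintRecord(
        doi=doi, title=title, abstract=abstract, authors=names, publication_date=pre_date
    )
    article = CandidateArticle(
        pmid="900001",
        doi=journal_doi,
        title=art_title if art_title is not None else title,
        abstract=art_abstract if art_abstract is not None else abstract,
        authors=names,
        publication_date=art_date,
    )
    return preprint, article


@pytest.fixture()
def twin_pair():
    return make_pair()
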