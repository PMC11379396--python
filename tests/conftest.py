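import numpy as np
import pandas as pd
import pytest

from crossfa import (
    ItemCatalog,
    RatingsTable,
    Situation,
    load_catalogs,
    load_published_loadings,
    load_set_mappings,
)


@pytest.fixture(scope="session")
def catalogs():
    return load_catalogs()


@pytest.fixture(scope="session")
def general_catalog(catalogs):
    return catalogs[Situation.GENERAL]


@pytest.fixture(scope="session")
def published_general():
    return load_published_loadings("general")


@pytest.fixture(scope="session")
def published_human():
    return load_published_loadings("human")


@pytest.fixture(scope="session")
def mappings_general():
    return load_set_mappings("general")


@pytest.fixture(scope="session")
def mappings_human():
    return load_set_mappings("human")


@pytest.fixture
def tiny_catalog():
    return ItemCatalog(Situation.GENERAL, ("bold", "timid", "sociable"))


def make_ratings(
    scores: np.ndarray,
    item: str = "bold",
    site: str = "siteA",
    situation: Situation = Situation.GENERAL,
) -> RatingsTable:
    """Wrap a subjects x raters matrix for one item into a RatingsTable."""
    n, k = scores.shape
    rows = []
    for s in range(n):
        for r in range(k):
            if not np.isnan(scores[s, r]):
                rows.append((f"r{r}", f"s{s:02d}", item, scores[s, r]))
    return RatingsTable(
        site_id=site,
        situation=situation,
        records=pd.DataFrame(rows, columns=["rater", "subject", "item", "score"]),
    )


def make_multi_item_ratings(
    item_scores: dict[str, np.ndarray],
    site: str = "siteA",
    situation: Situation = Situation.GENERAL,
) -> RatingsTable:
    frames = [make_ratings(m, item=i, site=site, situation=situation).records
              for i, m in item_scores.items()]
    return RatingsTable(site, situation, pd.concat(frames, ignore_index=True))
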