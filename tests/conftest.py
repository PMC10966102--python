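import warnings

import numpy as np
import pandas as pd
import pytest

from flavorbench import chemprep, reviews, synthdata


@pytest.fixture(scope="session")
def bundle():
    """Default-size synthetic study (250 beers, 100 compounds), shared
    read-only across tests."""
    return synthdata.generate_bundle(seed=3)


@pytest.fixture(scope="session")
def appreciation(bundle):
    """Per-beer consumer appreciation target from the bundle's reviews."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, _ = reviews.filter_reviews(bundle.reviews, min_reviews=5)
        per_beer = reviews.rater_center_scores(filtered)
    return per_beer["overall"].reindex(bundle.chemistry.values.index)


@pytest.fixture()
def small_chem():
    """Tiny hand-built chemistry matrix (3 beers, 2 properties)."""
    values = pd.DataFrame(
        {"ethanol": [40000.0, 55000.0, 1200.0], "lactic_acid": [90.0, 60.0, 300.0]},
        index=pd.Index(["b1", "b2", "b3"], name="beer_id"),
    )
    meta = pd.DataFrame(
        {"style": ["Blond", "Blond", "Low/No-alcohol"],
         "abv": [5.1, 7.0, 0.2], "price_per_l": [4.0, 6.0, 3.0]},
        index=values.index,
    )
    return chemprep.CompoundMatrix(values=values, meta=meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
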