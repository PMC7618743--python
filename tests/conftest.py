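import logging

import numpy as np
import pytest

from shelftrial import catalog, cleaning, ecoscore, nutriscore

# missing-component warnings are expected noise in bulk scoring tests
logging.getLogger("shelftrial.nutriscore").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def compact_scored_catalog():
    """A small fully scored catalog (10 target shelves x 40), quirk-free."""
    cfg = catalog.CatalogConfig.compact(
        seed=11,
        comma_decimal_rate=0.0,
        trace_word_rate=0.0,
        lt_prefix_rate=0.0,
        missing_rate=0.0,
        alcohol_rate=0.0,
    )
    raw = catalog.generate_catalog(cfg)
    clean = cleaning.clean_nutrients(catalog.alcohol_and_missing_filter(raw))
    scored = nutriscore.score_catalog_health(clean)
    return ecoscore.score_catalog_eco(scored)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
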