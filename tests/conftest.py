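import pytest

from strokemir import catalog, datasets


@pytest.fixture(scope="session")
def curated_catalog():
    """(studies, standardized reports) from the packaged study catalog."""
    studies, reports = datasets.load_catalog()
    reports = catalog.standardize_names(reports, datasets.load_aliases())
    return studies, reports


@pytest.fixture(scope="session")
def qualified_groups(curated_catalog):
    studies, reports = curated_catalog
    return catalog.qualify_groups(studies, reports)


@pytest.fixture(scope="session")
def validation_summaries():
    return datasets.load_validation_summaries()
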