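"""Accessors for the packaged fixture tables.

``catalog.tsv``    - curated study catalog of published circulating-miRNA
                     differential-expression reports in ischemic stroke
                     (one row per study x reported miRNA).
``aliases.tsv``    - static reported-name -> canonical mature-name map
                     standing in for a live miRBase lookup.
``validation_summaries.tsv`` - per-group (mean, SEM, n) relative-expression
                     summaries of the 12 meta-analysis candidates measured by
                     qRT-PCR in 20 stroke vs 20 healthy plasma samples.
"""

from __future__ import annotations

from importlib import resources

from . import catalog as _catalog
from . import qpcr as _qpcr


def _data_path(name: str):
    return resources.files("strokemir.data").joinpath(name)


def load_catalog():
    """(studies, reports) from the packaged study catalog."""
    with resources.as_file(_data_path("catalog.tsv")) as p:
        return _catalog.read_catalog(p)


def load_aliases() -> _catalog.AliasMap:
    with resources.as_file(_data_path("aliases.tsv")) as p:
        return _catalog.read_alias_map(p)


def load_validation_summaries() -> list[_qpcr.GroupSummary]:
    with resources.as_file(_data_path("validation_summaries.tsv")) as p:
        return _qpcr.read_summaries(p)


def load_qualified_groups():
    """Standardize and qualify the packaged catalog in one call."""
    studies, reports = load_catalog()
    reports = _catalog.standardize_names(reports, load_aliases())
    return _catalog.qualify_groups(studies, reports)
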