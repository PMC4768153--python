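import logging

import pytest

from lousenet import (SynthConfig, generate_dataset, build_frame,
                      centrality_table, lice_load_table)
from lousenet.dominance import dominance_from_records

logging.getLogger("lousenet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def dataset():
    """One default-condition synthetic study (seeded degree effect in
    winter and summer)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def stage_tables(dataset):
    """Centrality, dominance and lice-load tables for the session dataset."""
    cents = centrality_table(dataset.scans, dataset.females)
    dom = dominance_from_records(dataset.agonistic, dataset.females)
    lice = lice_load_table(dataset.scans, dataset.females)
    return cents, dom, lice


@pytest.fixture(scope="session")
def degree_frame(dataset, stage_tables):
    cents, dom, lice = stage_tables
    return build_frame(lice, cents, dom.rank, dataset.attributes, "degree")
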